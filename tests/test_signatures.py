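"""Catalog construction, channel classification (vs independent oracles),
FFPE correction, exposure refitting and the CIN window statistic."""

import numpy as np
import pytest

from ploidyscape.channels import ID83_LABELS, SBS96_LABELS
from ploidyscape.genome import tile_windows
from ploidyscape.signatures import (MutationCatalog, SignatureMatrix,
                                    VariantRecord, build_catalog,
                                    cin_fraction, classify_indel,
                                    classify_sbs, correct_ffpe, fit_exposures,
                                    reconstruction_cosine)
from ploidyscape.synth import (CatalogSimConfig, add_ffpe_artifacts,
                               realize_id_catalog, realize_sbs_catalog,
                               simulate_catalog, simulate_variant_table)

# ---------------------------------------------------------------------------
# independent oracles (table-driven, structured differently from the
# implementation: explicit enumeration and plain string scans)

_RC = str.maketrans("ACGT", "TGCA")


def oracle_sbs_label(five, ref, alt, three):
    if ref in "AG":
        ctx = (five + ref + three).translate(_RC)[::-1]
        five, ref, three = ctx[0], ctx[1], ctx[2]
        alt = alt.translate(_RC)
    return f"{five}[{ref}>{alt}]{three}"


def oracle_id83_label(chrom, pos, ref, alt, genome):
    """Plain-string reference implementation of the ID83 decision tree."""
    seq = genome[chrom]
    if len(ref) > 1 and len(alt) == 1:          # deletion, anchored
        d = ref[1:]
        start = pos                              # 0-based start of deletion
        L = len(d)
        # count consecutive copies of d around the deleted one by scanning
        right = seq[start + L:start + L + 30 * L]
        left = seq[max(0, start - 30 * L):start]
        copies = 1
        while right.startswith(d * (copies)):
            copies += 1
        copies -= 1
        n_right = copies
        copies = 1
        while left.endswith(d * copies):
            copies += 1
        n_left = copies - 1
        units = 1 + n_right + n_left
        if L == 1:
            base = {"A": "T", "G": "C"}.get(d, d)
            return f"1:Del:{base}:{min(units - 1, 5)}"
        size = min(L, 5)
        if units > 1:
            return f"{size}:Del:R:{min(units - 1, 5)}"
        mh_r = len_common_prefix(d, seq[start + L:])
        mh_l = len_common_suffix(d, seq[:start])
        mh = max(mh_r, mh_l)
        if mh:
            cap = 5 if size == 5 else size - 1
            return f"{size}:Del:M:{min(mh, cap)}"
        return f"{size}:Del:R:0"
    if len(alt) > 1 and len(ref) == 1:          # insertion, anchored
        d = alt[1:]
        L = len(d)
        after = seq[pos:pos + 30 * L]            # bases right of the anchor
        before = seq[max(0, pos - 30 * L):pos]
        n_right = 0
        while after.startswith(d * (n_right + 1)):
            n_right += 1
        n_left = 0
        while before.endswith(d * (n_left + 1)):
            n_left += 1
        units = n_right + n_left
        if L == 1:
            base = {"A": "T", "G": "C"}.get(d, d)
            return f"1:Ins:{base}:{min(units, 5)}"
        return f"{min(L, 5)}:Ins:R:{min(units, 5)}"
    return None


def len_common_prefix(a, b):
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def len_common_suffix(a, b):
    return len_common_prefix(a[::-1], b[::-1])


def random_indels(genome, n, seed):
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    out = []
    while len(out) < n:
        chrom = chroms[rng.integers(len(chroms))]
        seq = genome[chrom]
        s = int(rng.integers(50, len(seq) - 50))
        L = int(rng.integers(1, 7))
        anchor = seq[s - 1]
        if rng.random() < 0.5:
            out.append(VariantRecord(chrom, s, anchor + seq[s:s + L], anchor))
        else:
            ins = "".join(rng.choice(list("ACGT"), size=L))
            out.append(VariantRecord(chrom, s, anchor, anchor + ins))
    return out


# ---------------------------------------------------------------------------
# SBS classification

def test_sbs_schema_examples(genome):
    # forward pyrimidine context
    chrom, seq = "chr1", genome["chr1"]
    i = seq.find("ACA", 100)
    v = VariantRecord(chrom, i + 2, "C", "A")
    assert SBS96_LABELS[classify_sbs(v, genome)] == "A[C>A]A"
    # purine reference: T G A with G>T maps to T[C>A]A
    i = seq.find("TGA", 100)
    v = VariantRecord(chrom, i + 2, "G", "T")
    assert SBS96_LABELS[classify_sbs(v, genome)] == "T[C>A]A"


def test_sbs_agrees_with_enumeration_oracle(genome):
    rng = np.random.default_rng(7)
    seq = genome["chr1"]
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for _ in range(600):
        i = int(rng.integers(2, len(seq) - 2))
        ref = seq[i - 1]
        alt = others[ref][rng.integers(3)]
        got = SBS96_LABELS[classify_sbs(VariantRecord("chr1", i, ref, alt),
                                        genome)]
        assert got == oracle_sbs_label(seq[i - 2], ref, alt, seq[i])


def test_all_96_channels_reachable(genome):
    counts = np.ones(96, dtype=np.int64)
    df = realize_sbs_catalog(counts, seed=1)
    seen = set()
    for r in df.itertuples():
        seen.add(classify_sbs(VariantRecord(r.chrom, r.pos, r.ref, r.alt),
                              genome))
    assert seen == set(range(96))


def test_sbs_reference_mismatch_raises(genome):
    seq = genome["chr1"]
    wrong = "A" if seq[99] != "A" else "C"
    with pytest.raises(ValueError, match="mismatch"):
        classify_sbs(VariantRecord("chr1", 100, wrong, "T"), genome)


# ---------------------------------------------------------------------------
# ID classification

def test_id_schema_examples():
    g = {"c": "GGACTTTTTTACGGA" + "ACGT" * 10}
    #          0123456789
    # deletion of one T inside the 6-T run -> 1:Del:T:5
    v = VariantRecord("c", 5, "CT", "C")
    assert ID83_LABELS[classify_indel(v, g)] == "1:Del:T:5"
    # insertion of C where no C is adjacent -> 1:Ins:C:0
    g2 = {"c": "GGATATATGGG" + "ACGT" * 10}
    v = VariantRecord("c", 4, "T", "TC")
    assert ID83_LABELS[classify_indel(v, g2)] == "1:Ins:C:0"
    # 4-bp deletion whose 3' flank shares a 2-bp prefix, no tandem repeat
    g3 = {"c": "TTGGCATGCAGGCCTTAA" + "ACGT" * 10}
    #            del CATG at 0-based 4..7; right flank CAGG shares "CA"
    v = VariantRecord("c", 4, "GCATG", "G")
    assert ID83_LABELS[classify_indel(v, g3)] == "4:Del:M:2"


def test_id_agrees_with_string_scan_oracle(genome):
    for v in random_indels(genome, 600, seed=3):
        got = classify_indel(v, genome)
        want = oracle_id83_label(v.chrom, v.pos, v.ref, v.alt, genome)
        assert got is not None and ID83_LABELS[got] == want, (v, want)


def test_complex_records_are_skipped(genome):
    mnv = VariantRecord("chr1", 100, "AC", "GT")
    assert classify_indel(mnv, genome) is None


# ---------------------------------------------------------------------------
# catalogs

def test_empty_variant_list_gives_zero_catalog(genome):
    cat = build_catalog([], genome)
    assert cat.sbs.sum() == 0 and cat.indel.sum() == 0


def test_unknown_contig_raises(genome):
    with pytest.raises(ValueError, match="contig"):
        build_catalog([VariantRecord("chrZ", 10, "A", "T")], genome)


def test_sbs_catalog_round_trip(genome, sbs_signatures):
    cfg = CatalogSimConfig(signatures=sbs_signatures,
                           exposures=(0.3, 0.2, 0.1, 0.1, 0.2, 0.1),
                           n_mutations=400, seed=21)
    counts = simulate_catalog(cfg)
    df = realize_sbs_catalog(counts, seed=21)
    recs = [VariantRecord(r.chrom, int(r.pos), r.ref, r.alt)
            for r in df.itertuples()]
    cat = build_catalog(recs, genome)
    assert np.array_equal(cat.sbs, counts)
    assert cat.indel.sum() == 0


def test_id_catalog_round_trip(genome, id_signatures):
    cfg = CatalogSimConfig(signatures=id_signatures,
                           exposures=(0.2, 0.15, 0.2, 0.45, 0.0),
                           n_mutations=250, seed=22)
    counts = simulate_catalog(cfg)
    df = realize_id_catalog(counts, seed=22)
    recs = [VariantRecord(r.chrom, int(r.pos), r.ref, r.alt)
            for r in df.itertuples()]
    cat = build_catalog(recs, genome)
    assert np.array_equal(cat.indel, counts)


def test_simulated_catalog_conserves_total(sbs_signatures):
    cfg = CatalogSimConfig(signatures=sbs_signatures,
                           exposures=(1, 0, 0, 0, 0, 0), n_mutations=0, seed=0)
    assert simulate_catalog(cfg).sum() == 0
    cfg = CatalogSimConfig(signatures=sbs_signatures,
                           exposures=(0.5, 0.5, 0, 0, 0, 0),
                           n_mutations=1234, seed=1)
    assert simulate_catalog(cfg).sum() == 1234


def test_single_signature_catalog_matches_column(sbs_signatures):
    cfg = CatalogSimConfig(signatures=sbs_signatures,
                           exposures=(0, 1, 0, 0, 0, 0),
                           n_mutations=100_000, seed=2)
    counts = simulate_catalog(cfg)
    col = sbs_signatures.matrix[:, 1]
    cos = counts @ col / np.linalg.norm(counts) / np.linalg.norm(col)
    assert cos >= 0.999


def test_disjoint_support_mixture_splits_binomially():
    labels = tuple(SBS96_LABELS)
    m = np.zeros((96, 2))
    m[:48, 0] = 1 / 48
    m[48:, 1] = 1 / 48
    sig = SignatureMatrix(labels=labels, names=("a", "b"), matrix=m)
    cfg = CatalogSimConfig(signatures=sig, exposures=(0.5, 0.5),
                           n_mutations=10_000, seed=3)
    counts = simulate_catalog(cfg)
    assert abs(counts[:48].sum() - 5000) <= 150    # 3 sigma


# ---------------------------------------------------------------------------
# FFPE forward model and correction

def test_artifact_fraction_zero_is_identity(ffpe_profile):
    counts = np.arange(96, dtype=np.int64)
    out = add_ffpe_artifacts(counts, ffpe_profile, 0.0, seed=0)
    assert np.array_equal(out, counts)


def test_artifact_arithmetic_half_doubles_total(ffpe_profile):
    counts = np.zeros(96, np.int64)
    counts[:10] = 100
    out = add_ffpe_artifacts(counts, ffpe_profile, 0.5, seed=1)
    assert out.sum() == 2000
    assert (out[:10] >= 100).all()      # biological counts untouched


def test_single_channel_artifact_lands_in_that_channel():
    profile = np.zeros(96)
    profile[7] = 1.0
    counts = np.full(96, 5, np.int64)
    out = add_ffpe_artifacts(counts, profile, 0.4, seed=2)
    added = out - counts
    assert added[7] == added.sum() > 0


def test_correction_on_clean_catalog_removes_little(sbs_signatures,
                                                    ffpe_profile):
    cfg = CatalogSimConfig(signatures=sbs_signatures,
                           exposures=(0.2, 0.4, 0.0, 0.0, 0.2, 0.2),
                           n_mutations=5000, seed=4)
    counts = simulate_catalog(cfg)
    _, removed = correct_ffpe(counts, ffpe_profile, sbs_signatures)
    assert removed <= 0.02 * counts.sum()


def test_correction_on_pure_artifact_removes_nearly_all(sbs_signatures,
                                                        ffpe_profile):
    cfg = CatalogSimConfig(signatures=sbs_signatures,
                           exposures=(0.0, 1.0, 0, 0, 0, 0),
                           n_mutations=100, seed=5)
    counts = add_ffpe_artifacts(simulate_catalog(cfg), ffpe_profile,
                                0.99, seed=5)
    bio, removed = correct_ffpe(counts, ffpe_profile, sbs_signatures)
    assert bio.sum() <= 0.05 * counts.sum()


def test_correction_conserves_counts_per_channel(sbs_signatures, ffpe_profile):
    cfg = CatalogSimConfig(signatures=sbs_signatures,
                           exposures=(0.5, 0.0, 0, 0, 0, 0.5),
                           n_mutations=4000, seed=6)
    clean = simulate_catalog(cfg)
    obs = add_ffpe_artifacts(clean, ffpe_profile, 0.5, seed=6)
    bio, removed = correct_ffpe(obs, ffpe_profile, sbs_signatures)
    assert (bio >= 0).all()
    assert bio.sum() + removed == obs.sum()


def test_wrong_profile_length_raises(sbs_signatures):
    with pytest.raises(ValueError, match="length"):
        correct_ffpe(np.ones(96), np.ones(10) / 10, sbs_signatures)


# ---------------------------------------------------------------------------
# exposure refitting

def test_exact_linear_catalog_recovered(sbs_signatures):
    e = np.array([0.5, 0.3, 0.2, 0.0, 0.0, 0.0])
    counts = np.round(sbs_signatures.matrix @ e * 10000)
    got = fit_exposures(counts, sbs_signatures)
    assert np.allclose(got.relative[:3], e[:3], atol=0.01)
    assert got.reconstruction_cosine >= 1 - 1e-6


def test_single_signature_contribution_is_one(sbs_signatures):
    counts = np.round(sbs_signatures.matrix[:, 2] * 3000)
    got = fit_exposures(counts, sbs_signatures)
    assert got.relative[2] == pytest.approx(1.0, abs=1e-9)


def test_pruning_is_idempotent(sbs_signatures):
    cfg = CatalogSimConfig(signatures=sbs_signatures,
                           exposures=(0.4, 0.3, 0.3, 0, 0, 0),
                           n_mutations=3000, seed=8)
    counts = simulate_catalog(cfg)
    first = fit_exposures(counts, sbs_signatures)
    retained = [i for i, r in enumerate(first.relative) if r > 0]
    sub = SignatureMatrix(
        labels=sbs_signatures.labels,
        names=tuple(sbs_signatures.names[i] for i in retained),
        matrix=sbs_signatures.matrix[:, retained])
    second = fit_exposures(counts, sub)
    assert np.allclose(second.relative, first.relative[retained], atol=1e-9)


def test_all_zero_catalog_rejected(sbs_signatures):
    with pytest.raises(ValueError, match="zero"):
        fit_exposures(np.zeros(96), sbs_signatures)


def test_reconstruction_cosine_bounds(sbs_signatures):
    e = np.zeros(6)
    e[0] = 100.0
    exact = sbs_signatures.matrix @ e
    assert reconstruction_cosine(exact, e, sbs_signatures.matrix) == \
        pytest.approx(1.0, abs=1e-9)
    orth = np.zeros(96)
    orth[np.argmin(sbs_signatures.matrix[:, 0])] = 1.0
    with pytest.raises(ValueError):
        reconstruction_cosine(np.zeros(96), e, sbs_signatures.matrix)


# ---------------------------------------------------------------------------
# CIN window statistic

def test_cin_trivial_extremes(genome):
    windows = tile_windows(50_000)
    assert cin_fraction([], windows) == 0.0
    hits = [(c, s + 1, "A", "T") for c, s, _ in windows]
    assert cin_fraction(hits, windows) == 100.0
    with pytest.raises(ValueError, match="empty"):
        cin_fraction([], [])


def test_cin_matches_generator_construction(genome):
    windows = tile_windows(50_000)[:40]
    df = simulate_variant_table(60, 0.25, windows, seed=4)
    recs = [VariantRecord(r.chrom, int(r.pos), r.ref, r.alt)
            for r in df.itertuples()]
    assert cin_fraction(recs, windows) == pytest.approx(25.0)
    hit_windows = {(r.chrom, (r.pos - 1) // 50_000) for r in df.itertuples()}
    assert len(hit_windows) == 10


def test_variant_table_validation(genome):
    windows = tile_windows(50_000)[:20]
    assert len(simulate_variant_table(0, 0.0, windows, seed=0)) == 0
    df = simulate_variant_table(40, 1.0, windows, seed=1)
    recs = [VariantRecord(r.chrom, int(r.pos), r.ref, r.alt)
            for r in df.itertuples()]
    assert cin_fraction(recs, windows) == 100.0
    with pytest.raises(ValueError):
        simulate_variant_table(3, 0.5, windows, seed=2)
    # ref alleles consistent with the reference genome
    for r in df.head(20).itertuples():
        assert genome[r.chrom][r.pos - 1] == r.ref
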