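"""Simulated variant tables and catalog realizations on the packaged genome.

Two generators live here:

* ``simulate_variant_table`` — scatter SNVs so that an exact, known fraction
  of genomic windows contains at least one variant (the ground truth for the
  CIN window statistic);
* ``realize_sbs_catalog`` / ``realize_id_catalog`` — turn channel count
  vectors into concrete VCF-style variants whose reference context realizes
  each channel, by sampling genomic sites with the required trinucleotide /
  homopolymer / repeat / microhomology structure.
"""

from __future__ import annotations

import functools

import numpy as np
import pandas as pd

from ..channels import COMPLEMENT, ID83_LABELS, SBS96_LABELS
from ..genome import synthetic_genome
from ..signatures import VariantRecord, classify_indel

_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def simulate_variant_table(n_variants: int, window_hit_fraction: float,
                           windows, seed: int = 0,
                           genome: dict[str, str] | None = None) -> pd.DataFrame:
    """SNV table hitting exactly round(fraction * n_windows) windows.

    Each hit window receives at least one variant; remaining variants are
    spread over the hit windows. Columns: chrom, pos (1-based), ref, alt.
    """
    if not 0.0 <= window_hit_fraction <= 1.0:
        raise ValueError("window_hit_fraction must lie in [0, 1]")
    windows = list(windows)
    if not windows:
        raise ValueError("empty window set")
    genome = genome if genome is not None else synthetic_genome()
    n_hit = int(round(window_hit_fraction * len(windows)))
    if n_variants < n_hit:
        raise ValueError(f"{n_variants} variants cannot hit {n_hit} windows")

    rng = np.random.default_rng(seed)
    hit_idx = rng.choice(len(windows), size=n_hit, replace=False)
    assignment = list(hit_idx)
    if n_hit:
        assignment += list(rng.choice(hit_idx, size=n_variants - n_hit))
    rows = []
    used: set[tuple[str, int]] = set()
    for w in assignment:
        chrom, start, end = windows[w]
        for _ in range(100):
            pos0 = int(rng.integers(start, end))
            if (chrom, pos0) not in used:
                break
        used.add((chrom, pos0))
        ref = genome[chrom][pos0]
        alt = _OTHER[ref][rng.integers(0, 3)]
        rows.append((chrom, pos0 + 1, ref, alt))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return df.sort_values(["chrom", "pos"], ignore_index=True)


# ---------------------------------------------------------------------------
# SBS site index: positions whose trinucleotide context realizes a channel

@functools.lru_cache(maxsize=1)
def _sbs_site_index() -> dict[str, list[tuple[str, int, str, str]]]:
    """channel label -> [(chrom, 1-based pos, ref, alt), ...] candidate sites."""
    genome = synthetic_genome()
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    bases = "ACGT"
    index: dict[str, list[tuple[str, int, str, str]]] = {l: [] for l in SBS96_LABELS}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        g = np.searchsorted(np.frombuffer(b"ACGT", np.uint8), arr)
        tri = g[:-2] * 16 + g[1:-1] * 4 + g[2:]
        order = np.argsort(tri, kind="stable")
        boundaries = np.searchsorted(tri[order], np.arange(65))
        for t in range(64):
            pos0 = order[boundaries[t]:boundaries[t + 1]][:3000] + 1
            five, ref, three = bases[t >> 4], bases[(t >> 2) & 3], bases[t & 3]
            if ref in "CT":
                for alt in _OTHER[ref]:
                    lab = f"{five}[{ref}>{alt}]{three}"
                    index[lab].extend((chrom, int(p) + 1, ref, alt) for p in pos0)
            else:   # purine-strand site: channel is the reverse complement
                for alt in _OTHER[ref]:
                    lab = (f"{COMPLEMENT[three]}[{COMPLEMENT[ref]}>"
                           f"{COMPLEMENT[alt]}]{COMPLEMENT[five]}")
                    index[lab].extend((chrom, int(p) + 1, ref, alt) for p in pos0)
    return index


def realize_sbs_catalog(counts: np.ndarray, seed: int = 0) -> pd.DataFrame:
    """Concrete SNVs (chrom, pos, ref, alt) realizing an SBS96 count vector."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (96,):
        raise ValueError("expected an SBS96 count vector")
    index = _sbs_site_index()
    rng = np.random.default_rng(seed)
    rows = []
    used: set[tuple[str, int]] = set()
    for lab, c in zip(SBS96_LABELS, counts):
        if c == 0:
            continue
        sites = index[lab]
        if len(sites) < c:
            raise ValueError(f"not enough genomic sites for channel {lab}")
        picked = 0
        for j in rng.permutation(len(sites)):
            chrom, pos, ref, alt = sites[j]
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            rows.append((chrom, pos, ref, alt))
            picked += 1
            if picked == c:
                break
        if picked < c:
            raise ValueError(f"site collisions exhausted channel {lab}")
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return df.sort_values(["chrom", "pos"], ignore_index=True)


# ---------------------------------------------------------------------------
# ID site index

_ID_SCAN = (("chr1", 2, 250_000),)
_SITE_CAP = 300


@functools.lru_cache(maxsize=1)
def _id_site_index() -> dict[str, list[tuple[str, int, str, str]]]:
    """channel label -> candidate VCF-style indel records on the genome.

    Built by a single inlined scan over the genome: at each position every
    candidate deletion of length 1-6 and every insertion duplicating the
    adjacent sequence is bucketed by its ID83 channel (the channel logic
    mirrors ``classify_indel``; agreement is asserted in the test suite).
    The scan stops early once every reachable channel holds enough sites.
    The ``Ins:...:0`` channels (inserted sequence with no adjacent copy)
    are realized separately with verified random proposals.
    """
    genome = synthetic_genome()
    index: dict[str, list[tuple[str, int, str, str]]] = {l: [] for l in ID83_LABELS}
    pyr = {"A": "T", "G": "C", "C": "C", "T": "T"}
    unfilled = {l for l in ID83_LABELS
                if not (l.split(":")[1] == "Ins" and l.endswith(":0"))}

    for chrom, lo, hi in _ID_SCAN:
        seq = genome[chrom]
        step_check = 0
        for s in range(lo, hi):
            anchor = seq[s - 1]
            for L in range(1, 7):
                d = seq[s:s + L]
                # adjacent copies of d (including the deleted one)
                copies = 1
                t = s + L
                while seq[t:t + L] == d:
                    copies += 1
                    t += L
                t = s
                while t - L >= 0 and seq[t - L:t] == d:
                    copies += 1
                    t -= L
                size = min(L, 5)
                if L == 1:
                    del_lab = f"1:Del:{pyr[d]}:{min(copies - 1, 5)}"
                elif copies >= 2:
                    del_lab = f"{size}:Del:R:{min(copies - 1, 5)}"
                else:
                    right = 0
                    for j in range(L):
                        if s + L + j < len(seq) and seq[s + L + j] == d[j]:
                            right += 1
                        else:
                            break
                    left = 0
                    for j in range(L):
                        if s - 1 - j >= 0 and seq[s - 1 - j] == d[L - 1 - j]:
                            left += 1
                        else:
                            break
                    mh = max(right, left)
                    if mh >= 1:
                        cap = size - 1 if size < 5 else 5
                        del_lab = f"{size}:Del:M:{min(mh, cap)}"
                    else:
                        del_lab = f"{size}:Del:R:0"
                bucket = index[del_lab]
                if len(bucket) < _SITE_CAP and not (
                        bucket and bucket[-1][0] == chrom
                        and s - bucket[-1][1] < 30):
                    bucket.append((chrom, s, anchor + d, anchor))
                    if len(bucket) == _SITE_CAP:
                        unfilled.discard(del_lab)
                # insertion duplicating d right before it: existing copies
                if L == 1:
                    ins_lab = f"1:Ins:{pyr[d]}:{min(copies, 5)}"
                else:
                    ins_lab = f"{size}:Ins:R:{min(copies, 5)}"
                bucket = index[ins_lab]
                if len(bucket) < _SITE_CAP and not (
                        bucket and bucket[-1][0] == chrom
                        and s - bucket[-1][1] < 30):
                    bucket.append((chrom, s, anchor, anchor + d))
                    if len(bucket) == _SITE_CAP:
                        unfilled.discard(ins_lab)
            step_check += 1
            if step_check >= 4096:
                step_check = 0
                if not unfilled:
                    return index
        if not unfilled:
            break
    return index


def _realize_ins_novel(label: str, rng, genome, used) -> tuple[str, int, str, str]:
    """Find an insertion with zero adjacent copies of the inserted sequence.

    Covers the ``:Ins:...:0`` channels, which the adjacency-duplication scan
    cannot produce: the inserted sequence is proposed (the labelled base for
    1-bp events, a random unit otherwise) and verified by classification.
    """
    size, _, base_or_r, _ = label.split(":")
    L = int(size)
    chrom = "chr1"
    seq = genome[chrom]
    for _ in range(2000):
        s = int(rng.integers(2, len(seq) - 20))
        if (chrom, s) in used:
            continue
        if base_or_r in ("C", "T"):
            unit = base_or_r if rng.random() < 0.5 else COMPLEMENT[base_or_r]
        else:
            unit = "".join(rng.choice(list("ACGT"), size=L))
        v = VariantRecord(chrom, s, seq[s - 1], seq[s - 1] + unit)
        ch = classify_indel(v, genome)
        if ch is not None and ID83_LABELS[ch] == label:
            return (chrom, s, seq[s - 1], seq[s - 1] + unit)
    raise ValueError(f"could not realize channel {label}")


def realize_id_catalog(counts: np.ndarray, seed: int = 0) -> pd.DataFrame:
    """Concrete indels (chrom, pos, ref, alt) realizing an ID83 count vector."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (83,):
        raise ValueError("expected an ID83 count vector")
    genome = synthetic_genome()
    index = _id_site_index()
    rng = np.random.default_rng(seed)
    rows = []
    # exclusion zone: indels must not disturb each other's context
    used: set[tuple[str, int]] = set()

    def reserve(chrom, pos, span):
        for p in range(pos - span - 12, pos + span + 13):
            used.add((chrom, p))

    for lab, c in zip(ID83_LABELS, counts):
        parts = lab.split(":")
        for _ in range(int(c)):
            if parts[1] == "Ins" and parts[3] == "0":
                chrom, pos, ref, alt = _realize_ins_novel(lab, rng, genome, used)
                reserve(chrom, pos, len(alt))
                rows.append((chrom, pos, ref, alt))
                continue
            sites = index[lab]
            placed = False
            for j in rng.permutation(len(sites)):
                chrom, pos, ref, alt = sites[j]
                if (chrom, pos) not in used:
                    reserve(chrom, pos, max(len(ref), len(alt)))
                    rows.append((chrom, pos, ref, alt))
                    placed = True
                    break
            if not placed:
                raise ValueError(f"not enough genomic sites for channel {lab}")
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return df.sort_values(["chrom", "pos"], ignore_index=True)
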