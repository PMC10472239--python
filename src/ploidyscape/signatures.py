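"""SBS96/ID83 mutation catalogs, FFPE correction and signature refitting.

Builds COSMIC-style catalogs from VCF + FASTA, removes a formalin-fixation
(FFPE) C>T artifact component by constrained non-negative decomposition,
refits catalogs against a reference signature matrix by non-negative least
squares with sparsity pruning, and computes a windowed SNV/indel chromosomal
instability (CIN) statistic: the percentage of genomic windows containing at
least one somatic variant.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import cosine as _cosine_distance
from sklearn.base import BaseEstimator, TransformerMixin

from .channels import (COMPLEMENT, ID83_INDEX, ID83_LABELS, SBS96_INDEX,
                       SBS96_LABELS, sbs_label)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers

@dataclass
class VariantRecord:
    """One normalized variant. ``pos`` is 1-based (VCF convention)."""
    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")


@dataclass
class MutationCatalog:
    """Per-sample SBS96 and ID83 integer count vectors (COSMIC channel order)."""
    sample_id: str
    sbs: np.ndarray
    indel: np.ndarray

    def __post_init__(self):
        self.sbs = np.asarray(self.sbs, dtype=np.int64)
        self.indel = np.asarray(self.indel, dtype=np.int64)
        if self.sbs.shape != (96,) or self.indel.shape != (83,):
            raise ValueError("catalog must hold 96 SBS and 83 ID channels")
        if (self.sbs < 0).any() or (self.indel < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @classmethod
    def empty(cls, sample_id: str = "sample") -> "MutationCatalog":
        return cls(sample_id, np.zeros(96, np.int64), np.zeros(83, np.int64))

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([
            pd.DataFrame({"channel": SBS96_LABELS, "kind": "SBS96",
                          "count": self.sbs}),
            pd.DataFrame({"channel": ID83_LABELS, "kind": "ID83",
                          "count": self.indel}),
        ], ignore_index=True)


@dataclass
class SignatureMatrix:
    """Channel-probability columns in COSMIC layout (one column per signature)."""
    labels: tuple[str, ...]
    names: tuple[str, ...]
    matrix: np.ndarray   # (n_channels, n_signatures)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.labels), len(self.names)):
            raise ValueError("matrix shape does not match labels/names")
        if (self.matrix < -1e-12).any():
            raise ValueError("signature entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("every signature column must sum to 1 (tol 1e-6)")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = tuple(df.iloc[:, 0].astype(str))
        names = tuple(df.columns[1:])
        return cls(labels=labels, names=names,
                   matrix=df.iloc[:, 1:].to_numpy(dtype=np.float64))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=list(self.names))
        df.insert(0, "channel", list(self.labels))
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ExposureVector:
    """Non-negative signature contributions for one catalog."""
    names: tuple[str, ...]
    absolute: np.ndarray      # mutation counts attributed to each signature
    relative: np.ndarray      # sums to 1 over retained signatures
    reconstruction_cosine: float

    def as_dict(self, relative: bool = True) -> dict[str, float]:
        vec = self.relative if relative else self.absolute
        return {n: float(v) for n, v in zip(self.names, vec)}


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str):
    return importlib.resources.files("ploidyscape") / "data" / name


def load_sbs_signatures() -> SignatureMatrix:
    """Packaged synthetic miniature SBS96 signature set (COSMIC layout)."""
    return SignatureMatrix.from_tsv(_data_path("signatures/synthetic_sbs96_mini.tsv"))


def load_id_signatures() -> SignatureMatrix:
    """Packaged synthetic miniature ID83 signature set (COSMIC layout)."""
    return SignatureMatrix.from_tsv(_data_path("signatures/synthetic_id83_mini.tsv"))


def load_ffpe_profile() -> np.ndarray:
    """Packaged synthetic C>T-dominated FFPE artifact profile over SBS96."""
    df = pd.read_csv(_data_path("signatures/synthetic_ffpe_artifact_sbs96.tsv"),
                     sep="\t")
    if list(df.iloc[:, 0]) != list(SBS96_LABELS):
        raise ValueError("artifact profile channel order mismatch")
    return df.iloc[:, 1].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# channel classification

def classify_sbs(variant: VariantRecord, genome: dict[str, str]) -> int | None:
    """SBS96 channel index of an SNV, or None when the context contains N.

    The trinucleotide context is read from the reference; purine-reference
    variants are mapped to the pyrimidine-strand representation.
    """
    if not variant.is_snv:
        raise ValueError("classify_sbs expects a single-nucleotide variant")
    seq = genome[variant.chrom]
    i = variant.pos - 1
    if i < 1 or i > len(seq) - 2:
        raise IndexError("variant context out of reference bounds")
    ref = seq[i].upper()
    if ref != variant.ref.upper():
        raise ValueError(f"reference mismatch at {variant.chrom}:{variant.pos}")
    five, three = seq[i - 1].upper(), seq[i + 1].upper()
    if "N" in (five, ref, three, variant.alt.upper()):
        logger.info("skipping variant with N context at %s:%d",
                    variant.chrom, variant.pos)
        return None
    return SBS96_INDEX[sbs_label(five, ref, variant.alt, three)]


def _count_right(seq: str, start: int, unit: str) -> int:
    L, c, t = len(unit), 0, start
    while seq[t:t + L] == unit:
        c += 1
        t += L
    return c


def _count_left(seq: str, end: int, unit: str) -> int:
    L, c, t = len(unit), 0, end
    while t - L >= 0 and seq[t - L:t] == unit:
        c += 1
        t -= L
    return c


def _mh_length(seq: str, start: int, deleted: str) -> int:
    """Longest microhomology between the deleted sequence and its flanks."""
    L = len(deleted)
    right = 0
    for j in range(L):
        if start + L + j < len(seq) and seq[start + L + j] == deleted[j]:
            right += 1
        else:
            break
    left = 0
    for j in range(L):
        if start - 1 - j >= 0 and seq[start - 1 - j] == deleted[L - 1 - j]:
            left += 1
        else:
            break
    return max(right, left)


def normalize_indel(variant: VariantRecord) -> tuple[str, int, str] | None:
    """Reduce an anchored VCF indel to (kind, 0-based start, sequence).

    Returns ("del", start of deleted bases, deleted seq) or
    ("ins", 0-based anchor position, inserted seq); None for records that are
    neither simple insertions nor simple deletions (MNVs, complex alleles).
    """
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if len(ref) == len(alt):
        return None
    # strip the shared left anchor base(s)
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    if len(ref) > len(alt):
        if k != len(alt):
            return None           # complex substitution+indel
        return ("del", variant.pos - 1 + k, ref[k:])
    else:
        if k != len(ref):
            return None
        return ("ins", variant.pos - 1 + k - 1, alt[k:])


def classify_indel(variant: VariantRecord, genome: dict[str, str]) -> int | None:
    """ID83 channel index of a left-aligned indel; None for complex records.

    Decision tree: insertion/deletion, size bucket 1/2/3/4/5+; 1-bp events
    stratified by C-or-T base (pyrimidine representation) and homopolymer
    run length; longer events by tandem-repeat copy number; deletions not in
    a repeat additionally by flanking-microhomology length.
    """
    norm = normalize_indel(variant)
    if norm is None:
        logger.info("skipping complex indel at %s:%d", variant.chrom, variant.pos)
        return None
    kind, start, seq_ind = norm
    g = genome[variant.chrom].upper()
    L = len(seq_ind)
    size = min(L, 5)
    if "N" in seq_ind:
        return None

    if kind == "del":
        if g[start:start + L] != seq_ind:
            raise ValueError(f"reference mismatch at {variant.chrom}:{variant.pos}")
        copies = 1 + _count_right(g, start + L, seq_ind) \
                   + _count_left(g, start, seq_ind)
        if L == 1:
            base = seq_ind if seq_ind in "CT" else COMPLEMENT[seq_ind]
            return ID83_INDEX[f"1:Del:{base}:{min(copies - 1, 5)}"]
        if copies >= 2:
            return ID83_INDEX[f"{size}:Del:R:{min(copies - 1, 5)}"]
        mh = _mh_length(g, start, seq_ind)
        if mh >= 1:
            cap = size - 1 if size < 5 else 5
            return ID83_INDEX[f"{size}:Del:M:{min(mh, cap)}"]
        return ID83_INDEX[f"{size}:Del:R:0"]

    # insertion between g[start] and g[start + 1]
    copies = _count_right(g, start + 1, seq_ind) + _count_left(g, start + 1, seq_ind)
    if L == 1:
        base = seq_ind if seq_ind in "CT" else COMPLEMENT[seq_ind]
        return ID83_INDEX[f"1:Ins:{base}:{min(copies, 5)}"]
    return ID83_INDEX[f"{size}:Ins:R:{min(copies, 5)}"]


def build_catalog(variants, genome: dict[str, str],
                  sample_id: str = "sample") -> MutationCatalog:
    """Classify an iterable of VariantRecords into a MutationCatalog.

    Unclassifiable records (N context, complex alleles) are counted and
    logged, not fatal. Contigs absent from the reference raise a ValueError
    naming them.
    """
    cat = MutationCatalog.empty(sample_id)
    sbs = np.zeros(96, np.int64)
    ind = np.zeros(83, np.int64)
    skipped = 0
    for v in variants:
        if v.chrom not in genome:
            raise ValueError(
                f"contig {v.chrom!r} absent from reference "
                f"(known: {sorted(genome)})")
        if v.is_snv:
            ch = classify_sbs(v, genome)
            if ch is None:
                skipped += 1
            else:
                sbs[ch] += 1
        else:
            ch = classify_indel(v, genome)
            if ch is None:
                skipped += 1
            else:
                ind[ch] += 1
    if skipped:
        logger.info("build_catalog: skipped %d unclassifiable records", skipped)
    cat.sbs = sbs
    cat.indel = ind
    return cat


# ---------------------------------------------------------------------------
# decomposition

def reconstruction_cosine(observed: np.ndarray, exposures: np.ndarray,
                          matrix: np.ndarray) -> float:
    """Cosine similarity between an observed catalog and its reconstruction."""
    observed = np.asarray(observed, dtype=np.float64)
    recon = np.asarray(matrix, dtype=np.float64) @ np.asarray(exposures, float)
    if not observed.any() or not recon.any():
        raise ValueError("cosine undefined for zero vectors")
    return float(1.0 - _cosine_distance(observed, recon))


def fit_exposures(counts: np.ndarray, signatures: SignatureMatrix,
                  min_contribution: float = 0.05) -> ExposureVector:
    """Refit a catalog onto reference signatures by NNLS with pruning.

    Signatures whose relative contribution falls below ``min_contribution``
    are dropped (all at once per round) and the fit repeated until every
    retained signature passes; relative contributions are renormalized over
    the retained set. Dropped signatures report zero contribution.
    """
    y = np.asarray(counts, dtype=np.float64)
    if y.shape != (signatures.n_channels,):
        raise ValueError("catalog and signature matrix schemas differ")
    if not y.any():
        raise ValueError("cannot fit an all-zero catalog")

    active = list(range(len(signatures.names)))
    while True:
        coef, _ = nnls(signatures.matrix[:, active], y)
        total = coef.sum()
        rel = coef / total if total > 0 else np.zeros_like(coef)
        below = [i for i, r in enumerate(rel) if r < min_contribution]
        if not below or len(active) - len(below) < 1:
            break
        active = [a for i, a in enumerate(active) if i not in set(below)]

    absolute = np.zeros(len(signatures.names))
    relative = np.zeros(len(signatures.names))
    absolute[active] = coef
    if coef.sum() > 0:
        relative[active] = coef / coef.sum()
    cos = reconstruction_cosine(y, absolute, signatures.matrix)
    return ExposureVector(names=signatures.names, absolute=absolute,
                          relative=relative, reconstruction_cosine=cos)


def correct_ffpe(counts: np.ndarray, artifact_profile: np.ndarray,
                 signatures: SignatureMatrix) -> tuple[np.ndarray, int]:
    """Split an SBS96 catalog into biological and FFPE-artifact components.

    Solves ``observed ~ S e + a * artifact_profile`` by NNLS over the
    reference matrix augmented with the artifact column, then subtracts the
    rounded artifact expectation channel-wise (clamped at zero). Returns
    (biological counts, removed artifact count); biological + removed equals
    the observed total per channel.
    """
    y = np.asarray(counts, dtype=np.float64)
    profile = np.asarray(artifact_profile, dtype=np.float64)
    if profile.shape != (signatures.n_channels,):
        raise ValueError("artifact profile length does not match channel schema")
    aug = np.column_stack([signatures.matrix, profile])
    coef, _ = nnls(aug, y)
    a = coef[-1]
    removed = np.minimum(np.round(a * profile).astype(np.int64),
                         np.asarray(counts, np.int64))
    biological = np.asarray(counts, np.int64) - removed
    return biological, int(removed.sum())


def cin_fraction(variants, windows) -> float:
    """Percentage of genomic windows containing at least one variant.

    ``windows`` are disjoint half-open 0-based (chrom, start, end) intervals;
    variant positions are 1-based.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("empty window set")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for w_idx, (chrom, start, end) in enumerate(windows):
        by_chrom.setdefault(chrom, []).append((start, end, w_idx))
    hit = np.zeros(len(windows), dtype=bool)
    for v in variants:
        chrom, pos = (v.chrom, v.pos) if isinstance(v, VariantRecord) else (v[0], v[1])
        p0 = pos - 1
        for start, end, w_idx in by_chrom.get(chrom, ()):
            if start <= p0 < end:
                hit[w_idx] = True
                break
    return 100.0 * hit.sum() / len(windows)


# ---------------------------------------------------------------------------
# estimators

class SignatureRefitter(BaseEstimator):
    """Refit catalogs onto a reference signature matrix (NNLS + pruning).

    ``fit(X)`` with X of shape (n_samples, n_channels) stores one
    ExposureVector per sample in ``exposures_`` and a relative-contribution
    DataFrame in ``contributions_``.
    """

    def __init__(self, signatures: SignatureMatrix | None = None,
                 min_contribution: float = 0.05):
        self.signatures = signatures
        self.min_contribution = min_contribution

    def _resolved(self) -> SignatureMatrix:
        return self.signatures if self.signatures is not None \
            else load_sbs_signatures()

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X))
        sig = self._resolved()
        self.exposures_ = [fit_exposures(row, sig, self.min_contribution)
                           for row in X]
        self.contributions_ = pd.DataFrame(
            [e.relative for e in self.exposures_], columns=list(sig.names))
        self.reconstruction_cosines_ = np.array(
            [e.reconstruction_cosine for e in self.exposures_])
        return self


class FfpeCorrector(BaseEstimator, TransformerMixin):
    """Remove an FFPE C>T artifact component from SBS96 catalogs.

    ``transform(X)`` with X of shape (n_samples, 96) returns corrected
    catalogs; per-sample removed artifact counts are stored in
    ``removed_counts_``.
    """

    def __init__(self, artifact_profile: np.ndarray | None = None,
                 signatures: SignatureMatrix | None = None):
        self.artifact_profile = artifact_profile
        self.signatures = signatures

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X))
        profile = self.artifact_profile if self.artifact_profile is not None \
            else load_ffpe_profile()
        sig = self.signatures if self.signatures is not None \
            else load_sbs_signatures()
        out = np.empty_like(X)
        removed = np.empty(X.shape[0], dtype=np.int64)
        for i, row in enumerate(X):
            out[i], removed[i] = correct_ffpe(row, profile, sig)
        self.removed_counts_ = removed
        return out
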