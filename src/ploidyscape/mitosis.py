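"""Morphometric scoring of mitotic chromatin figures.

Classifies binary chromatin masks by mitotic phase and detects the
aberrations scored in liver tissue sections: spindle multipolarity (more
than two major chromatin masses), metaphase-plate asymmetry, lagging
chromosomes (small chromatin fragments stranded between the segregating
masses) and anaphase bridges (a thin chromatin strand still connecting
them). The anaphase/telophase bucket includes anaphase figures.

A figure is aberrant when pole count > 2, plate asymmetry exceeds the
configured threshold (default 0.25), any lagging chromatin is present, or a
bridge is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image, disk
from sklearn.base import BaseEstimator

PROPHASE = "prophase"
METAPHASE = "metaphase"
ANA_TELO = "anaphase_telophase"
PHASES = (PROPHASE, METAPHASE, ANA_TELO)

ASYMMETRY_THRESHOLD = 0.25   # tau flagging an asymmetric plate as aberrant
MAJOR_MASS_FRACTION = 0.20   # a component this large counts as a pole
_OPEN_SELEM = disk(2)
_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class MitoticFigure:
    """One scored mitotic event."""
    figure_id: int
    phase: str
    pole_count: int = 1
    plate_asymmetry: float = 0.0
    lagging_count: int = 0
    bridge: bool = False

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase: {self.phase}")
        if self.phase != ANA_TELO and (self.bridge or self.lagging_count):
            raise ValueError("bridge/lagging chromatin is only defined for "
                             "anaphase/telophase figures")
        if self.pole_count < 1:
            raise ValueError("pole_count must be >= 1")
        if not 0.0 <= self.plate_asymmetry <= 1.0:
            raise ValueError("plate_asymmetry must lie in [0, 1]")

    def is_aberrant(self, asymmetry_threshold: float = ASYMMETRY_THRESHOLD) -> bool:
        return (self.pole_count > 2
                or self.plate_asymmetry > asymmetry_threshold
                or self.lagging_count > 0
                or self.bridge)

    @property
    def aberrant(self) -> bool:
        return self.is_aberrant()


@dataclass
class MitosisSummary:
    phase_counts: dict[str, int]
    aberrant_count: int
    n_figures: int
    aberrant_fraction: float
    metaphase_to_telophase_ratio: float | None   # None when no ana/telo events

    def to_dict(self) -> dict:
        return {
            "phase_counts": dict(self.phase_counts),
            "aberrant_count": self.aberrant_count,
            "n_figures": self.n_figures,
            "aberrant_fraction": self.aberrant_fraction,
            "metaphase_to_telophase_ratio": self.metaphase_to_telophase_ratio,
        }


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("chromatin mask must be 2D")
    if not m.any():
        raise ValueError("empty chromatin mask")
    return m


def _major_components(mask: np.ndarray):
    """(labels, major label list, minor label list) after opening."""
    opened = ndi.binary_opening(mask, structure=_OPEN_SELEM)
    if not opened.any():
        opened = mask                      # figure thinner than the opening
    lab, n = ndi.label(opened, structure=_CONN)
    sizes = ndi.sum_labels(opened, lab, index=np.arange(1, n + 1))
    total = sizes.sum()
    majors = [i + 1 for i, s in enumerate(sizes) if s >= MAJOR_MASS_FRACTION * total]
    minors = [i + 1 for i, s in enumerate(sizes) if s < MAJOR_MASS_FRACTION * total]
    return lab, sizes, majors, minors


def classify_phase(mask) -> str:
    """Phase from gross chromatin geometry.

    Two or more major masses (each >= 20% of chromatin area after opening)
    mean anaphase/telophase; a single elongated band (aspect ratio >= 2.5)
    means metaphase; a single compact mass means prophase.
    """
    m = _as_mask(mask)
    _, _, majors, _ = _major_components(m)
    if len(majors) >= 2:
        return ANA_TELO
    props = regionprops(m.astype(np.uint8))[0]
    minor = props.axis_minor_length
    aspect = props.axis_major_length / minor if minor > 0 else np.inf
    return METAPHASE if aspect >= 2.5 else PROPHASE


def count_poles(mask) -> int:
    """Number of major chromatin masses (candidate spindle poles)."""
    m = _as_mask(mask)
    _, _, majors, _ = _major_components(m)
    return max(1, len(majors))


def plate_asymmetry(mask) -> float:
    """Chromatin mass imbalance across the plate's principal axis.

    The mask is split by the principal (largest-variance) axis through the
    centroid; the score is |m1 - m2| / (m1 + m2) over the pixel counts on
    each side. Degenerate (collinear) masks score 0 with a warning.
    """
    m = _as_mask(mask)
    pts = np.column_stack(np.nonzero(m)).astype(np.float64)
    pts -= pts.mean(axis=0)
    cov = np.cov(pts.T) if len(pts) > 1 else np.zeros((2, 2))
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-9:     # all pixels collinear along the principal axis
        warnings.warn("degenerate (collinear) chromatin mask; asymmetry "
                      "score set to 0", stacklevel=2)
        return 0.0
    normal = evecs[:, 0]    # eigenvector of the SMALLER eigenvalue
    d = pts @ normal
    m1 = float(np.sum(d > 0)) + 0.5 * float(np.sum(d == 0))
    m2 = float(np.sum(d < 0)) + 0.5 * float(np.sum(d == 0))
    return abs(m1 - m2) / (m1 + m2)


def detect_anaphase_anomalies(mask) -> tuple[int, bool]:
    """(lagging chromatin count, bridge flag) for an anaphase/telophase figure.

    Lagging chromatin: minor components (< 20% of chromatin area after
    opening) lying within the convex hull spanned by the two largest masses.
    Bridge: the two largest masses are connected in the raw mask but only
    through a strand thin enough to vanish under morphological opening.
    """
    m = _as_mask(mask)
    lab, sizes, majors, minors = _major_components(m)
    if len(majors) < 2:
        raise ValueError("anaphase anomaly detection needs >= 2 poles")
    two = sorted(majors, key=lambda i: sizes[i - 1], reverse=True)[:2]
    hull = convex_hull_image(np.isin(lab, two))

    lagging = 0
    for i in minors:
        cy, cx = ndi.center_of_mass(lab == i)
        if hull[int(round(cy)), int(round(cx))]:
            lagging += 1

    raw_lab, _ = ndi.label(m, structure=_CONN)
    c0 = ndi.center_of_mass(lab == two[0])
    c1 = ndi.center_of_mass(lab == two[1])
    id0 = raw_lab[int(round(c0[0])), int(round(c0[1]))]
    id1 = raw_lab[int(round(c1[0])), int(round(c1[1]))]
    bridge = bool(id0 != 0 and id0 == id1)
    return lagging, bridge


def score_figure(mask, figure_id: int = 0) -> MitoticFigure:
    """Score one chromatin mask: phase, poles, asymmetry, anomalies."""
    m = _as_mask(mask)
    phase = classify_phase(m)
    if phase == ANA_TELO:
        poles = count_poles(m)
        lagging, bridge = detect_anaphase_anomalies(m)
        return MitoticFigure(figure_id=figure_id, phase=phase,
                             pole_count=poles, lagging_count=lagging,
                             bridge=bridge)
    if phase == METAPHASE:
        return MitoticFigure(figure_id=figure_id, phase=phase, pole_count=1,
                             plate_asymmetry=plate_asymmetry(m))
    return MitoticFigure(figure_id=figure_id, phase=phase, pole_count=1)


def summarize(figures: list[MitoticFigure],
              asymmetry_threshold: float = ASYMMETRY_THRESHOLD) -> MitosisSummary:
    """Cohort summary: phase counts, aberrant fraction, metaphase:telophase."""
    if not figures:
        raise ValueError("need at least one figure to summarize")
    counts = {p: 0 for p in PHASES}
    for f in figures:
        counts[f.phase] += 1
    n = len(figures)
    n_ab = sum(1 for f in figures if f.is_aberrant(asymmetry_threshold))
    n_telo = counts[ANA_TELO]
    ratio = counts[METAPHASE] / n_telo if n_telo else None
    return MitosisSummary(phase_counts=counts, aberrant_count=n_ab,
                          n_figures=n, aberrant_fraction=n_ab / n,
                          metaphase_to_telophase_ratio=ratio)


class MitosisScorer(BaseEstimator):
    """Estimator scoring a collection of chromatin masks.

    ``fit(X)`` with X an iterable of 2D binary masks populates ``figures_``
    (one MitoticFigure per mask) and ``summary_``.
    """

    def __init__(self, asymmetry_threshold: float = ASYMMETRY_THRESHOLD):
        self.asymmetry_threshold = asymmetry_threshold

    def fit(self, X, y=None):
        self.figures_ = [score_figure(m, figure_id=i) for i, m in enumerate(X)]
        self.summary_ = summarize(self.figures_, self.asymmetry_threshold)
        return self
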