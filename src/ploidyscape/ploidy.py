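"""Nuclear and cellular ploidy profiling from two-channel images.

The chain mirrors how hepatocyte ploidy is scored on Hoechst/β-catenin-style
stainings: segment nuclei in the DNA channel, integrate background-corrected
DNA-stain intensity per nucleus, locate the diploid (2n) reference intensity
as the lowest mode of the log2 intensity distribution, assign each nucleus a
ploidy class by rounding its log2 ratio to the reference, group nuclei into
cells with the membrane channel, and summarize the cohort profile: 2n / 4n /
>=8n fractions among mononucleated hepatocytes and the binucleated fraction
relative to total nuclei.

Border-touching and mitotic-flagged nuclei are excluded from calibration and
from every profile denominator (condensed mitotic chromatin and clipped
nuclei bias the DNA-content readout).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    lab, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab]


@dataclass
class NucleusRecord:
    nucleus_id: int
    centroid: tuple[float, float]          # (row, col), 0-based
    area: int
    raw_intensity: float
    corrected_intensity: float
    ploidy_class: int | None = None        # 2, 4, 8, 16, ... or None
    cell_id: int | None = None
    border: bool = False
    mitotic: bool = False

    @property
    def flagged(self) -> bool:
        return self.border or self.mitotic


@dataclass
class CellRecord:
    cell_id: int
    nucleus_ids: tuple[int, ...]

    @property
    def nuclearity(self) -> int:
        return len(self.nucleus_ids)


@dataclass
class PloidyProfile:
    """Cohort-level ploidy summary.

    ``class_fractions`` are over unflagged mononuclear nuclei (keys "2n",
    "4n", "8n_plus"); ``binucleated_fraction`` uses binucleated cells over
    total unflagged nuclei, so it is bounded by 0.5.
    """
    reference_intensity: float
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    binucleated_count: int
    total_nuclei: int
    binucleated_fraction: float
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "reference_intensity": self.reference_intensity,
            "class_counts": dict(self.class_counts),
            "class_fractions": dict(self.class_fractions),
            "binucleated_count": self.binucleated_count,
            "total_nuclei": self.total_nuclei,
            "binucleated_fraction": self.binucleated_fraction,
            "n_excluded": self.n_excluded,
        }


def segment_nuclei(dna: np.ndarray, min_area: int = 30,
                   min_separation: int = 6, smoothing_sigma: float = 1.0
                   ) -> np.ndarray:
    """Segment nuclei in a DNA-stain channel.

    Otsu foreground thresholding after light Gaussian smoothing, small-object
    removal, then a distance-transform watershed that splits touching nuclei.
    Returns an int32 label image (0 = background).
    """
    img = np.asarray(dna, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if img.max() <= img.min():
        return np.zeros(img.shape, dtype=np.int32)

    sm = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    mask = sm > threshold_otsu(sm)
    mask = _drop_small(mask, min_area)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(mask)
    coords = peak_local_max(dist, min_distance=min_separation, labels=mask,
                            exclude_border=False)
    peaks = np.zeros(mask.shape, dtype=bool)
    peaks[tuple(coords.T)] = True
    # merge plateau peaks of one nucleus into a single marker
    markers, _ = ndi.label(ndi.binary_dilation(peaks, structure=disk(2)))
    labels = watershed(-dist, markers, mask=mask)
    labels = labels.astype(np.int32)

    # drop any fragments below the minimum area produced by the split
    for r in regionprops(labels):
        if r.area < min_area:
            labels[labels == r.label] = 0
    return labels


def measure_nuclei(labels: np.ndarray, dna: np.ndarray,
                   annulus_width: int = 4) -> list[NucleusRecord]:
    """Integrate background-corrected DNA-stain intensity per nucleus.

    The local background of each nucleus is the median intensity in an
    annulus (morphological dilation ring) around it, excluding pixels of any
    labelled nucleus. Corrected intensity is sum(pixel - background) over the
    nucleus, clamped at zero. Nuclei touching the image border are flagged.
    """
    labels = np.asarray(labels)
    img = np.asarray(dna, dtype=np.float64)
    if labels.shape != img.shape:
        raise ValueError("label map and image shapes differ")
    h, w = img.shape
    any_label = labels > 0
    global_bg = float(np.median(img[~any_label])) if (~any_label).any() else 0.0

    records = []
    selem = disk(annulus_width)
    for r in regionprops(labels, intensity_image=img):
        y0, x0, y1, x1 = r.bbox
        py0 = max(0, y0 - annulus_width - 1)
        px0 = max(0, x0 - annulus_width - 1)
        py1 = min(h, y1 + annulus_width + 1)
        px1 = min(w, x1 + annulus_width + 1)
        patch_lab = labels[py0:py1, px0:px1]
        region = patch_lab == r.label
        # integrate over a 1-px dilation of the mask so edge intensity cut
        # off by thresholding is still counted; background ring lies beyond
        grown = ndi.binary_dilation(region, structure=disk(1)) & \
            ((patch_lab == 0) | region)
        ring = ndi.binary_dilation(grown, structure=selem) \
            & (patch_lab == 0) & ~grown
        patch_img = img[py0:py1, px0:px1]
        bg = float(np.median(patch_img[ring])) if ring.any() else global_bg
        raw = float(patch_img[grown].sum())
        corrected = max(0.0, raw - bg * int(grown.sum()))
        border = y0 == 0 or x0 == 0 or y1 == h or x1 == w
        records.append(NucleusRecord(
            nucleus_id=int(r.label), centroid=tuple(r.centroid),
            area=int(r.area), raw_intensity=raw,
            corrected_intensity=corrected, border=border))
    return records


def flag_mitotic(records: list[NucleusRecord], mitotic_mask: np.ndarray,
                 labels: np.ndarray, min_overlap: float = 0.5) -> None:
    """Set the mitotic flag on nuclei overlapping a mitotic annotation mask.

    The flag is metadata-driven (e.g. a pHH3-style annotation or generator
    ground truth); this package does not infer mitosis from the DNA channel.
    """
    mitotic_mask = np.asarray(mitotic_mask, dtype=bool)
    for rec in records:
        region = labels == rec.nucleus_id
        overlap = float((region & mitotic_mask).sum())
        if overlap >= min_overlap * rec.area:
            rec.mitotic = True


def calibrate_diploid_reference(intensities, bandwidth: float = 0.12,
                                mode_mass_floor: float = 0.05) -> float:
    """Locate the diploid (2n) reference intensity.

    Takes unflagged corrected intensities, forms a Gaussian kernel density
    estimate on log2 intensity (bandwidth in log2 units; Silverman's rule is
    used when ``bandwidth`` is None) and returns the lowest-intensity local
    mode whose +-0.5-log2-unit neighbourhood holds at least
    ``mode_mass_floor`` of the nuclei. Equivariant under rescaling all
    intensities by a constant.
    """
    x = np.log2(np.asarray([v for v in intensities if v > 0], dtype=np.float64))
    if x.size < 50:
        raise ValueError("need at least 50 positive intensities to calibrate")
    if bandwidth is None:
        bandwidth = 1.06 * x.std(ddof=1) * x.size ** (-1 / 5)
    grid = np.arange(x.min() - 0.6, x.max() + 0.6, 0.01)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bandwidth) ** 2).sum(axis=1)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:]) \
        & (dens[1:-1] > 0)
    modes = grid[1:-1][interior]
    # collapse plateau runs to single mode locations
    for m in np.sort(modes):
        mass = np.mean(np.abs(x - m) <= 0.5)
        if mass >= mode_mass_floor:
            return float(2.0 ** m)
    raise ValueError("no density mode holds the required mass; "
                     "supply a manual diploid reference intensity")


def assign_ploidy_class(intensity: float, reference: float) -> int:
    """Ploidy class 2 * 2^round(log2(intensity / reference)).

    Class boundaries fall at geometric midpoints 2^(m +- 0.5) * reference.
    Values below the diploid reference round down no further than class 1;
    profile summaries bucket classes <= 2 as 2n and >= 8 as >=8n.
    """
    if intensity <= 0 or reference <= 0:
        raise ValueError("intensity and reference must be positive")
    m = int(np.round(np.log2(intensity / reference)))
    return int(2 * 2.0 ** m) if m >= 0 else max(1, int(round(2 * 2.0 ** m)))


def segment_cells(membrane: np.ndarray, nucleus_labels: np.ndarray,
                  ridge_fraction: float = 0.25, max_pair_distance: float = 80.0
                  ) -> np.ndarray:
    """Group nuclei into cells using the membrane channel.

    Nucleus seeds are merged when no membrane ridge above a contrast
    threshold (``ridge_fraction`` of the robust membrane maximum) separates
    their centroids; a watershed on the membrane landscape, restricted to the
    filled membrane foreground, then draws cell territories. Every nucleus is
    covered by exactly one cell region. When the membrane channel carries no
    usable contrast a low-confidence warning is emitted and cell assignment
    degenerates towards one cell per unmerged seed group.
    """
    mem = np.asarray(membrane, dtype=np.float64)
    labels = np.asarray(nucleus_labels)
    if mem.shape != labels.shape:
        raise ValueError("membrane and nucleus label shapes differ")

    lo, hi = np.percentile(mem, (50, 99.5))
    threshold = lo + ridge_fraction * (hi - lo)
    if hi - lo < 4.0 * max(1.0, np.sqrt(max(lo, 1.0))):
        warnings.warn("membrane channel has no usable contrast; cell "
                      "segmentation is low-confidence", stacklevel=2)

    props = regionprops(labels)
    ids = [p.label for p in props]
    cents = np.array([p.centroid for p in props]) if props else np.empty((0, 2))

    parent = {i: i for i in ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    if len(ids) > 1:
        tree = cKDTree(cents)
        for i, j in tree.query_pairs(max_pair_distance):
            p0, p1 = cents[i], cents[j]
            npts = max(8, int(np.hypot(*(p1 - p0)) * 2))
            line = np.linspace(p0, p1, npts).T
            ridge = ndi.map_coordinates(mem, line, order=1).max()
            if ridge < threshold:
                ra, rb = find(ids[i]), find(ids[j])
                if ra != rb:
                    parent[rb] = ra
    seed_map = {i: find(i) for i in ids}
    merged = np.where(labels > 0, labels, 0).copy()
    for old, new in seed_map.items():
        if old != new:
            merged[labels == old] = new

    fg = ndi.binary_closing(mem > threshold, structure=disk(3))
    fg = ndi.binary_fill_holes(fg) | (labels > 0)
    cells = watershed(mem, merged.astype(np.int32), mask=fg)
    # relabel to consecutive ids
    out = np.zeros_like(cells, dtype=np.int32)
    for new_id, old in enumerate(np.unique(cells[cells > 0]), start=1):
        out[cells == old] = new_id
    return out


def assign_cells(records: list[NucleusRecord], cell_labels: np.ndarray
                 ) -> list[CellRecord]:
    """Attach cell ids to nuclei (by centroid lookup) and build CellRecords."""
    owners: dict[int, list[int]] = {}
    for rec in records:
        cy, cx = (int(round(c)) for c in rec.centroid)
        cy = int(np.clip(cy, 0, cell_labels.shape[0] - 1))
        cx = int(np.clip(cx, 0, cell_labels.shape[1] - 1))
        cid = int(cell_labels[cy, cx])
        if cid == 0:   # centroid fell on a boundary pixel; probe outward
            patch = cell_labels[max(0, cy - 2):cy + 3, max(0, cx - 2):cx + 3]
            nz = patch[patch > 0]
            cid = int(nz[0]) if nz.size else 0
        rec.cell_id = cid if cid else None
        if cid:
            owners.setdefault(cid, []).append(rec.nucleus_id)
    return [CellRecord(cell_id=c, nucleus_ids=tuple(sorted(n)))
            for c, n in sorted(owners.items())]


def compute_profile(records: list[NucleusRecord], cells: list[CellRecord],
                    reference: float) -> PloidyProfile:
    """Summarize a cohort of classified nuclei into a PloidyProfile."""
    unflagged = [r for r in records if not r.flagged]
    n_total = len(unflagged)
    n_excluded = len(records) - n_total
    nuclearity = {c.cell_id: c.nuclearity for c in cells}

    mono = [r for r in unflagged
            if r.cell_id is not None and nuclearity.get(r.cell_id, 1) == 1]
    if not mono:
        raise ValueError("no unflagged mononuclear nuclei; cannot profile")

    counts = {"2n": 0, "4n": 0, "8n_plus": 0}
    for r in mono:
        if r.ploidy_class is None:
            raise ValueError("ploidy classes must be assigned before profiling")
        if r.ploidy_class <= 2:
            counts["2n"] += 1
        elif r.ploidy_class == 4:
            counts["4n"] += 1
        else:
            counts["8n_plus"] += 1
    n_mono = len(mono)
    fractions = {k: v / n_mono for k, v in counts.items()}

    unflagged_ids = {r.nucleus_id for r in unflagged}
    n_binuc = sum(1 for c in cells if c.nuclearity == 2
                  and any(n in unflagged_ids for n in c.nucleus_ids))
    binuc_fraction = n_binuc / n_total if n_total else float("nan")
    return PloidyProfile(
        reference_intensity=reference, class_counts=counts,
        class_fractions=fractions, binucleated_count=n_binuc,
        total_nuclei=n_total, binucleated_fraction=binuc_fraction,
        n_excluded=n_excluded)


class PloidyProfiler(BaseEstimator):
    """End-to-end ploidy profiling estimator.

    ``fit(X)`` takes a (2, h, w) two-channel image (DNA, membrane) or a 2D
    DNA-only image, runs segmentation, intensity measurement, diploid
    calibration, class assignment, cell grouping and cohort summary, and
    exposes the results as fitted attributes.

    Attributes (after fit)
    ----------------------
    nucleus_labels_, cell_labels_ : label images
    nuclei_ : list[NucleusRecord]; cells_ : list[CellRecord]
    reference_intensity_ : diploid reference (a.u.)
    profile_ : PloidyProfile
    """

    def __init__(self, min_area: int = 30, min_separation: int = 6,
                 smoothing_sigma: float = 1.0, annulus_width: int = 4,
                 kde_bandwidth: float = 0.12, mode_mass_floor: float = 0.05,
                 ridge_fraction: float = 0.25, max_pair_distance: float = 80.0):
        self.min_area = min_area
        self.min_separation = min_separation
        self.smoothing_sigma = smoothing_sigma
        self.annulus_width = annulus_width
        self.kde_bandwidth = kde_bandwidth
        self.mode_mass_floor = mode_mass_floor
        self.ridge_fraction = ridge_fraction
        self.max_pair_distance = max_pair_distance

    def fit(self, X, y=None, mitotic_mask: np.ndarray | None = None):
        X = np.asarray(X)
        if X.ndim == 3 and X.shape[0] == 2:
            dna, membrane = X[0], X[1]
        elif X.ndim == 2:
            dna, membrane = X, None
        else:
            raise ValueError("X must be (2, h, w) two-channel or (h, w) DNA image")

        self.nucleus_labels_ = segment_nuclei(
            dna, min_area=self.min_area, min_separation=self.min_separation,
            smoothing_sigma=self.smoothing_sigma)
        self.nuclei_ = measure_nuclei(self.nucleus_labels_, dna,
                                      annulus_width=self.annulus_width)
        if mitotic_mask is not None:
            flag_mitotic(self.nuclei_, mitotic_mask, self.nucleus_labels_)

        usable = [r.corrected_intensity for r in self.nuclei_ if not r.flagged]
        self.reference_intensity_ = calibrate_diploid_reference(
            usable, bandwidth=self.kde_bandwidth,
            mode_mass_floor=self.mode_mass_floor)
        for r in self.nuclei_:
            if r.corrected_intensity > 0:
                r.ploidy_class = assign_ploidy_class(
                    r.corrected_intensity, self.reference_intensity_)

        if membrane is not None:
            self.cell_labels_ = segment_cells(
                membrane, self.nucleus_labels_,
                ridge_fraction=self.ridge_fraction,
                max_pair_distance=self.max_pair_distance)
        else:
            self.cell_labels_ = self.nucleus_labels_
        self.cells_ = assign_cells(self.nuclei_, self.cell_labels_)
        self.profile_ = compute_profile(self.nuclei_, self.cells_,
                                        self.reference_intensity_)
        return self

    def nuclei_frame(self) -> pd.DataFrame:
        rows = [{
            "nucleus_id": r.nucleus_id, "cy": r.centroid[0], "cx": r.centroid[1],
            "area": r.area, "raw_intensity": r.raw_intensity,
            "corrected_intensity": r.corrected_intensity,
            "ploidy_class": r.ploidy_class, "cell_id": r.cell_id,
            "border": r.border, "mitotic": r.mitotic,
        } for r in self.nuclei_]
        return pd.DataFrame(rows)

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"cell_id": c.cell_id,
                              "nuclearity": c.nuclearity,
                              "nucleus_ids": ";".join(map(str, c.nucleus_ids))}
                             for c in self.cells_])
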