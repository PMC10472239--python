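"""Synthetic mitotic chromatin figures with ground truth.

Each figure is a binary chromatin mask realizing a labelled geometry:

* prophase — one roughly round condensed mass;
* metaphase — one elongated plate (aspect ratio >= 2.5); the "asymmetric
  plate" aberration splits chromatin into two connected parallel bands with
  a 60/40 mass ratio across the plate axis;
* anaphase/telophase — two (or, for multipolar figures, three to four)
  separated major masses; "lagging" adds small chromatin fragments between
  the poles, "bridge" adds a thin connecting strand.

Aberration categories are mutually exclusive per figure and force a
compatible phase (multipolarity, lagging and bridging are anaphase/telophase
phenotypes; plate asymmetry is a metaphase phenotype), so generated labels
are never contradictory.
"""

from __future__ import annotations

import math

import numpy as np

from ..mitosis import ANA_TELO, METAPHASE, PROPHASE, MitoticFigure

ABERRATIONS = ("multipolar", "asymmetric", "lagging", "bridge")


def _blank(size: int) -> np.ndarray:
    return np.zeros((size, size), dtype=bool)


def _grid(size: int):
    yy, xx = np.mgrid[0:size, 0:size]
    return yy - size / 2.0, xx - size / 2.0


def _rot(yy, xx, angle):
    ca, sa = math.cos(angle), math.sin(angle)
    u = xx * ca + yy * sa
    v = -xx * sa + yy * ca
    return u, v


def _blob(mask, cy, cx, r, rng=None, wobble=0.0):
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    d = np.hypot(yy - cy, xx - cx)
    rr = r
    if rng is not None and wobble > 0:
        theta = np.arctan2(yy - cy, xx - cx)
        k = rng.integers(2, 5)
        phase = rng.uniform(0, 2 * np.pi)
        rr = r * (1.0 + wobble * np.sin(k * theta + phase))
    mask |= d <= rr


def _draw_prophase(size, rng) -> np.ndarray:
    m = _blank(size)
    _blob(m, size / 2, size / 2, size * 0.15, rng, wobble=0.08)
    return m


def _draw_metaphase(size, rng, angle) -> np.ndarray:
    m = _blank(size)
    yy, xx = _grid(size)
    u, v = _rot(yy, xx, angle)
    half_len = size * 0.27
    half_w = size * 0.055
    m |= (np.abs(u) <= half_len) & (np.abs(v) <= half_w)
    return m


def _draw_asymmetric_plate(size, rng, angle, split=(0.7, 0.3),
                           connected=True) -> np.ndarray:
    # two parallel bands with chromatin areas in the requested ratio across
    # the plate axis; a wide end connector keeps the figure one component
    # under morphological opening (set connected=False for the pure two-band
    # fixture whose principal-axis split recovers |s1 - s2| exactly)
    m = _blank(size)
    yy, xx = _grid(size)
    u, v = _rot(yy, xx, angle)
    half_len = size * 0.27
    gap = size * 0.07
    total_w = size * 0.11
    w1 = total_w * split[0]
    w2 = total_w * split[1]
    band1 = (np.abs(u) <= half_len) & (v >= gap / 2) & (v <= gap / 2 + w1)
    band2 = (np.abs(u) <= half_len) & (v <= -gap / 2) & (v >= -gap / 2 - w2)
    m = m | band1 | band2
    if connected:
        m |= (u >= half_len - 6.0) & (u <= half_len) & \
            (v >= -gap / 2 - 1.5) & (v <= gap / 2 + 1.5)
    return m


def _draw_anaphase(size, rng, angle, n_poles=2) -> np.ndarray:
    m = _blank(size)
    c = size / 2.0
    if n_poles == 2:
        d = size * 0.24
        r = size * 0.105
        for s in (-1, 1):
            _blob(m, c + s * d * math.sin(angle), c + s * d * math.cos(angle),
                  r, rng, wobble=0.06)
    else:
        d = size * 0.23
        r = size * 0.095
        offs = rng.uniform(0, 2 * np.pi)
        for k in range(n_poles):
            a = offs + 2 * np.pi * k / n_poles + rng.uniform(-0.15, 0.15)
            _blob(m, c + d * math.sin(a), c + d * math.cos(a), r, rng,
                  wobble=0.06)
    return m


def _add_lagging(m, size, rng, angle, n_frag) -> np.ndarray:
    c = size / 2.0
    d = size * 0.24
    # fragments sit in the midzone at distinct stations along the pole axis
    # so they never merge with each other or with the poles
    stations = np.linspace(-0.14, 0.14, n_frag) if n_frag > 1 else [0.0]
    for t0 in stations:
        t = t0 + rng.uniform(-0.02, 0.02)
        off = rng.uniform(-0.04, 0.04) * size  # across the axis
        cy = c + t * d * 2 * math.sin(angle) + off * math.cos(angle)
        cx = c + t * d * 2 * math.cos(angle) - off * math.sin(angle)
        _blob(m, cy, cx, 3.0)
    return m


def _add_bridge(m, size, angle) -> np.ndarray:
    yy, xx = _grid(size)
    u, v = _rot(yy, xx, angle)  # u runs along the pole axis
    d = size * 0.24
    m |= (np.abs(u) <= d) & (np.abs(v) <= 1.2)
    return m


def sample_mitotic_figures(n: int,
                           aberration_probs: dict[str, float] | None = None,
                           phase_probs: tuple[float, float, float] = (0.2, 0.5, 0.3),
                           seed: int = 0, size: int = 96,
                           ) -> list[tuple[np.ndarray, MitoticFigure]]:
    """Sample ``n`` (chromatin mask, ground-truth figure) pairs.

    ``aberration_probs`` maps {"multipolar", "asymmetric", "lagging",
    "bridge"} to probabilities (missing keys are 0; the remainder is the
    probability of a normal figure). ``phase_probs`` is (prophase, metaphase,
    anaphase/telophase) and applies to normal figures; aberrant figures take
    the phase their aberration requires. Deterministic for a fixed seed.
    """
    aberration_probs = dict(aberration_probs or {})
    for k in aberration_probs:
        if k not in ABERRATIONS:
            raise ValueError(f"unknown aberration type: {k}")
    p_ab = np.array([aberration_probs.get(k, 0.0) for k in ABERRATIONS])
    if np.any(p_ab < 0) or p_ab.sum() > 1.0 + 1e-9:
        raise ValueError("aberration probabilities must be >= 0 and sum <= 1")
    ph = np.asarray(phase_probs, dtype=float)
    if np.any(ph < 0) or abs(ph.sum() - 1.0) > 1e-9:
        raise ValueError("phase_probs must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        u = rng.random()
        edges = np.cumsum(p_ab)
        category = "normal"
        for k, e in zip(ABERRATIONS, edges):
            if u < e:
                category = k
                break
        angle = rng.uniform(0, 2 * np.pi)

        poles = 2
        asym = 0.0
        lagging = 0
        bridge = False
        if category == "normal":
            phase = (PROPHASE, METAPHASE, ANA_TELO)[rng.choice(3, p=ph / ph.sum())]
            if phase == PROPHASE:
                mask = _draw_prophase(size, rng)
                poles = 1
            elif phase == METAPHASE:
                mask = _draw_metaphase(size, rng, angle)
                poles = 1
            else:
                mask = _draw_anaphase(size, rng, angle)
        elif category == "multipolar":
            phase = ANA_TELO
            poles = int(rng.choice([3, 4], p=[0.7, 0.3]))
            mask = _draw_anaphase(size, rng, angle, n_poles=poles)
        elif category == "asymmetric":
            phase = METAPHASE
            poles = 1
            split = (0.7, 0.3)
            asym = split[0] - split[1]
            mask = _draw_asymmetric_plate(size, rng, angle, split=split)
        elif category == "lagging":
            phase = ANA_TELO
            lagging = int(rng.choice([1, 2], p=[0.6, 0.4]))
            mask = _draw_anaphase(size, rng, angle)
            mask = _add_lagging(mask, size, rng, angle, lagging)
        else:  # bridge
            phase = ANA_TELO
            bridge = True
            mask = _draw_anaphase(size, rng, angle)
            mask = _add_bridge(mask, size, angle)

        truth = MitoticFigure(
            figure_id=i, phase=phase, pole_count=poles,
            plate_asymmetry=asym, lagging_count=lagging, bridge=bridge)
        out.append((mask, truth))
    return out
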