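"""Ploidy profiling chain: segmentation, densitometry, calibration, classes."""

import dataclasses

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from ploidyscape.ploidy import (CellRecord, NucleusRecord, PloidyProfiler,
                                assign_ploidy_class,
                                calibrate_diploid_reference, compute_profile,
                                measure_nuclei, segment_cells, segment_nuclei)
from ploidyscape.synth import SceneConfig, render_scene, sample_scene


# ---------------------------------------------------------------------------
# segmentation

def test_noise_free_scene_segments_to_exact_count(noise_free_config):
    scene = sample_scene(noise_free_config)
    labels = segment_nuclei(render_scene(scene)[0].astype(float))
    assert labels.max() == len(scene.nuclei)


def test_blank_image_yields_no_labels():
    assert segment_nuclei(np.zeros((64, 64))).max() == 0


def test_non_finite_pixels_rejected():
    img = np.zeros((32, 32))
    img[3, 3] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        segment_nuclei(img)


def test_touching_nuclei_are_split_by_watershed():
    img = np.zeros((64, 64))
    for cx in (24, 38):   # two radius-7 disks touching along one edge
        rr, cc = draw_disk((32, cx), 7)
        img[rr, cc] = 500.0
    labels = segment_nuclei(img, min_area=20, min_separation=5)
    assert labels.max() == 2


# ---------------------------------------------------------------------------
# measurement

def test_uniform_offset_changes_corrected_intensity_little(default_scene):
    scene, img = default_scene
    dna = img[0].astype(float)
    labels = segment_nuclei(dna)
    base = {r.nucleus_id: r.corrected_intensity
            for r in measure_nuclei(labels, dna)}
    offset = {r.nucleus_id: r.corrected_intensity
              for r in measure_nuclei(labels, dna + 500.0)}
    rel = [abs(offset[k] - base[k]) / base[k]
           for k in base if base[k] > 1000]
    assert np.median(rel) < 0.02


def test_4n_to_2n_corrected_ratio_at_default_noise(default_scene):
    scene, img = default_scene
    dna = img[0].astype(float)
    recs = measure_nuclei(scene.nucleus_mask, dna)
    truth = scene.nuclei.set_index("nucleus_id")
    by_class = {}
    for r in recs:
        cls = int(truth.loc[r.nucleus_id, "ploidy_class"])
        by_class.setdefault(cls, []).append(r.corrected_intensity)
    ratio = np.mean(by_class[4]) / np.mean(by_class[2])
    assert ratio == pytest.approx(2.0, abs=0.1)


def test_border_touching_nucleus_is_flagged():
    img = np.full((64, 64), 10.0)
    rr, cc = draw_disk((2, 32), 8, shape=img.shape)
    img[rr, cc] = 500.0
    rr, cc = draw_disk((40, 32), 8)
    img[rr, cc] = 500.0
    labels = segment_nuclei(img, min_area=20)
    recs = measure_nuclei(labels, img)
    flags = sorted((round(r.centroid[0]), r.border) for r in recs)
    assert flags[0][1] is True and flags[1][1] is False


def test_empty_label_map_measures_to_empty_list():
    assert measure_nuclei(np.zeros((32, 32), int), np.zeros((32, 32))) == []


# ---------------------------------------------------------------------------
# calibration and class assignment

def test_calibration_unimodal_lognormal_sample():
    rng = np.random.default_rng(0)
    i0 = 5000.0
    vals = i0 * np.exp(rng.normal(0, 0.1, size=400))
    assert calibrate_diploid_reference(vals) == pytest.approx(i0, rel=0.05)


def test_calibration_bimodal_picks_lower_mode():
    rng = np.random.default_rng(1)
    i0 = 8000.0
    vals = np.concatenate([
        i0 * np.exp(rng.normal(0, 0.1, size=240)),
        2 * i0 * np.exp(rng.normal(0, 0.1, size=160))])
    assert calibrate_diploid_reference(vals) == pytest.approx(i0, rel=0.05)


def test_calibration_scale_equivariance():
    rng = np.random.default_rng(2)
    vals = 3000.0 * np.exp(rng.normal(0, 0.1, size=300))
    ref = calibrate_diploid_reference(vals)
    assert calibrate_diploid_reference(vals * 3.7) == \
        pytest.approx(3.7 * ref, rel=1e-6)


def test_calibration_requires_enough_nuclei():
    with pytest.raises(ValueError, match="at least 50"):
        calibrate_diploid_reference(np.full(10, 100.0))


def test_calibration_reports_missing_mode():
    # minor contamination below a dominant mode, floor set above its mass
    rng = np.random.default_rng(3)
    vals = 1000.0 * np.exp(rng.normal(0, 0.05, size=100))
    with pytest.raises(ValueError, match="manual"):
        calibrate_diploid_reference(vals, mode_mass_floor=1.1)


@pytest.mark.parametrize("factor,expected", [
    (1.0, 2), (2.0, 4), (2 ** 1.49, 4), (2 ** 1.51, 8), (4.0, 8), (8.0, 16),
])
def test_class_assignment_boundaries(factor, expected):
    assert assign_ploidy_class(1000.0 * factor, 1000.0) == expected


def test_class_assignment_rejects_non_positive():
    with pytest.raises(ValueError):
        assign_ploidy_class(0.0, 100.0)
    with pytest.raises(ValueError):
        assign_ploidy_class(100.0, -1.0)


# ---------------------------------------------------------------------------
# cell segmentation

def test_binucleated_cells_resolved_from_membrane(noise_free_config):
    cfg = dataclasses.replace(noise_free_config, binuclear_fraction=0.4)
    scene = sample_scene(cfg)
    img = render_scene(scene)
    cells = segment_cells(img[1].astype(float), scene.nucleus_mask)
    truth = scene.nuclei.set_index("nucleus_id")
    # nuclei of one true cell map to one segmented cell, and nuclei of
    # different true cells map to different segmented cells
    seg_of = {}
    for nid in truth.index:
        region = scene.nucleus_mask == nid
        seg_of[nid] = np.bincount(cells[region]).argmax()
    by_true_cell = truth.groupby("cell_id").groups
    seg_ids = []
    for cell_id, nids in by_true_cell.items():
        ids = {seg_of[n] for n in nids}
        assert len(ids) == 1
        seg_ids.append(ids.pop())
    assert len(set(seg_ids)) == len(seg_ids)


def test_no_membrane_signal_warns_low_confidence():
    labels = np.zeros((64, 64), int)
    rr, cc = draw_disk((32, 32), 6)
    labels[rr, cc] = 1
    with pytest.warns(UserWarning, match="low-confidence"):
        segment_cells(np.zeros((64, 64)), labels)


# ---------------------------------------------------------------------------
# profile

def _record(nid, cls, cell, **kw):
    return NucleusRecord(nucleus_id=nid, centroid=(0.0, 0.0), area=100,
                         raw_intensity=1.0, corrected_intensity=1.0,
                         ploidy_class=cls, cell_id=cell, **kw)


def test_all_mononuclear_diploid_profile():
    recs = [_record(i, 2, i) for i in range(1, 6)]
    cells = [CellRecord(i, (i,)) for i in range(1, 6)]
    p = compute_profile(recs, cells, reference=100.0)
    assert p.class_fractions == {"2n": 1.0, "4n": 0.0, "8n_plus": 0.0}
    assert p.binucleated_fraction == 0.0
    assert sum(p.class_fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_profile_flags_exclude_nuclei_from_denominators():
    recs = [_record(i, 2, i) for i in range(1, 5)]
    recs.append(_record(5, 8, 5, border=True))
    recs.append(_record(6, 8, 6, mitotic=True))
    cells = [CellRecord(i, (i,)) for i in range(1, 7)]
    p = compute_profile(recs, cells, reference=100.0)
    assert p.total_nuclei == 4 and p.n_excluded == 2
    assert p.class_fractions["8n_plus"] == 0.0


def test_profile_requires_mononuclear_nuclei():
    recs = [_record(1, 2, 1), _record(2, 2, 1)]
    cells = [CellRecord(1, (1, 2))]
    with pytest.raises(ValueError, match="mononuclear"):
        compute_profile(recs, cells, reference=100.0)


def test_binucleation_denominator_is_total_nuclei():
    # 2 binucleated cells (4 nuclei) + 4 mononuclear: fraction = 2/8
    recs = [_record(i, 2, c) for i, c in
            [(1, 1), (2, 1), (3, 2), (4, 2), (5, 3), (6, 4), (7, 5), (8, 6)]]
    cells = [CellRecord(1, (1, 2)), CellRecord(2, (3, 4)),
             CellRecord(3, (5,)), CellRecord(4, (6,)),
             CellRecord(5, (7,)), CellRecord(6, (8,))]
    p = compute_profile(recs, cells, reference=100.0)
    assert p.binucleated_fraction == pytest.approx(0.25)
    assert p.binucleated_fraction <= 0.5


def test_profiler_recovers_known_cohort_mixture():
    cfg = SceneConfig(n_cells=500, binuclear_fraction=0.30,
                      ploidy_class_probs=(0.60, 0.25, 0.12, 0.03), seed=55)
    scene = sample_scene(cfg)
    img = render_scene(scene).astype(np.float64)
    prof = PloidyProfiler().fit(img, mitotic_mask=scene.mitotic_mask)
    truth = scene.mononuclear_class_fractions()
    for key in ("2n", "4n", "8n_plus"):
        assert prof.profile_.class_fractions[key] == \
            pytest.approx(truth[key], abs=0.03)
    assert prof.profile_.binucleated_fraction == \
        pytest.approx(scene.binucleated_nucleus_fraction(), abs=0.02)


def test_profiler_is_sklearn_compatible():
    est = PloidyProfiler(min_area=40)
    params = est.get_params()
    assert params["min_area"] == 40
    clone = PloidyProfiler(**params)
    assert clone.get_params() == params
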