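"""Workflow over cases and cohorts: the combination grid, gating, statistics
and the synthetic-cohort generator."""

import dataclasses
import warnings

import numpy as np
import pytest

import petoverlap as po
from petoverlap.cohort import COMBINATIONS


@pytest.fixture(scope="module")
def high_case(pet_pair, rois, canonical_gts):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return po.run_case(pet_pair[0], pet_pair[1], rois[0], rois[1],
                           gt=canonical_gts["high"], case_id="high")


@pytest.fixture(scope="module")
def none_case(canonical_gts, default_config):
    gt = canonical_gts["none"]
    pet1 = po.render(gt, default_config, "PET1")
    pet2 = po.render(gt, default_config, "PET2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return po.run_case(pet1, pet2, po.roi_from_mask(gt.tumour_mask, 3),
                           po.roi_from_mask(gt.v2_mask, 3), gt=gt, case_id="none")


@pytest.fixture(scope="module")
def size_sweep_cases(default_config):
    """Fixed geometry and overlap; only the residual size ratio varies."""
    cases = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ratio in (0.8, 0.9, 1.0, 1.1, 1.2):
            cfg = dataclasses.replace(default_config, v2_size_ratio=ratio)
            gt = po.place_residual(po.build_ground_truth(cfg), (2, -2, -2))
            pet1 = po.render(gt, cfg, "PET1")
            pet2 = po.render(gt, cfg, "PET2")
            cases.append(po.run_case(pet1, pet2,
                                     po.roi_from_mask(gt.tumour_mask, 3),
                                     po.roi_from_mask(gt.v2_mask, 3),
                                     gt=gt, case_id=f"ratio{ratio}"))
    return cases


# ------------------------------------------------------------------ run_case

def test_grid_has_all_fifteen_combinations(high_case):
    assert set(high_case.metric_grid) == set(COMBINATIONS)
    assert len(high_case.metric_grid) == 15
    assert high_case.error is None


def test_no_overlap_case_behaviour(none_case):
    """The Bayesian pair detects the missing overlap; loose threshold
    combinations report a spurious one."""
    flab = none_case.metric_grid["FLAB"]
    assert flab.dice == flab.of == flab.x == flab.y == 0.0
    assert none_case.metric_grid["3040"].dice > 0.0
    assert none_case.metric_grid["4040"].dice > 0.0


def test_accuracy_reported_against_ground_truth(high_case, none_case):
    assert high_case.metric_grid["FLAB"].accuracy > 0.9
    assert none_case.metric_grid["FLAB"].accuracy is None  # GT overlap empty


# -------------------------------------------------------------------- gating

def test_gating_is_strict_and_exact(size_sweep_cases):
    kept, counts = po.gate_cohort(size_sweep_cases, "FLAB")
    for rec in size_sweep_cases:
        expected = rec.volumes_v2["FLAB"] < rec.volumes_v1["FLAB"]
        assert (rec in kept) == expected
        assert rec.gated == expected
    assert counts["retained"] + counts["excluded"] == len(size_sweep_cases)
    assert 0 < counts["retained"] < len(size_sweep_cases)


def test_gating_empty_when_all_residuals_larger(size_sweep_cases):
    bigger = [r for r in size_sweep_cases
              if r.volumes_v2["FLAB"] >= r.volumes_v1["FLAB"]]
    kept, counts = po.gate_cohort(bigger, "FLAB")
    assert kept == [] and counts["retained"] == 0


def test_gating_unknown_tag(size_sweep_cases):
    with pytest.raises(ValueError):
        po.gate_cohort(size_sweep_cases, "foo")


def test_excluding_larger_residuals_does_not_raise_mean_of(size_sweep_cases):
    """Cases whose residual exceeds V1 inflate the overlap fraction, so the
    gated mean is no larger than the all-cases mean for a fixed combination."""
    all_of = [r.metric_grid["7040"].of for r in size_sweep_cases]
    gated_of = [r.metric_grid["7040"].of for r in size_sweep_cases if r.gated]
    assert np.mean(gated_of) <= np.mean(all_of) + 1e-12
    # and OF grows with residual size at fixed overlap geometry
    assert all_of == sorted(all_of)


# ------------------------------------------------------------------ statistics

def test_volume_change():
    assert po.volume_change(10, 10) == 0.0
    assert po.volume_change(10, 5) == -50.0
    assert po.volume_change(10, 24.8) == pytest.approx(148.0)
    with pytest.raises(ValueError):
        po.volume_change(0, 5)


def test_summarize_against_oracle():
    s = po.summarize([1, 2, 3])
    assert (s.mean, s.sd, s.median) == (2.0, 1.0, 2.0)
    single = po.summarize([4.2])
    assert single.sd == 0.0 and single.degenerate
    rng = np.random.default_rng(0)
    vals = rng.normal(size=101)
    s = po.summarize(vals)
    assert s.mean == pytest.approx(vals.mean(), abs=1e-12)
    assert s.sd == pytest.approx(vals.std(ddof=1), abs=1e-12)
    assert s.median == pytest.approx(np.median(vals), abs=1e-12)
    with pytest.raises(ValueError):
        po.summarize([])


def test_mann_whitney_small_sample_exact():
    """Fully separated 4-vs-4 samples: p equals the enumerated 2/70."""
    p, sig = po.compare_distributions([1, 2, 3, 4], [10, 11, 12, 13])
    assert p == pytest.approx(2 / 70)
    assert not sig  # 0.0286 > 0.01


def test_mann_whitney_degenerate_and_identical():
    assert po.compare_distributions([5, 5, 5], [5, 5, 5]) == (1.0, False)
    p, sig = po.compare_distributions([1, 2, 3], [1, 2, 3])
    assert p == 1.0 and not sig
    with pytest.raises(ValueError):
        po.compare_distributions([1, 2], [1, 2, 3])


def test_mann_whitney_detects_shift():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 20)
        b = rng.normal(2, 1, 20)
        hits += po.compare_distributions(a, b)[1]
    assert hits >= 18


# --------------------------------------------------------------- synth cohort

def test_cohort_deterministic():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = po.synth_cohort(1, "oesophageal-like", seed=5)[0]
        b = po.synth_cohort(1, "oesophageal-like", seed=5)[0]
    assert a.volumes_v1 == b.volumes_v1
    assert a.volumes_v2 == b.volumes_v2
    assert a.metric_grid["FLAB"].dice == b.metric_grid["FLAB"].dice
    assert a.misalignment_mm == b.misalignment_mm


def test_cohort_structure_and_variability(mixed_cohort):
    assert all(len(r.metric_grid) == 15 for r in mixed_cohort)
    dices = [r.metric_grid["FLAB"].dice for r in mixed_cohort]
    assert np.std(dices, ddof=1) > 0.2  # highly variable across cases
    # residual misalignment is worse for the profile with harder registration
    oeso = [r.residual_misalignment_mm for r in mixed_cohort
            if r.site_tag == "oesophageal-like"]
    hn = [r.residual_misalignment_mm for r in mixed_cohort
          if r.site_tag == "HN-like"]
    assert np.mean(hn) > np.mean(oeso)


def test_tight_thresholds_gate_more_cases(mixed_cohort):
    """90%-threshold residuals are tiny, so nearly every case keeps V2 < V1;
    40%-threshold residuals are huge, so almost none does."""
    kept90 = po.gate_cohort(mixed_cohort, "7090")[1]["retained"]
    kept40 = po.gate_cohort(mixed_cohort, "7040")[1]["retained"]
    assert kept90 > kept40


def test_cohort_summary(mixed_cohort):
    summary = po.summarize_cohort(mixed_cohort)
    assert summary.n_cases == len(mixed_cohort)
    assert 0 <= summary.n_gated <= summary.n_cases
    assert summary.v2_smaller_counts["7090"] > summary.v2_smaller_counts["7040"]
    if summary.n_gated:
        for stats in summary.per_combination.values():
            assert stats["dice"].n == summary.n_gated
    assert summary.volume_change is not None


def test_unknown_profile_rejected():
    with pytest.raises(ValueError):
        po.synth_cohort(2, "lung-like", seed=0)
    with pytest.raises(ValueError):
        po.synth_cohort(0, "mixed", seed=0)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=40))
def test_summarize_matches_numpy_oracle(values):
    s = po.summarize(values)
    arr = np.asarray(values)
    assert s.mean == pytest.approx(arr.mean(), abs=1e-9, rel=1e-12)
    assert s.sd == pytest.approx(arr.std(ddof=1), abs=1e-9, rel=1e-12)
    assert s.median == pytest.approx(np.median(arr), abs=1e-9, rel=1e-12)
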