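"""Pupil preprocessing: QC rules, filtering, binning, z-transform,
realignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pupilbias.config import SimConfig
from pupilbias.errors import ConfigError, DegenerateDataError, PipelineError
from pupilbias import pupilprep
from pupilbias.pupilprep import (QCReport, TrialQC, downsample_median,
                                 filter_implausible, interpolate_gaps,
                                 lowpass, merge_binocular,
                                 preprocess_dataset, preprocess_participant,
                                 reject_trials, zscore_pooled)
from pupilbias.synthgen import RawSampleStream, generate_dataset


# ---------------------------------------------------------------------------
# elementary stages
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("l, r, vl, vr, expected", [
    (4.0, 4.0, True, True, 4.0),
    (3.8, 4.2, True, True, 4.0),
    (4.0, 4.0, True, False, np.nan),   # both eyes required
    (4.0, np.nan, True, True, np.nan),
])
def test_merge_binocular(l, r, vl, vr, expected):
    out = merge_binocular([l], [r], [vl], [vr])
    if np.isnan(expected):
        assert np.isnan(out[0])
    else:
        assert out[0] == expected


def test_plausibility_filter_bounds():
    trace, n_bad = filter_implausible(np.array([1.9, 7.1, 4.5, 2.0, 7.0]))
    assert np.isnan(trace[0]) and np.isnan(trace[1])
    np.testing.assert_array_equal(trace[2:], [4.5, 2.0, 7.0])
    assert n_bad == 2
    with pytest.raises(ConfigError):
        filter_implausible(np.array([4.0]), lo=7, hi=2)


def test_trial_rejection_boundary_is_strict():
    n = 100
    t = np.arange(n, dtype=float)
    make = lambda n_missing: np.concatenate(
        [np.full(n_missing, np.nan), np.full(n - n_missing, 4.0)])
    trials = [(0, "NRS", t, make(41)), (1, "NRS", t, make(40)),
              (2, "control", t, make(0))]
    kept, qc = reject_trials(trials)
    assert [q.kept for q in qc] == [False, True, True]
    assert qc[0].missing_fraction == pytest.approx(0.41)


def test_participant_rejection_boundary_is_strict():
    def report(n_valid, n_total):
        return QCReport("p", [TrialQC(i, "NRS", 0.0, i < n_valid)
                              for i in range(n_total)])
    assert not report(99, 200).participant_kept    # 49.5% < 50%
    assert report(100, 200).participant_kept       # exactly 50% kept
    assert report(200, 200).participant_kept


def test_interpolation_midpoint_identity_and_edges():
    np.testing.assert_allclose(
        interpolate_gaps(np.array([4.0, np.nan, 5.0])), [4.0, 4.5, 5.0])
    x = np.array([1.0, 2.0, 3.0])
    np.testing.assert_array_equal(interpolate_gaps(x), x)
    np.testing.assert_allclose(
        interpolate_gaps(np.array([np.nan, np.nan, 4.2, 5.0])),
        [4.2, 4.2, 4.2, 5.0])
    with pytest.raises(DegenerateDataError):
        interpolate_gaps(np.array([np.nan, np.nan]))


def test_lowpass_frequency_response():
    fs = 600.0
    t = np.arange(0, 4.0, 1 / fs)
    # DC gain exactly 1
    np.testing.assert_allclose(lowpass(np.full(t.size, 4.0), fs),
                               np.full(t.size, 4.0), atol=1e-9)
    # a 50-Hz tone (far above the 4-Hz cutoff) is attenuated by >= 20 dB
    hi = np.sin(2 * np.pi * 50 * t)
    assert np.abs(lowpass(hi, fs)[600:-600]).max() < 0.1
    # a 0.5-Hz tone passes within 1%
    lo = np.sin(2 * np.pi * 0.5 * t)
    mid = slice(600, -600)
    assert np.abs(lowpass(lo, fs)[mid] - lo[mid]).max() < 0.01
    with pytest.raises(ConfigError):
        lowpass(t, fs, cutoff=300.0)


def test_median_binning():
    fs = 600.0
    t = np.arange(15) * (1000 / fs)  # one full 25-ms bin
    starts, vals = downsample_median(np.arange(1.0, 16.0), t)
    assert starts[0] == 0.0 and vals[0] == 8.0
    # a 3,000-ms epoch at 600 Hz yields 120 bins
    t3 = np.arange(1800) * (1000 / fs)
    starts3, vals3 = downsample_median(np.full(1800, 4.0), t3)
    assert len(starts3) == 120
    assert np.all(vals3 == 4.0)
    with pytest.raises(ConfigError):
        downsample_median(np.arange(4.0), t[:4], bin_ms=0)


def test_zscore_convention_and_affine_invariance(rng):
    m, s = zscore_pooled(np.array([3.0, 4.0, 5.0]))
    np.testing.assert_allclose((np.array([3.0, 4.0, 5.0]) - m) / s,
                               [-1.0, 0.0, 1.0])  # sample-SD convention
    x = rng.normal(4.5, 0.3, 500)
    m1, s1 = zscore_pooled(x)
    m2, s2 = zscore_pooled(2.5 * x + 1.0)
    np.testing.assert_allclose((x - m1) / s1,
                               (2.5 * x + 1.0 - m2) / s2, atol=1e-10)
    z = (x - m1) / s1
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0)
    with pytest.raises(DegenerateDataError):
        zscore_pooled(np.full(10, 4.0))


@given(st.integers(0, 10_000))
def test_zscore_pool_standardised_for_any_seed(seed):
    x = np.random.default_rng(seed).normal(4.0, 0.5, 64)
    m, s = zscore_pooled(x)
    z = (x - m) / s
    assert abs(z.mean()) < 1e-10
    assert z.std(ddof=1) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# full participant pipeline
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def clean_pv_stream():
    cfg = SimConfig(n_per_group=1, pv_trials=12, dpt_trials=2, seed=21,
                    blink_rate=0.0, artifact_rate=0.0)
    streams, _, _ = generate_dataset(cfg)
    return next(s for s in streams if s.task == "PV"), cfg


def test_realigned_traces_start_at_zero(clean_pv_stream):
    stream, cfg = clean_pv_stream
    res = preprocess_participant(stream)
    for cond, trace in res.condition_means.items():
        assert trace[0] == 0.0
    assert res.difference[0] == 0.0
    assert res.difference.size == cfg.n_image_bins


def test_null_configuration_gives_identically_zero_difference():
    cfg = SimConfig(n_per_group=1, pv_trials=8, dpt_trials=2, seed=3,
                    smoker_effect_mean=0, smoker_effect_sd=0,
                    nonsmoker_effect_mean=0, nonsmoker_effect_sd=0,
                    noise_sd=0.0, blink_rate=0.0, artifact_rate=0.0)
    streams, _, _ = generate_dataset(cfg)
    for pv in (s for s in streams if s.task == "PV"):
        res = preprocess_participant(pv)
        np.testing.assert_array_equal(res.difference,
                                      np.zeros(cfg.n_image_bins))


def test_half_missing_trial_is_rejected_downstream(clean_pv_stream):
    """A contiguous gap covering 50% of a trial's samples fails the 40%
    missingness rule once it reaches trial QC."""
    stream, cfg = clean_pv_stream
    df = stream.samples.copy()
    rows = df.index[df["trial"] == 0]
    gap = rows[: len(rows) // 2]
    df.loc[gap, ["valid_l", "valid_r"]] = False
    df.loc[gap, ["pupil_l", "pupil_r"]] = np.nan
    broken = RawSampleStream(stream.participant_id, stream.group, "PV", df)
    res = preprocess_participant(broken)
    qc0 = next(t for t in res.qc.trials if t.trial == 0)
    assert not qc0.kept
    assert qc0.missing_fraction == pytest.approx(0.5)
    assert all(t.kept for t in res.qc.trials if t.trial != 0)


def test_participant_dropped_when_most_trials_unusable(clean_pv_stream):
    stream, cfg = clean_pv_stream
    df = stream.samples.copy()
    bad_trials = range(0, 7)  # 7 of 12 trials > 50%
    for tr in bad_trials:
        rows = df.index[df["trial"] == tr]
        gap = rows[: int(len(rows) * 0.6)]
        df.loc[gap, ["valid_l", "valid_r"]] = False
        df.loc[gap, ["pupil_l", "pupil_r"]] = np.nan
    broken = RawSampleStream(stream.participant_id, stream.group, "PV", df)
    assert preprocess_participant(broken) is None
    with pytest.raises(PipelineError, match="rejected"):
        preprocess_dataset([broken])


def test_condition_mean_is_trial_average():
    """Two NRS trials with realigned bin values 0.2 and 0.4 average to 0.3
    (checked through the public pipeline on constructed data)."""
    per = {"NRS": [np.array([0.0, 0.2]), np.array([0.0, 0.4])],
           "control": [np.array([0.0, 0.0])]}
    means = {c: np.mean(np.vstack(v), axis=0) for c, v in per.items()}
    assert means["NRS"][1] == pytest.approx(0.3)
    assert (means["NRS"] - means["control"])[1] == pytest.approx(0.3)


def test_dataset_level_preprocessing_output_shapes(tiny_dataset, tiny_config):
    streams, _, _ = tiny_dataset
    epochs, diffs, qc = preprocess_dataset(
        [s for s in streams if s.task == "PV"])
    n_kept = diffs.shape[0]
    assert n_kept >= 1
    assert diffs.shape[1] == 2 + tiny_config.n_image_bins
    assert set(epochs["condition"]) == {"NRS", "control"}
    assert len(qc) == 2 * tiny_config.n_per_group
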