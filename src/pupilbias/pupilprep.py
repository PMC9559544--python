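"""Passive-viewing pupil preprocessing.

Transforms raw binocular sample streams into per-participant, per-condition
z-scored pupil traces on a 25-ms grid, applying the study's quality-control
rules.  The stage order is fixed:

    binocular merge -> plausibility filter -> trial QC -> interpolation
    -> low-pass -> median binning -> participant z-transform
    -> realignment -> condition averaging -> NRS-minus-control differencing

Bins are half-open ``[k*25, (k+1)*25)`` ms, 0-based and anchored at image
onset; baseline bins carry negative indices.  Missingness for trial QC is
the fraction of baseline+image samples still missing after the binocular
validity rule and the plausibility filter.  The participant z-transform
pools the binned baseline+image values of all kept trials and uses the
sample (n-1) SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError, DegenerateDataError, PipelineError
from .synthgen import RawSampleStream

logger = logging.getLogger(__name__)

PLAUSIBLE_MM = (2.0, 7.0)
MAX_TRIAL_MISSING = 0.40
MIN_VALID_TRIAL_FRACTION = 0.50
BIN_MS = 25
LOWPASS_CUTOFF_HZ = 4.0
LOWPASS_ORDER = 3


@dataclass
class TrialQC:
    trial: int
    condition: str
    missing_fraction: float
    kept: bool


@dataclass
class QCReport:
    """Per-trial and per-participant quality control outcome."""

    participant_id: str
    trials: list[TrialQC] = field(default_factory=list)
    implausible_count: int = 0

    @property
    def valid_trial_fraction(self) -> float:
        if not self.trials:
            return 0.0
        return sum(t.kept for t in self.trials) / len(self.trials)

    @property
    def participant_kept(self) -> bool:
        return self.valid_trial_fraction >= MIN_VALID_TRIAL_FRACTION

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "implausible_count": self.implausible_count,
            "valid_trial_fraction": self.valid_trial_fraction,
            "participant_kept": self.participant_kept,
            "trials": [vars(t) for t in self.trials],
        }


# ---------------------------------------------------------------------------
# elementary stages
# ---------------------------------------------------------------------------

def merge_binocular(left: np.ndarray, right: np.ndarray,
                    valid_left: np.ndarray, valid_right: np.ndarray,
                    ) -> np.ndarray:
    """Average the two eyes where both are valid; missing (NaN) otherwise."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    both = (np.asarray(valid_left, dtype=bool)
            & np.asarray(valid_right, dtype=bool)
            & np.isfinite(left) & np.isfinite(right))
    return np.where(both, (left + right) / 2.0, np.nan)


def filter_implausible(trace: np.ndarray, lo: float = PLAUSIBLE_MM[0],
                       hi: float = PLAUSIBLE_MM[1]) -> tuple[np.ndarray, int]:
    """Blank diameters outside the physiologically plausible [lo, hi] mm."""
    if lo >= hi:
        raise ConfigError("plausibility bounds require lo < hi")
    trace = np.asarray(trace, dtype=float).copy()
    bad = np.isfinite(trace) & ((trace < lo) | (trace > hi))
    trace[bad] = np.nan
    return trace, int(bad.sum())


def missing_fraction(trace: np.ndarray) -> float:
    trace = np.asarray(trace, dtype=float)
    return float(np.mean(~np.isfinite(trace)))


def interpolate_gaps(trace: np.ndarray) -> np.ndarray:
    """Linear interpolation of interior gaps; edge gaps take the nearest
    valid value."""
    trace = np.asarray(trace, dtype=float)
    ok = np.isfinite(trace)
    if not ok.any():
        raise DegenerateDataError("cannot interpolate an all-missing trace")
    if ok.all():
        return trace.copy()
    idx = np.arange(trace.size)
    return np.interp(idx, idx[ok], trace[ok])


def lowpass(trace: np.ndarray, fs: float, cutoff: float = LOWPASS_CUTOFF_HZ,
            order: int = LOWPASS_ORDER) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward); unit DC gain."""
    if cutoff >= fs / 2.0:
        raise ConfigError("lowpass cutoff must be below the Nyquist "
                          f"frequency {fs / 2.0:g} Hz")
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    return signal.filtfilt(b, a, np.asarray(trace, dtype=float))


def downsample_median(trace: np.ndarray, t_ms: np.ndarray,
                      bin_ms: float = BIN_MS) -> tuple[np.ndarray, np.ndarray]:
    """Median per half-open ``[k*bin_ms, (k+1)*bin_ms)`` bin.

    Returns ``(bin_start_ms, values)`` for the bins fully represented in the
    trace's time range.
    """
    if bin_ms <= 0:
        raise ConfigError("bin_ms must be positive")
    t_ms = np.asarray(t_ms, dtype=float)
    trace = np.asarray(trace, dtype=float)
    k = np.floor(t_ms / bin_ms).astype(int)
    n_bins = int(np.floor((t_ms[-1] + (t_ms[1] - t_ms[0])) / bin_ms + 1e-9))
    n_bins = max(n_bins, k.max() + 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = k == b
        if m.any():
            out[b] = np.median(trace[m])
    starts = np.arange(n_bins) * bin_ms
    return starts, out


def zscore_pooled(values: np.ndarray) -> tuple[float, float]:
    """Pooled mean and sample SD for the participant z-transform."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise DegenerateDataError("z-transform needs at least two values")
    sd = values.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDataError("z-transform undefined: zero variance")
    return float(values.mean()), float(sd)


# ---------------------------------------------------------------------------
# per-participant pipeline
# ---------------------------------------------------------------------------

@dataclass
class ParticipantEpochs:
    """Binned, z-scored, realigned image-epoch traces for one participant."""

    participant_id: str
    group: str
    bin_starts_ms: np.ndarray          # image-epoch bins, 0-based
    condition_means: dict[str, np.ndarray]
    difference: np.ndarray             # NRS - control per bin
    n_trials: dict[str, int]
    qc: QCReport


def _trial_traces(stream: RawSampleStream, baseline_ms: int,
                  ) -> tuple[list[tuple[int, str, np.ndarray, np.ndarray]],
                             int]:
    """Merged, plausibility-filtered trace per trial on a continuous
    baseline+image time axis (t=0 at image onset, baseline negative)."""
    out = []
    implausible_total = 0
    df = stream.samples
    for trial, tdf in df.groupby("trial", sort=True):
        cond = str(tdf["condition"].iloc[0])
        t = np.where(tdf["epoch"].to_numpy() == "baseline",
                     tdf["t_ms"].to_numpy(dtype=float) - baseline_ms,
                     tdf["t_ms"].to_numpy(dtype=float))
        order = np.argsort(t, kind="stable")
        t = t[order]
        merged = merge_binocular(tdf["pupil_l"].to_numpy()[order],
                                 tdf["pupil_r"].to_numpy()[order],
                                 tdf["valid_l"].to_numpy()[order],
                                 tdf["valid_r"].to_numpy()[order])
        merged, n_bad = filter_implausible(merged)
        implausible_total += n_bad
        out.append((int(trial), cond, t, merged))
    return out, implausible_total


def reject_trials(trials: list[tuple[int, str, np.ndarray, np.ndarray]],
                  max_missing: float = MAX_TRIAL_MISSING,
                  ) -> tuple[list, list[TrialQC]]:
    """Drop trials whose missing fraction strictly exceeds ``max_missing``."""
    kept, qc = [], []
    for trial, cond, t, trace in trials:
        frac = missing_fraction(trace)
        ok = frac <= max_missing
        qc.append(TrialQC(trial, cond, frac, ok))
        if ok:
            kept.append((trial, cond, t, trace))
    return kept, qc


def preprocess_participant(stream: RawSampleStream, baseline_ms: int = 1000,
                           image_ms: int = 3000,
                           sampling_rate: float = 600.0,
                           cutoff_hz: float = LOWPASS_CUTOFF_HZ,
                           filter_order: int = LOWPASS_ORDER,
                           ) -> ParticipantEpochs | None:
    """Run the full PV pipeline for one participant.

    Returns ``None`` when the participant fails the valid-trial rule
    (strictly fewer than half of the trials usable).  Raises
    :class:`~pupilbias.errors.PipelineError` if a kept participant has no
    usable trial in one condition.
    """
    if stream.task != "PV":
        raise PipelineError(f"{stream.participant_id}: expected a PV stream")
    trials, implausible = _trial_traces(stream, baseline_ms)
    kept, trial_qc = reject_trials(trials)
    qc = QCReport(stream.participant_id, trial_qc, implausible)
    if not qc.participant_kept:
        logger.info("participant %s rejected: %.1f%% valid trials",
                    stream.participant_id, 100 * qc.valid_trial_fraction)
        return None

    binned_by_trial = []
    for trial, cond, t, trace in kept:
        filled = interpolate_gaps(trace)
        smooth = lowpass(filled, fs=sampling_rate, cutoff=cutoff_hz,
                         order=filter_order)
        starts, vals = downsample_median(smooth, t - t[0])
        starts = starts + t[0]  # shift back so 0 = image onset
        binned_by_trial.append((trial, cond, starts, vals))

    mean, sd = zscore_pooled(np.concatenate(
        [vals for (_, _, _, vals) in binned_by_trial]))

    n_image_bins = image_ms // BIN_MS
    image_starts = np.arange(n_image_bins) * float(BIN_MS)
    per_cond: dict[str, list[np.ndarray]] = {}
    for trial, cond, starts, vals in binned_by_trial:
        z = (vals - mean) / sd
        img = z[starts >= -1e-9][:n_image_bins]
        img = img - img[0]  # realign to image onset
        per_cond.setdefault(cond, []).append(img)

    missing_conds = [c for c in ("NRS", "control") if not per_cond.get(c)]
    if missing_conds:
        raise PipelineError(
            f"participant {stream.participant_id} has no kept trials in "
            f"condition(s) {missing_conds}")

    cond_means = {c: np.mean(np.vstack(v), axis=0)
                  for c, v in per_cond.items()}
    return ParticipantEpochs(
        participant_id=stream.participant_id,
        group=stream.group,
        bin_starts_ms=image_starts,
        condition_means=cond_means,
        difference=cond_means["NRS"] - cond_means["control"],
        n_trials={c: len(v) for c, v in per_cond.items()},
        qc=qc,
    )


def preprocess_dataset(streams: list[RawSampleStream], baseline_ms: int = 1000,
                       image_ms: int = 3000, sampling_rate: float = 600.0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, list[QCReport]]:
    """Preprocess every PV stream and assemble the epoch matrix.

    Returns ``(epochs, differences, qc_reports)``: ``epochs`` in long form
    (participant, group, condition, bin, bin_start_ms, z), ``differences``
    wide (one row per kept participant, one column per image bin), and the
    per-participant QC reports (including rejected participants).
    """
    pv = [s for s in streams if s.task == "PV"]
    if not pv:
        raise PipelineError("no PV streams in input")
    rows, diff_rows, reports = [], [], []
    for stream in pv:
        res = preprocess_participant(stream, baseline_ms, image_ms,
                                     sampling_rate)
        if res is None:
            trials, implausible = _trial_traces(stream, baseline_ms)
            _, trial_qc = reject_trials(trials)
            reports.append(QCReport(stream.participant_id, trial_qc,
                                    implausible))
            continue
        reports.append(res.qc)
        for cond, vals in res.condition_means.items():
            for b, (start, z) in enumerate(zip(res.bin_starts_ms, vals)):
                rows.append((res.participant_id, res.group, cond, b,
                             float(start), float(z)))
        diff_rows.append([res.participant_id, res.group]
                         + list(res.difference))
    if not diff_rows:
        summary = {r.participant_id: round(r.valid_trial_fraction, 3)
                   for r in reports}
        raise PipelineError(
            f"all participants rejected by QC; valid-trial fractions: "
            f"{summary}")
    epochs = pd.DataFrame(rows, columns=["participant_id", "group",
                                         "condition", "bin", "bin_start_ms",
                                         "z"])
    n_bins = image_ms // BIN_MS
    differences = pd.DataFrame(
        diff_rows, columns=["participant_id", "group"]
        + [f"bin{b}" for b in range(n_bins)])
    return epochs, differences, reports
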