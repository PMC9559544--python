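"""Dot-probe attentional-bias measures from gaze and response data.

Three bias scores are computed per participant, each oriented so that
positive values index enhanced engagement with nicotine-related stimuli
(NRS):

* **RT bias** — mean correct RT to targets on the control side minus mean
  correct RT to targets on the NRS side (faster at NRS => positive).
* **Dwell-time bias** — per-trial cumulative fixation duration inside the
  NRS image region minus the control region, averaged over trials.
* **First-fixation bias** — proportion of trials whose first lateral-image
  fixation lands on NRS minus the proportion landing on control.

Fixations are reconstructed over the 1,500-ms cue window with a
velocity-based detector: gaze gaps are linearly interpolated on both axes,
angular velocity is smoothed with a 3-sample moving average, and runs of
sub-threshold samples lasting at least 40 ms become fixation events.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .pupilprep import interpolate_gaps
from .synthgen import (AOI_CENTER_X, AOI_HEIGHT_DEG, AOI_WIDTH_DEG,
                       RawSampleStream)

logger = logging.getLogger(__name__)

MIN_FIXATION_MS = 40.0
MIN_RT_MS = 100.0
VELOCITY_THRESHOLD_DEG_S = 30.0
VELOCITY_SMOOTH_SAMPLES = 3


@dataclass(frozen=True)
class FixationEvent:
    """A detected fixation inside one cue window."""

    onset_ms: float
    offset_ms: float
    centroid_x_deg: float
    centroid_y_deg: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class AOILayout:
    """Left/right lateral image regions (degrees of visual angle).

    Rectangles of ``width x height`` whose centers sit ``center_x`` degrees
    left/right of fixation; membership is decided by fixation centroid
    containment.
    """

    center_x: float = AOI_CENTER_X
    width: float = AOI_WIDTH_DEG
    height: float = AOI_HEIGHT_DEG

    def __post_init__(self) -> None:
        if self.center_x - self.width / 2.0 < 0:
            raise ConfigError("AOILayout regions overlap the midline: "
                              "center_x must exceed width / 2")

    def side_of(self, x: float, y: float) -> str | None:
        """'left', 'right', or None for a point outside both regions."""
        if abs(y) > self.height / 2.0:
            return None
        if abs(x - self.center_x) <= self.width / 2.0:
            return "right"
        if abs(x + self.center_x) <= self.width / 2.0:
            return "left"
        return None


def filter_responses(trials: pd.DataFrame,
                     min_rt: float = MIN_RT_MS) -> pd.DataFrame:
    """Drop practice trials and anticipations (RT strictly below ``min_rt``).

    Correctness is not filtered here; RT means downstream use correct
    responses only.
    """
    out = trials.loc[~trials["practice"].astype(bool)]
    rt = out["rt_ms"].astype(float)
    return out.loc[rt.isna() | (rt >= min_rt)].copy()


def detect_fixations(t_ms: np.ndarray, x: np.ndarray, y: np.ndarray,
                     min_duration: float = MIN_FIXATION_MS,
                     velocity_threshold: float = VELOCITY_THRESHOLD_DEG_S,
                     smooth_samples: int = VELOCITY_SMOOTH_SAMPLES,
                     ) -> list[FixationEvent]:
    """Velocity-based fixation detection on one cue window.

    Gaps in x/y are linearly interpolated (edges extended); the point-to-
    point angular speed is assigned to the trailing sample, smoothed with a
    centered ``smooth_samples`` moving average, and samples below
    ``velocity_threshold`` deg/s are grouped into runs.  Runs spanning at
    least ``min_duration`` ms become fixations with centroid = mean position.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t_ms.size < 2:
        return []
    if not np.isfinite(x).any() or not np.isfinite(y).any():
        warnings.warn("cue window fully missing; no fixations detected")
        return []
    x = interpolate_gaps(x)
    y = interpolate_gaps(y)
    vel = sample_velocities(t_ms, x, y, smooth_samples)
    slow = vel < velocity_threshold
    events: list[FixationEvent] = []
    i = 0
    n = t_ms.size
    dt = float(np.median(np.diff(t_ms)))
    while i < n:
        if slow[i]:
            j = i
            while j + 1 < n and slow[j + 1]:
                j += 1
            duration = t_ms[j] - t_ms[i] + dt
            if duration >= min_duration:
                events.append(FixationEvent(
                    onset_ms=float(t_ms[i]),
                    offset_ms=float(t_ms[j] + dt),
                    centroid_x_deg=float(x[i:j + 1].mean()),
                    centroid_y_deg=float(y[i:j + 1].mean())))
            i = j + 1
        else:
            i += 1
    return events


def sample_velocities(t_ms: np.ndarray, x: np.ndarray, y: np.ndarray,
                      smooth_samples: int = VELOCITY_SMOOTH_SAMPLES,
                      ) -> np.ndarray:
    """Smoothed angular speed (deg/s) per sample.

    The speed over ``(i-1, i]`` is assigned to sample ``i``; sample 0 copies
    sample 1.  A centered moving average of ``smooth_samples`` (edge-truncated)
    is then applied.
    """
    dt_s = np.diff(t_ms) / 1000.0
    speed = np.hypot(np.diff(x), np.diff(y)) / dt_s
    speed = np.concatenate([[speed[0]], speed])
    if smooth_samples <= 1:
        return speed
    kernel = np.ones(smooth_samples)
    smoothed = (np.convolve(speed, kernel, mode="same")
                / np.convolve(np.ones_like(speed), kernel, mode="same"))
    return smoothed


# ---------------------------------------------------------------------------
# bias scores
# ---------------------------------------------------------------------------

def _aoi_condition(fix: FixationEvent, layout: AOILayout,
                   nrs_side: str) -> str | None:
    side = layout.side_of(fix.centroid_x_deg, fix.centroid_y_deg)
    if side is None:
        return None
    return "NRS" if side == nrs_side else "control"


def first_fixation_bias(fixations_per_trial: list[list[FixationEvent]],
                        nrs_sides: list[str],
                        layout: AOILayout | None = None) -> float:
    """P(first AOI fixation on NRS) - P(first AOI fixation on control).

    Fixations outside both regions (e.g. on the central cross) are skipped
    until the first AOI hit; trials with no AOI fixation do not enter either
    proportion.  Returns NaN (logged) when no trial has an AOI fixation.
    """
    layout = layout or AOILayout()
    n_nrs = n_ctrl = 0
    for fixes, nrs_side in zip(fixations_per_trial, nrs_sides):
        for fix in fixes:
            cond = _aoi_condition(fix, layout, nrs_side)
            if cond == "NRS":
                n_nrs += 1
                break
            if cond == "control":
                n_ctrl += 1
                break
    total = n_nrs + n_ctrl
    if total == 0:
        logger.warning("no AOI fixations in any trial; first-fixation bias "
                       "undefined")
        return float("nan")
    return (n_nrs - n_ctrl) / total


def dwell_time_bias(fixations_per_trial: list[list[FixationEvent]],
                    nrs_sides: list[str],
                    layout: AOILayout | None = None) -> float:
    """Mean over trials of (NRS dwell - control dwell), in ms.

    Dwell is the cumulative duration of fixations whose centroid falls in
    the region.
    """
    layout = layout or AOILayout()
    diffs = []
    for fixes, nrs_side in zip(fixations_per_trial, nrs_sides):
        dwell = {"NRS": 0.0, "control": 0.0}
        for fix in fixes:
            cond = _aoi_condition(fix, layout, nrs_side)
            if cond is not None:
                dwell[cond] += fix.duration_ms
        diffs.append(dwell["NRS"] - dwell["control"])
    return float(np.mean(diffs)) if diffs else float("nan")


def rt_bias(trials: pd.DataFrame) -> float:
    """Mean correct RT on control-side targets minus NRS-side targets (ms).

    Positive values mean faster responses when the target appears at the
    NRS location, i.e. attentional engagement with NRS.  Returns NaN
    (logged) if either condition lacks correct responses.
    """
    ok = trials.loc[trials["correct"].astype(bool)
                    & trials["rt_ms"].notna()]
    means = ok.groupby("target_on")["rt_ms"].mean()
    if "NRS" not in means or "control" not in means:
        logger.warning("rt_bias: a condition has no correct responses")
        return float("nan")
    return float(means["control"] - means["NRS"])


# ---------------------------------------------------------------------------
# per-participant feature assembly
# ---------------------------------------------------------------------------

def dpt_fixations(stream: RawSampleStream, trials: pd.DataFrame,
                  velocity_threshold: float = VELOCITY_THRESHOLD_DEG_S,
                  ) -> tuple[list[list[FixationEvent]], list[str]]:
    """Detect fixations for each experimental DPT trial of one participant.

    ``trials`` must carry the participant's DPT rows with the per-trial
    ``nrs_side`` mapping.
    """
    side_map = (trials.loc[(trials["task"] == "DPT")
                           & ~trials["practice"].astype(bool)]
                .set_index("trial")["nrs_side"].to_dict())
    fixations, sides = [], []
    for trial, tdf in stream.samples.groupby("trial", sort=True):
        if trial not in side_map:
            continue
        fixes = detect_fixations(tdf["t_ms"].to_numpy(dtype=float),
                                 tdf["gaze_x"].to_numpy(dtype=float),
                                 tdf["gaze_y"].to_numpy(dtype=float),
                                 velocity_threshold=velocity_threshold)
        fixations.append(fixes)
        sides.append(str(side_map[trial]))
    return fixations, sides


def compute_bias_features(streams: list[RawSampleStream],
                          trials: pd.DataFrame,
                          pupil_bias: dict[str, float] | None = None,
                          layout: AOILayout | None = None) -> pd.DataFrame:
    """One row of bias scores per participant (the classifier's input).

    Columns: ``rt_bias_dpt_ms``, ``dwell_bias_ms``, ``first_fix_bias``,
    ``rt_bias_pv_ms``, optionally ``pupil_bias_z`` (cluster-window mean of
    the participant's NRS-control pupil difference curve, supplied via
    ``pupil_bias``), and ``group``.
    """
    layout = layout or AOILayout()
    clean = filter_responses(trials)
    rows = []
    for stream in streams:
        if stream.task != "DPT":
            continue
        pid = stream.participant_id
        mine = clean.loc[clean["participant_id"] == pid]
        fixes, sides = dpt_fixations(stream, mine)
        row = {
            "participant_id": pid,
            "group": stream.group,
            "rt_bias_dpt_ms": rt_bias(mine.loc[mine["task"] == "DPT"]),
            "dwell_bias_ms": dwell_time_bias(fixes, sides, layout),
            "first_fix_bias": first_fixation_bias(fixes, sides, layout),
            "rt_bias_pv_ms": rt_bias(mine.loc[mine["task"] == "PV"]),
        }
        if pupil_bias is not None:
            row["pupil_bias_z"] = pupil_bias.get(pid, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
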