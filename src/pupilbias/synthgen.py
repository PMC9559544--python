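"""Synthetic two-task eye-tracking data with a known group structure.

This module is the package's ground-truth factory.  It generates, for two
groups of participants (smokers and non-smokers), the raw data the analysis
pipeline consumes:

* **Passive viewing (PV)** sample streams: binocular pupil diameter at 600 Hz
  over a 1-s scrambled-image baseline plus a 3-s image epoch per trial.  All
  trials share a saturating anticipatory dilation ramp; each participant
  carries a latent NRS-minus-control pupil offset drawn from their group's
  effect distribution and applied inside the configured effect window.
* **Dot-probe (DPT)** sample streams: a gaze path over the 1,500-ms cue
  window built from a simulated fixation sequence visiting the two lateral
  image regions.
* **Trial response tables**: lognormal RTs and accuracy flags per trial,
  with practice trials flagged.
* **Stimulus-image utilities**: luminance normalisation to a common
  mean/SD and pixel-shuffling scrambles.

Two tiers are provided.  :func:`generate_dataset` emits full raw sample
streams and exercises every preprocessing rule downstream.
:func:`simulate_difference_curves` emits participant-level NRS-minus-control
pupil curves directly on the 25-ms bin grid the pipeline would produce; it is
the tier used for large simulation studies (permutation-test calibration,
classifier recovery), where regenerating 600-Hz raw streams adds nothing but
runtime.  Both tiers draw participant effects from the same distributions.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GROUPS, SimConfig
from .errors import ConfigError, DegenerateDataError

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = [
    "trial", "condition", "epoch", "t_ms",
    "pupil_l", "pupil_r", "valid_l", "valid_r", "gaze_x", "gaze_y",
]


@dataclass
class RawSampleStream:
    """Per-sample eye-tracker records for one participant and one task.

    ``samples`` holds one row per sample with columns ``trial`` (0-based
    experimental trial index), ``condition`` (``NRS``/``control``), ``epoch``
    (``baseline``/``image`` for PV, ``cue`` for DPT), ``t_ms`` (time since
    epoch onset), binocular pupil diameters in mm, validity flags, and gaze
    position in degrees of visual angle.
    """

    participant_id: str
    group: str
    task: str
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")


# ---------------------------------------------------------------------------
# low-level noise helpers
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, phi: float, sd: float,
         shape: tuple[int, int]) -> np.ndarray:
    """Stationary AR(1) rows with marginal SD ``sd`` and coefficient ``phi``."""
    n_series, n_steps = shape
    if sd == 0.0 or n_steps == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    x = np.empty(shape)
    x[:, 0] = rng.normal(0.0, sd, size=n_series)
    eps = rng.normal(0.0, innov_sd, size=(n_series, n_steps - 1))
    for t in range(1, n_steps):
        x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
    return x


def _lognormal_ms(rng: np.random.Generator, mean_ms: float, sd_ms: float,
                  size: int) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and SD."""
    if sd_ms == 0:
        return np.full(size, float(mean_ms))
    sigma2 = np.log1p((sd_ms / mean_ms) ** 2)
    mu = np.log(mean_ms) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _balanced_conditions(rng: np.random.Generator, n: int) -> np.ndarray:
    cond = np.array(["NRS", "control"]).repeat([n - n // 2, n // 2])
    rng.shuffle(cond)
    return cond


def _participant_rng(config: SimConfig, participant_id: str,
                     salt: int = 0) -> np.random.Generator:
    crc = zlib.crc32(participant_id.encode())
    return np.random.default_rng([config.seed, crc, salt])


# ---------------------------------------------------------------------------
# passive viewing
# ---------------------------------------------------------------------------

def _pv_samples(config: SimConfig, rng: np.random.Generator, group: str,
                delta: float) -> pd.DataFrame:
    """Raw PV sample table for one participant with latent effect ``delta``.

    The latent z-scale signal is standardised against its own realised
    pooled (binned) mean/SD before the NRS-minus-control offset is added, so
    the downstream per-participant z-transform recovers ``delta`` in z units.
    """
    nt = config.pv_trials
    dt = config.sample_dt_ms
    n_bl, n_im = config.n_baseline_samples, config.n_image_samples
    nb_bl, nb_im = config.n_baseline_bins, config.n_image_bins
    spb = max(int(round(25.0 / dt)), 1)  # samples per 25-ms bin

    noise_bins = _ar1(rng, config.noise_ar1_phi, config.noise_sd,
                      (nt, nb_bl + nb_im))
    t_im = (np.arange(n_im) + 0.5) * dt
    ramp = config.ramp_amplitude * (1.0 - np.exp(-t_im / config.ramp_tau_ms))
    # binned view of the latent signal, mirroring the pipeline's median bins
    usable = nb_im * spb
    ramp_bins = np.median(ramp[:usable].reshape(nb_im, spb), axis=1)
    binned = noise_bins.copy()
    binned[:, nb_bl:] += ramp_bins
    m, s = binned.mean(), binned.std(ddof=1)
    if s == 0.0:
        m, s = 0.0, 1.0  # null configuration: leave the flat signal alone

    sig = np.repeat(noise_bins, spb, axis=1)[:, : n_bl + n_im]
    sig[:, n_bl:] += ramp
    z = (sig - m) / s

    cond = _balanced_conditions(rng, nt)
    lo, hi = config.effect_window_ms
    win = (t_im >= lo) & (t_im < hi)
    z[np.ix_(cond == "NRS", n_bl + np.nonzero(win)[0])] += delta

    base = config.pupil_base_mm[group] + rng.normal(0.0, 0.2)
    mm = base + config.pupil_scale_mm * z

    n_per_trial = n_bl + n_im
    # instrument noise only when the trial-noise model is active, so a null
    # configuration yields exactly identical NRS/control traces
    eye_sd = 0.01 if config.noise_sd > 0 else 0.0
    t_ms = np.concatenate([np.arange(n_bl) * dt, np.arange(n_im) * dt])
    df = pd.DataFrame({
        "trial": np.repeat(np.arange(nt), n_per_trial),
        "condition": np.repeat(cond, n_per_trial),
        "epoch": np.tile(np.array(["baseline"] * n_bl + ["image"] * n_im),
                         nt),
        "t_ms": np.tile(np.round(t_ms, 4), nt),
        "pupil_l": mm.ravel() + rng.normal(0.0, eye_sd, mm.size),
        "pupil_r": mm.ravel() + rng.normal(0.0, eye_sd, mm.size),
        "valid_l": True,
        "valid_r": True,
        "gaze_x": rng.normal(0.0, 0.15, mm.size),
        "gaze_y": rng.normal(0.0, 0.15, mm.size),
    })
    return df


def _pv_trial_rows(config: SimConfig, rng: np.random.Generator, group: str,
                   pid: str, cond: np.ndarray) -> list[dict]:
    rows = []
    # practice trials: flagged, negative indices, never analysed
    for k in range(8):
        rows.append(dict(participant_id=pid, task="PV", trial=-(8 - k),
                         target_on="control" if k % 2 else "NRS",
                         rt_ms=float(_lognormal_ms(rng, 430.0, 90.0, 1)[0]),
                         correct=True, practice=True, nrs_side="center"))
    n_probe = int(round(config.probe_fraction * config.pv_trials))
    probe_trials = np.sort(rng.choice(config.pv_trials, n_probe,
                                      replace=False))
    for tr in probe_trials:
        c = cond[tr]
        mean_ms, sd_ms = config.rt_params[group]["PV"][c]
        rows.append(dict(participant_id=pid, task="PV", trial=int(tr),
                         target_on=c,
                         rt_ms=float(_lognormal_ms(rng, mean_ms, sd_ms, 1)[0]),
                         correct=bool(rng.random() < config.accuracy),
                         practice=False, nrs_side="center"))
    return rows


# ---------------------------------------------------------------------------
# dot-probe task
# ---------------------------------------------------------------------------

#: Lateral image geometry (degrees): 6 x 4.5 images whose inner edge sits 2
#: degrees from fixation.
AOI_INNER_DEG = 2.0
AOI_WIDTH_DEG = 6.0
AOI_HEIGHT_DEG = 4.5
AOI_CENTER_X = AOI_INNER_DEG + AOI_WIDTH_DEG / 2.0  # 5 degrees


def _dpt_fixation_sequence(config: SimConfig, rng: np.random.Generator,
                           group: str, nrs_side: str) -> list[tuple]:
    """(start_ms, end_ms, x, y) fixation events inside one cue window."""
    events = []
    t = 0.0
    # initial central fixation
    central = rng.uniform(200.0, 400.0)
    events.append((t, t + central, 0.0, 0.0))
    t += central + 30.0  # saccade
    p_nrs = config.first_fix_p_nrs[group]
    side = nrs_side if rng.random() < p_nrs else ("left" if nrs_side == "right"
                                                  else "right")
    while t < config.cue_ms - 60.0:
        cond = "NRS" if side == nrs_side else "control"
        dur = max(rng.normal(config.dwell_ms[group][cond], 120.0), 80.0)
        end = min(t + dur, config.cue_ms)
        x = AOI_CENTER_X if side == "right" else -AOI_CENTER_X
        events.append((t, end, x, 0.0))
        t = end + 30.0
        side = "left" if side == "right" else "right"
    return events


def _render_gaze(events: list[tuple], n_samples: int,
                 dt: float, rng: np.random.Generator) -> tuple[np.ndarray,
                                                               np.ndarray]:
    """Sample a gaze path from fixation events; saccades are linear ramps."""
    t = np.arange(n_samples) * dt
    x = np.empty(n_samples)
    y = np.empty(n_samples)
    # anchor points: fixation centroids held over [start, end]
    anchor_t, anchor_x, anchor_y = [], [], []
    for (s, e, ex, ey) in events:
        anchor_t += [s, e]
        anchor_x += [ex, ex]
        anchor_y += [ey, ey]
    x[:] = np.interp(t, anchor_t, anchor_x)
    y[:] = np.interp(t, anchor_t, anchor_y)
    x += rng.normal(0.0, 0.005, n_samples)
    y += rng.normal(0.0, 0.005, n_samples)
    return x, y


def _dpt_samples(config: SimConfig, rng: np.random.Generator, group: str,
                 nrs_sides: np.ndarray) -> pd.DataFrame:
    nt = config.dpt_trials
    dt = config.sample_dt_ms
    n_cue = config.n_cue_samples
    frames = []
    base = config.pupil_base_mm[group]
    for tr in range(nt):
        events = _dpt_fixation_sequence(config, rng, group, nrs_sides[tr])
        gx, gy = _render_gaze(events, n_cue, dt, rng)
        mm = base + rng.normal(0.0, 0.05)
        frames.append(pd.DataFrame({
            "trial": tr,
            "condition": "NRS",   # both image classes on screen; side mapping
            "epoch": "cue",       # carried separately via the trial table
            "t_ms": np.round(np.arange(n_cue) * dt, 4),
            "pupil_l": mm + rng.normal(0.0, 0.02, n_cue),
            "pupil_r": mm + rng.normal(0.0, 0.02, n_cue),
            "valid_l": True,
            "valid_r": True,
            "gaze_x": gx,
            "gaze_y": gy,
        }))
    return pd.concat(frames, ignore_index=True)


def _dpt_trial_rows(config: SimConfig, rng: np.random.Generator, group: str,
                    pid: str) -> tuple[list[dict], np.ndarray]:
    rows = []
    for k in range(12):
        rows.append(dict(participant_id=pid, task="DPT", trial=-(12 - k),
                         target_on="control" if k % 2 else "NRS",
                         rt_ms=float(_lognormal_ms(rng, 560.0, 90.0, 1)[0]),
                         correct=True, practice=True,
                         nrs_side="left" if k % 2 else "right"))
    nt = config.dpt_trials
    nrs_sides = np.array(["left", "right"]).repeat([nt - nt // 2, nt // 2])
    rng.shuffle(nrs_sides)
    target_on = _balanced_conditions(rng, nt)
    for tr in range(nt):
        c = target_on[tr]
        mean_ms, sd_ms = config.rt_params[group]["DPT"][c]
        rows.append(dict(participant_id=pid, task="DPT", trial=tr,
                         target_on=c,
                         rt_ms=float(_lognormal_ms(rng, mean_ms, sd_ms, 1)[0]),
                         correct=bool(rng.random() < config.accuracy),
                         practice=False, nrs_side=str(nrs_sides[tr])))
    return rows, nrs_sides


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_dataset(config: SimConfig) -> tuple[list[RawSampleStream],
                                                 pd.DataFrame,
                                                 pd.DataFrame]:
    """Generate the full synthetic study: streams, trial table, truth table.

    Returns ``(streams, trials, participants)`` where ``streams`` holds one
    PV and one DPT :class:`RawSampleStream` per participant (missingness
    already injected at the configured rates), ``trials`` is the pooled
    trial-response table, and ``participants`` records each participant's
    group and latent pupil effect.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    streams: list[RawSampleStream] = []
    trial_rows: list[dict] = []
    truth_rows: list[dict] = []
    master = np.random.default_rng(config.seed)
    for group in GROUPS:
        mean, sd = config.group_effect(group)
        for k in range(config.n_per_group):
            pid = f"{'S' if group == 'smoker' else 'N'}{k + 1:03d}"
            delta = float(master.normal(mean, sd))
            truth_rows.append(dict(participant_id=pid, group=group,
                                   latent_effect_z=delta))
            rng = _participant_rng(config, pid)
            pv = _pv_samples(config, rng, group, delta)
            cond = pv.loc[~pv["trial"].duplicated(), "condition"].to_numpy()
            trial_rows += _pv_trial_rows(config, rng, group, pid, cond)
            dpt_rows, nrs_sides = _dpt_trial_rows(config, rng, group, pid)
            trial_rows += dpt_rows
            dpt = _dpt_samples(config, rng, group, nrs_sides)
            pv_stream = RawSampleStream(pid, group, "PV", pv)
            dpt_stream = RawSampleStream(pid, group, "DPT", dpt)
            mrng = _participant_rng(config, pid, salt=1)
            streams.append(inject_missingness(pv_stream, config, rng=mrng))
            streams.append(inject_missingness(dpt_stream, config, rng=mrng))
    trials = pd.DataFrame(trial_rows)
    # attach the NRS side mapping for DPT feature extraction
    return streams, trials, pd.DataFrame(truth_rows)


def inject_missingness(stream: RawSampleStream, config: SimConfig,
                       rng: np.random.Generator | None = None,
                       ) -> RawSampleStream:
    """Insert blink gaps, single-eye dropouts, and implausible pupil values.

    Blinks arrive as a Bernoulli process at ``blink_rate`` events/s with
    geometric gap lengths (mean ``blink_ms_mean``) and invalidate both eyes;
    artifacts invalidate one random eye per hit sample; implausible values
    replace one eye's diameter with an out-of-range (<2 or >7 mm) value while
    leaving validity flags untouched, as a tracker would.
    """
    if config.blink_rate < 0:
        raise ConfigError("blink_rate must be non-negative")
    for name in ("artifact_rate", "implausible_rate"):
        if not 0.0 <= getattr(config, name) <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1]")
    if rng is None:
        rng = _participant_rng(config, stream.participant_id, salt=1)
    df = stream.samples.copy()
    n = len(df)
    dt = config.sample_dt_ms
    pupil_l = df["pupil_l"].to_numpy(dtype=float).copy()
    pupil_r = df["pupil_r"].to_numpy(dtype=float).copy()
    valid_l = df["valid_l"].to_numpy(dtype=bool).copy()
    valid_r = df["valid_r"].to_numpy(dtype=bool).copy()
    gaze_x = df["gaze_x"].to_numpy(dtype=float).copy()
    gaze_y = df["gaze_y"].to_numpy(dtype=float).copy()

    if config.blink_rate > 0:
        p_start = config.blink_rate * dt / 1000.0
        starts = np.nonzero(rng.random(n) < p_start)[0]
        mean_len = max(config.blink_ms_mean / dt, 1.0)
        lengths = rng.geometric(1.0 / mean_len, size=starts.size)
        blink = np.zeros(n, dtype=bool)
        for s, L in zip(starts, lengths):
            blink[s:s + L] = True
        valid_l[blink] = valid_r[blink] = False
        pupil_l[blink] = pupil_r[blink] = np.nan
        gaze_x[blink] = gaze_y[blink] = np.nan

    if config.artifact_rate > 0:
        hit = rng.random(n) < config.artifact_rate
        left_eye = rng.random(n) < 0.5
        ml, mr = hit & left_eye, hit & ~left_eye
        valid_l[ml] = False
        pupil_l[ml] = np.nan
        valid_r[mr] = False
        pupil_r[mr] = np.nan

    if config.implausible_rate > 0:
        hit = (rng.random(n) < config.implausible_rate) & valid_l & valid_r
        low = rng.random(n) < 0.5
        vals = np.where(low, rng.uniform(0.5, 1.9, n),
                        rng.uniform(7.05, 9.0, n))
        left_eye = rng.random(n) < 0.5
        pupil_l[hit & left_eye] = vals[hit & left_eye]
        pupil_r[hit & ~left_eye] = vals[hit & ~left_eye]

    df["pupil_l"], df["pupil_r"] = pupil_l, pupil_r
    df["valid_l"], df["valid_r"] = valid_l, valid_r
    df["gaze_x"], df["gaze_y"] = gaze_x, gaze_y
    return RawSampleStream(stream.participant_id, stream.group, stream.task,
                           df)


def simulate_difference_curves(config: SimConfig,
                               rng: np.random.Generator | None = None,
                               ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Participant-level NRS-minus-control pupil curves on the 25-ms grid.

    Each participant's curve is their latent group-drawn effect over the
    effect-window bins plus realigned AR(1) residual noise (pinned to 0 at
    the first image bin, mirroring the pipeline's first-sample subtraction).
    Returns ``(curves, groups, participant_ids)`` with ``curves`` of shape
    ``(2 * n_per_group, image_ms / 25)``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nb = config.n_image_bins
    lo_bin, hi_bin = config.effect_window_bins()
    curves, groups, ids = [], [], []
    for group in GROUPS:
        mean, sd = config.group_effect(group)
        deltas = rng.normal(mean, sd, size=config.n_per_group)
        noise = _ar1(rng, config.noise_ar1_phi, config.curve_noise_sd,
                     (config.n_per_group, nb))
        noise = noise - noise[:, :1]  # realignment pins bin 0 at zero
        block = noise
        block[:, lo_bin:hi_bin] += deltas[:, None]
        curves.append(block)
        groups += [group] * config.n_per_group
        ids += [f"{'S' if group == 'smoker' else 'N'}{k + 1:03d}"
                for k in range(config.n_per_group)]
    return np.vstack(curves), np.array(groups), ids


# ---------------------------------------------------------------------------
# stimulus images
# ---------------------------------------------------------------------------

def normalize_image_luminance(img: np.ndarray, target_mean: float = 0.4,
                              target_sd: float = 0.15) -> np.ndarray:
    """Map a grayscale image to a common luminance distribution.

    The image is z-transformed and rescaled to ``target_mean``/``target_sd``;
    values pushed outside [0, 1] are clipped afterwards and the clipped
    fraction is logged.  A constant image has no z-transform and raises
    :class:`~pupilbias.errors.DegenerateDataError`.
    """
    img = np.asarray(img, dtype=float)
    sd = img.std()
    if sd == 0.0:
        raise DegenerateDataError("constant image: zero intensity variance")
    out = target_mean + target_sd * (img - img.mean()) / sd
    clipped = float(np.mean((out < 0.0) | (out > 1.0)))
    if clipped:
        logger.info("luminance normalisation clipped %.4f of pixels", clipped)
    return np.clip(out, 0.0, 1.0)


def scramble_image(img: np.ndarray, seed: int) -> np.ndarray:
    """Pixel-shuffled scramble: a seeded random permutation of all pixels."""
    img = np.asarray(img, dtype=float)
    rng = np.random.default_rng(seed)
    flat = img.ravel().copy()
    rng.shuffle(flat)
    return flat.reshape(img.shape)
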