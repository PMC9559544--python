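"""Simulation configuration for the two-task eye-tracking study design.

A :class:`SimConfig` captures the design constants of the study the package
models: a dot-probe task (DPT; 240 trials, 1,500-ms cue window) followed by a
passive-viewing task (PV; 200 trials, 1-s scrambled baseline + 3-s image, 30%
probe trials), recorded binocularly at 600 Hz.  The group-level pupil effect is
parameterised as the mean/SD (in within-participant z units) of each group's
NRS-minus-control pupil response inside the effect window.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Any

from .errors import ConfigError

#: Per-group / per-task / per-condition RT calibration (mean_ms, sd_ms) for the
#: lognormal RT generator.  Values follow the descriptive statistics of the
#: study population the generator emulates.
DEFAULT_RT_PARAMS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "smoker": {
        "DPT": {"NRS": (538.0, 87.0), "control": (547.0, 88.0)},
        "PV": {"NRS": (448.0, 105.0), "control": (448.0, 106.0)},
    },
    "nonsmoker": {
        "DPT": {"NRS": (537.0, 71.0), "control": (540.0, 69.0)},
        "PV": {"NRS": (420.0, 70.0), "control": (416.0, 68.0)},
    },
}

#: Probability that the first lateral fixation in a DPT trial lands on the
#: nicotine-related image, per group.
DEFAULT_FIRST_FIX_P_NRS: dict[str, float] = {"smoker": 0.50, "nonsmoker": 0.49}

#: Mean dwell calibration (ms per trial spent on NRS vs control images).
DEFAULT_DWELL_MS: dict[str, dict[str, float]] = {
    "smoker": {"NRS": 513.0, "control": 502.0},
    "nonsmoker": {"NRS": 468.0, "control": 463.0},
}

GROUPS = ("smoker", "nonsmoker")


@dataclass
class SimConfig:
    """Parameters of the synthetic two-task dataset.

    Durations are in milliseconds, pupil effects in within-participant z
    units, rates as stated per field.  Defaults encode the study design the
    generator emulates; ``validate`` (called on construction) raises
    :class:`~pupilbias.errors.ConfigError` naming the first invalid field.
    """

    n_per_group: int = 20
    sampling_rate: float = 600.0          # Hz
    pv_trials: int = 200
    probe_fraction: float = 0.30
    dpt_trials: int = 240
    baseline_ms: int = 1000
    image_ms: int = 3000
    cue_ms: int = 1500
    effect_window_ms: tuple[int, int] = (800, 2850)
    smoker_effect_mean: float = -0.025    # z
    smoker_effect_sd: float = 0.075       # z
    nonsmoker_effect_mean: float = 0.036  # z
    nonsmoker_effect_sd: float = 0.067    # z
    ramp_amplitude: float = 1.0           # z; shared anticipatory dilation
    ramp_tau_ms: float = 1000.0           # saturating-exponential time constant
    noise_ar1_phi: float = 0.95           # AR(1) coefficient at 25-ms bin scale
    noise_sd: float = 0.15                # marginal SD of bin-scale AR(1), z
    curve_noise_sd: float = 0.03          # residual SD of difference curves, z
    blink_rate: float = 0.10              # blink events per second
    blink_ms_mean: float = 100.0          # mean geometric blink-gap length
    artifact_rate: float = 0.005          # per-sample single-eye dropout prob.
    implausible_rate: float = 0.0         # per-sample out-of-range pupil prob.
    accuracy: float = 0.984               # per-trial correct-response prob.
    pupil_base_mm: dict[str, float] = field(
        default_factory=lambda: {"smoker": 4.7, "nonsmoker": 4.56}
    )
    pupil_scale_mm: float = 0.35          # mm per latent z unit
    rt_params: dict[str, dict[str, dict[str, tuple[float, float]]]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_RT_PARAMS)
    )
    first_fix_p_nrs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIRST_FIX_P_NRS)
    )
    dwell_ms: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_DWELL_MS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_window_ms = tuple(self.effect_window_ms)  # type: ignore[assignment]
        self.rt_params = {
            g: {t: {c: tuple(v) for c, v in conds.items()}
                for t, conds in tasks.items()}
            for g, tasks in self.rt_params.items()}
        self.validate()

    def validate(self) -> None:
        for name in ("n_per_group", "pv_trials", "dpt_trials", "baseline_ms",
                     "image_ms", "cue_ms"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if not 0.0 <= self.probe_fraction <= 1.0:
            raise ConfigError("probe_fraction must lie in [0, 1]")
        lo, hi = self.effect_window_ms
        if not (0 <= lo < hi <= self.image_ms):
            raise ConfigError(
                "effect_window_ms must be a [start, end) interval inside "
                f"[0, image_ms={self.image_ms})"
            )
        if not 0.0 <= self.noise_ar1_phi < 1.0:
            raise ConfigError("noise_ar1_phi must lie in [0, 1)")
        for name in ("smoker_effect_sd", "nonsmoker_effect_sd", "noise_sd",
                     "curve_noise_sd", "blink_rate", "blink_ms_mean"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("artifact_rate", "implausible_rate", "accuracy"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.pupil_scale_mm <= 0:
            raise ConfigError("pupil_scale_mm must be positive")

    # -- derived sizes -----------------------------------------------------
    @property
    def sample_dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def n_baseline_samples(self) -> int:
        return int(round(self.baseline_ms * self.sampling_rate / 1000.0))

    @property
    def n_image_samples(self) -> int:
        return int(round(self.image_ms * self.sampling_rate / 1000.0))

    @property
    def n_cue_samples(self) -> int:
        return int(round(self.cue_ms * self.sampling_rate / 1000.0))

    @property
    def n_image_bins(self) -> int:
        return self.image_ms // 25

    @property
    def n_baseline_bins(self) -> int:
        return self.baseline_ms // 25

    def effect_window_bins(self, bin_ms: int = 25) -> tuple[int, int]:
        """Half-open bin-index interval covered by the effect window."""
        lo, hi = self.effect_window_ms
        return lo // bin_ms, -(-hi // bin_ms)

    def group_effect(self, group: str) -> tuple[float, float]:
        if group == "smoker":
            return self.smoker_effect_mean, self.smoker_effect_sd
        if group == "nonsmoker":
            return self.nonsmoker_effect_mean, self.nonsmoker_effect_sd
        raise ConfigError(f"unknown group {group!r}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["effect_window_ms"] = list(self.effect_window_ms)
        d["rt_params"] = {
            g: {t: {c: list(v) for c, v in conds.items()}
                for t, conds in tasks.items()}
            for g, tasks in self.rt_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)
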