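"""Tabular readers/writers, run manifests, and the end-to-end pipeline.

File conventions: tab-separated UTF-8 with a mandatory header row, "." as
the decimal mark, and missing values encoded as empty fields.  Sample files
carry exactly the generator's column contract (extra columns are preserved
on read but ignored); trial files likewise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import GROUPS, SimConfig
from .errors import FormatError, PipelineError
from .synthgen import RawSampleStream

logger = logging.getLogger(__name__)

SAMPLE_FILE_COLUMNS = [
    "participant_id", "group", "task", "trial", "condition", "epoch", "t_ms",
    "pupil_l", "pupil_r", "valid_l", "valid_r", "gaze_x", "gaze_y",
]
TRIAL_FILE_COLUMNS = [
    "participant_id", "task", "trial", "target_on", "rt_ms", "correct",
    "practice",
]


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

def write_samples(streams: list[RawSampleStream], path: str | Path) -> None:
    frames = []
    for s in streams:
        df = s.samples.copy()
        df.insert(0, "participant_id", s.participant_id)
        df.insert(1, "group", s.group)
        df.insert(2, "task", s.task)
        df["valid_l"] = df["valid_l"].astype(int)
        df["valid_r"] = df["valid_r"].astype(int)
        frames.append(df[SAMPLE_FILE_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                na_rep="")


def read_samples(path: str | Path) -> list[RawSampleStream]:
    """Read a sample TSV back into typed per-participant/task streams.

    Raises :class:`~pupilbias.errors.FormatError` for a missing required
    column or non-monotone timestamps within a trial epoch (reported with
    the offending 1-based data line).
    """
    df = pd.read_csv(path, sep="\t")
    for col in SAMPLE_FILE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        logger.warning("%s: header only, no samples", path)
        return []
    df["valid_l"] = df["valid_l"].astype(bool)
    df["valid_r"] = df["valid_r"].astype(bool)
    for key, g in df.groupby(["participant_id", "task", "trial", "epoch"],
                             sort=False):
        t = g["t_ms"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = int(g.index[bad[0] + 1]) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-monotone t_ms within trial-epoch {key} at "
                f"line {line}")
    streams = []
    for (pid, group, task), g in df.groupby(
            ["participant_id", "group", "task"], sort=False):
        streams.append(RawSampleStream(
            str(pid), str(group), str(task),
            g.drop(columns=["participant_id", "group", "task"])
            .reset_index(drop=True)))
    return streams


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    df = trials.copy()
    df["correct"] = df["correct"].astype(int)
    df["practice"] = df["practice"].astype(int)
    cols = TRIAL_FILE_COLUMNS + [c for c in df.columns
                                 if c not in TRIAL_FILE_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in TRIAL_FILE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df["correct"] = df["correct"].astype(bool)
    df["practice"] = df["practice"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> SimConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(data)


def write_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seeds: dict[str, int]
    version: str = __version__
    qc_summary: dict = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def add_file(self, path: Path) -> None:
        self.checksums[path.name] = _sha256(path)

    def write(self, path: str | Path) -> None:
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(vars(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: SimConfig, outdir: str | Path,
                 n_perm: int = 1000, simulate: bool = True,
                 resume: bool = False) -> RunManifest:
    """simulate -> preprocess -> cluster -> features -> classify -> power.

    Each stage writes its outputs under ``outdir``; with ``resume=True`` a
    stage whose outputs already exist is skipped.  Returns the run manifest
    (also written as ``manifest.json``).
    """
    from . import classifiersuite, clusterperm, gazedpt, powerstats, pupilprep
    from .synthgen import generate_dataset

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(),
                           seeds={"config": config.seed,
                                  "cluster": config.seed + 1})
    samples_path = out / "samples.tsv"
    trials_path = out / "trials.tsv"

    # -- simulate ----------------------------------------------------------
    if simulate and not (resume and samples_path.exists()
                         and trials_path.exists()):
        streams, trials, truth = generate_dataset(config)
        write_samples(streams, samples_path)
        write_trials(trials, trials_path)
        truth.to_csv(out / "participants.tsv", sep="\t", index=False)
    elif not samples_path.exists() or not trials_path.exists():
        raise PipelineError("no input data: run with simulate=True or place "
                            "samples.tsv/trials.tsv in the output directory")
    streams = read_samples(samples_path)
    trials = read_trials(trials_path)

    # -- preprocess --------------------------------------------------------
    epochs, differences, qc = pupilprep.preprocess_dataset(
        streams, baseline_ms=config.baseline_ms, image_ms=config.image_ms,
        sampling_rate=config.sampling_rate)
    epochs.to_csv(out / "epochs.tsv", sep="\t", index=False)
    differences.to_csv(out / "differences.tsv", sep="\t", index=False)
    with open(out / "qc.json", "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in qc], fh, indent=2)
    manifest.qc_summary = {
        "participants_in": len(qc),
        "participants_kept": int(sum(r.participant_kept for r in qc)),
    }

    # -- cluster test ------------------------------------------------------
    bins = [c for c in differences.columns if c.startswith("bin")]
    curves = {g: differences.loc[differences["group"] == g, bins]
              .to_numpy(dtype=float) for g in GROUPS}
    two = clusterperm.permutation_test(curves["smoker"], curves["nonsmoker"],
                                       n_perm=n_perm,
                                       seed=config.seed + 1)
    cluster_out = {"two_sample": two.to_dict()}
    for g in GROUPS:
        if curves[g].shape[0] >= 2:
            one = clusterperm.permutation_test(curves[g], n_perm=n_perm,
                                               seed=config.seed + 1)
            cluster_out[f"one_sample_{g}"] = one.to_dict()
    with open(out / "clusters.json", "w", encoding="utf-8") as fh:
        json.dump(cluster_out, fh, indent=2)

    # -- features ----------------------------------------------------------
    sig = two.significant()
    if sig:
        best = min(sig, key=lambda c: (c.p_value, -abs(c.mass)))
        lo_bin, hi_bin = best.start_bin, best.end_bin
    elif two.clusters:
        best = min(two.clusters, key=lambda c: (c.p_value, -abs(c.mass)))
        lo_bin, hi_bin = best.start_bin, best.end_bin
        logger.info("no significant cluster; using the smallest-p cluster "
                    "window for the pupil feature")
    else:
        lo_bin, hi_bin = config.effect_window_bins()
        logger.info("no clusters found; falling back to the configured "
                    "effect window for the pupil feature")
    pupil_bias = {
        row["participant_id"]: float(np.mean(
            [row[f"bin{b}"] for b in range(lo_bin, hi_bin)]))
        for _, row in differences.iterrows()}
    kept = set(differences["participant_id"])
    features = gazedpt.compute_bias_features(
        [s for s in streams if s.participant_id in kept], trials,
        pupil_bias=pupil_bias)
    features.to_csv(out / "features.tsv", sep="\t", index=False)

    # -- classify ----------------------------------------------------------
    feature_cols = ["rt_bias_dpt_ms", "dwell_bias_ms", "first_fix_bias",
                    "rt_bias_pv_ms", "pupil_bias_z"]
    x = features.set_index("participant_id")[feature_cols].dropna()
    y = (features.set_index("participant_id").loc[x.index, "group"]
         == "smoker").to_numpy(dtype=float)
    scores = classifiersuite.best_subset(x, y)
    cv = classifiersuite.loo_cv(x, y, subset=scores[0].features)
    with open(out / "classification.json", "w", encoding="utf-8") as fh:
        json.dump({
            "best_subsets": [{"features": list(s.features),
                              "deviance": s.deviance, "aic": s.aic,
                              "bic": s.bic} for s in scores[:10]],
            "selected": list(scores[0].features),
            "cv": cv.to_dict(),
        }, fh, indent=2)

    # -- power -------------------------------------------------------------
    n_analysed = len(y)
    crit = powerstats.min_significant_count(n_analysed)
    grid = powerstats.power_curve([n_analysed], [0.6, 0.65, 0.7, 0.75, 0.8])
    grid.table.to_csv(out / "power_grid.tsv", sep="\t", index=False)
    with open(out / "power.json", "w", encoding="utf-8") as fh:
        json.dump({"n": n_analysed, "critical_count": crit.k,
                   "critical_accuracy_percent": crit.accuracy_percent,
                   "power_at_0.70": powerstats.binomial_power(n_analysed,
                                                              0.70)},
                  fh, indent=2)

    for name in ("samples.tsv", "trials.tsv", "participants.tsv",
                 "epochs.tsv", "differences.tsv", "qc.json", "clusters.json",
                 "features.tsv", "classification.json", "power_grid.tsv",
                 "power.json"):
        p = out / name
        if p.exists():
            manifest.add_file(p)
    manifest.write(out / "manifest.json")
    return manifest
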