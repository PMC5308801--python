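"""Agreement between motion-capture trunk trajectories and force-plate COP.

A markerless camera tracking the trunk and a force plate under the seat see
the same postural sway through different physics.  To quantify agreement, the
600 Hz center-of-pressure trace is block-averaged down to the 30 Hz camera
rate, both series are standardized (mean-centered, unit variance), and
per-trial Pearson correlation and RMSE are computed between each mapped axis
pair.  Axis mapping follows the force-plate coordinate frame: camera lateral
(x) <-> COP "X", camera depth (z) <-> COP "Y"; the vertical camera axis has
no COP counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from posturekit.datamodel_io import Dataset, Device, Trial

#: camera axis -> COP channel correspondence (configurable per call).
DEFAULT_AXIS_MAP = {"x": "cop_x", "z": "cop_y"}

SPINAL_JOINTS = ("SpineMid", "Neck", "Head")


class UndefinedCorrelationError(ValueError):
    """A channel has zero variance; Pearson r is undefined."""


def block_downsample(trial: Trial, target_rate_hz: float) -> Trial:
    """Reduce a trial's rate by non-overlapping block means.

    The source rate must be an integer multiple of the target rate; a
    trailing partial block is dropped.  A factor-1 request returns the trial
    unchanged.
    """
    if target_rate_hz <= 0:
        raise ValueError("target rate must be positive")
    ratio = trial.sample_rate_hz / target_rate_hz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"source rate {trial.sample_rate_hz} Hz is not an integer "
            f"multiple of target {target_rate_hz} Hz"
        )
    if factor == 1:
        return trial
    n_blocks = trial.n_frames // factor
    if n_blocks < 2:
        raise ValueError("too few frames for the requested downsampling")
    x = trial.samples[:, : n_blocks * factor]
    blocked = x.reshape(trial.n_channels, n_blocks, factor).mean(axis=2)
    from dataclasses import replace

    return replace(trial, samples=blocked, sample_rate_hz=target_rate_hz)


def _standardize(x: np.ndarray, label: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise UndefinedCorrelationError(
            f"channel {label!r} has zero variance"
        )
    return (x - x.mean()) / sd


def correlate_pair(
    mk2: Trial,
    kfp: Trial,
    joint: str = "SpineMid",
    axis_map: dict[str, str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-axis (Pearson r, RMSE) between one joint's motion and the COP.

    The force-plate trial is block-downsampled to the camera rate, both
    series truncated to the common length, and each standardized before
    comparison (so RMSE is on the standardized scale and rescaling either
    input changes nothing).
    """
    if mk2.device is not Device.MK2 or kfp.device is not Device.KFP:
        raise ValueError("expected (MK2 trial, KFP trial)")
    if (mk2.subject_id, mk2.task_id, mk2.condition_id) != (
            kfp.subject_id, kfp.task_id, kfp.condition_id):
        raise ValueError("trials are not a simultaneous pair")
    axis_map = DEFAULT_AXIS_MAP if axis_map is None else axis_map
    kfp_ds = block_downsample(kfp, mk2.sample_rate_hz)
    n = min(mk2.n_frames, kfp_ds.n_frames)
    labels = list(mk2.channel_labels)
    kfp_labels = list(kfp_ds.channel_labels)
    out: dict[str, tuple[float, float]] = {}
    for axis, cop_name in axis_map.items():
        mk2_label = f"{joint}_{axis}"
        if mk2_label not in labels:
            raise LookupError(f"joint channel {mk2_label!r} not in MK2 trial")
        a = _standardize(mk2.samples[labels.index(mk2_label), :n], mk2_label)
        b = _standardize(kfp_ds.samples[kfp_labels.index(cop_name), :n],
                         cop_name)
        r = float(stats.pearsonr(a, b).statistic)
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        out[axis] = (r, rmse)
    return out


@dataclass
class BenchmarkReport:
    """Per-(task, joint, axis) agreement summary across subjects.

    ``table`` columns: task, joint, axis, mean_r, sd_r, mean_rmse, n (number
    of contributing subjects); ``per_subject`` keeps the per-subject values
    (one row per subject x task x joint x axis, conditions averaged).
    """

    table: pd.DataFrame
    per_subject: pd.DataFrame

    def to_wide(self) -> pd.DataFrame:
        """Rows = tasks, columns = joint (axis), entries 'mean +/- sd'."""
        wide = self.table.copy()
        wide["cell"] = (wide["mean_r"].round(2).astype(str) + "±"
                        + wide["sd_r"].round(2).astype(str))
        return wide.pivot(index="task", columns=["joint", "axis"],
                          values="cell")


def benchmark_dataset(
    dataset: Dataset,
    joints: tuple[str, ...] = SPINAL_JOINTS,
    axis_map: dict[str, str] | None = None,
    conditions: tuple[int, ...] | None = None,
) -> BenchmarkReport:
    """Correlate every paired MK2/KFP trial; summarize per task/joint/axis.

    Per-trial correlations are averaged over conditions within each subject
    (``conditions`` restricts which are pooled; default all), then the mean
    and standard deviation across subjects are reported.  Unpaired trials are
    skipped with a warning.
    """
    axis_map = DEFAULT_AXIS_MAP if axis_map is None else axis_map
    rows = []
    for mk2 in dataset:
        if mk2.device is not Device.MK2:
            continue
        if conditions is not None and mk2.condition_id not in conditions:
            continue
        kfp = dataset.get(mk2.subject_id, mk2.task_id, mk2.condition_id,
                          Device.KFP)
        if kfp is None:
            warnings.warn(
                f"no paired KFP trial for {mk2.key}; skipped", stacklevel=2
            )
            continue
        for joint in joints:
            for axis, (r, rmse) in correlate_pair(
                    mk2, kfp, joint, axis_map).items():
                rows.append({
                    "subject": mk2.subject_id, "task": mk2.task_id,
                    "condition": mk2.condition_id, "joint": joint,
                    "axis": axis, "r": r, "rmse": rmse,
                })
    if not rows:
        raise ValueError("no paired trials to benchmark")
    per_trial = pd.DataFrame(rows)
    per_subject = (
        per_trial.groupby(["subject", "task", "joint", "axis"],
                          as_index=False)[["r", "rmse"]].mean()
    )
    grouped = per_subject.groupby(["task", "joint", "axis"])
    table = grouped.agg(
        mean_r=("r", "mean"),
        sd_r=("r", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        mean_rmse=("rmse", "mean"),
        n=("r", "size"),
    ).reset_index()
    return BenchmarkReport(table=table, per_subject=per_subject)
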