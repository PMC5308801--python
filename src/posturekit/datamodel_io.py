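"""Trial/session data model, CSV dialects, joint subsets, and frame cleaning.

A :class:`Trial` is one multivariate recording, channels x frames, with
subject / task / condition / device metadata.  Motion-capture ("MK2") trials
carry 3 channels per tracked joint, ordered joint-major (x, y, z); force-plate
("KFP") trials carry the two center-of-pressure coordinates.  Units are meters
throughout (millimeter input is converted at ingest).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AXES = ("x", "y", "z")

#: Kinect-2 joint vocabulary, device order.
FULL_25_JOINTS = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)

#: The 16 joints at or above SpineMid: the trunk and upper extremities.
UPPER_16_JOINTS = (
    "SpineMid", "SpineShoulder", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "HandTipLeft", "ThumbLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HandTipRight", "ThumbRight",
)

#: The four spinal-column joints, caudal to cranial.
SPINE_4_JOINTS = ("SpineMid", "SpineShoulder", "Neck", "Head")

KFP_CHANNELS = ("cop_x", "cop_y")


class Device(str, Enum):
    MK2 = "MK2"
    KFP = "KFP"


class JointSubset(Enum):
    """Named joint subsets used for channel selection."""

    FULL_25 = FULL_25_JOINTS
    UPPER_16 = UPPER_16_JOINTS
    SPINE_4 = SPINE_4_JOINTS

    @property
    def joints(self) -> tuple[str, ...]:
        return self.value

    @property
    def channel_labels(self) -> list[str]:
        return [f"{j}_{a}" for j in self.value for a in AXES]

    @classmethod
    def from_name(cls, name: str) -> "JointSubset":
        key = name.strip().lower().replace("-", "").replace("_", "")
        table = {"full25": cls.FULL_25, "full": cls.FULL_25,
                 "upper16": cls.UPPER_16, "spine4": cls.SPINE_4}
        if key not in table:
            raise ValueError(f"unknown joint subset {name!r}")
        return table[key]


class FormatError(ValueError):
    """A file's header or tokens do not match the declared dialect."""


class ValidationError(ValueError):
    """Structurally valid input violating a data-model invariant."""


class DataQualityError(ValueError):
    """Too many missing samples to repair by interpolation."""


@dataclass(frozen=True)
class Trial:
    """One multivariate recording with its metadata.

    ``samples`` is channels x frames, in meters.  MK2 channel labels follow
    ``<Joint>_<axis>``; KFP channels are ``cop_x``, ``cop_y``.
    """

    subject_id: str
    task_id: int
    condition_id: int
    device: Device
    channel_labels: tuple[str, ...]
    sample_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if samples.ndim != 2:
            raise ValidationError("samples must be a channels x frames matrix")
        if samples.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{samples.shape[0]} sample rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if samples.shape[1] < 2:
            raise ValidationError("a trial needs at least 2 frames")
        if not 1 <= self.task_id <= 6:
            raise ValidationError(f"task_id {self.task_id} outside 1-6")
        if not 1 <= self.condition_id <= 3:
            raise ValidationError(f"condition_id {self.condition_id} outside 1-3")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.device is Device.KFP and self.channel_labels != KFP_CHANNELS:
            raise ValidationError(
                f"KFP trials must have channels {KFP_CHANNELS}, "
                f"got {self.channel_labels}"
            )
        if self.device is Device.MK2 and len(self.channel_labels) % 3 != 0:
            raise ValidationError("MK2 channel count must be 3 x (#joints)")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_frames(self) -> int:
        return self.samples.shape[1]

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.subject_id, self.task_id, self.condition_id, self.device.value)

    @property
    def joints(self) -> tuple[str, ...]:
        """Joint names, for MK2 trials (every third channel label)."""
        if self.device is not Device.MK2:
            raise ValidationError("joints defined for MK2 trials only")
        return tuple(lab.rsplit("_", 1)[0] for lab in self.channel_labels[::3])

    def with_samples(self, samples: np.ndarray) -> "Trial":
        return replace(self, samples=samples)


@dataclass
class Dataset:
    """A collection of trials indexed by (subject, task, condition, device)."""

    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, int, int, str], Trial] = {}
        for t in self.trials:
            if t.key in self._index:
                raise ValidationError(f"duplicate trial for key {t.key}")
            self._index[t.key] = t

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def add(self, trial: Trial) -> None:
        if trial.key in self._index:
            raise ValidationError(f"duplicate trial for key {trial.key}")
        self._index[trial.key] = trial
        self.trials.append(trial)

    def get(self, subject_id: str, task_id: int, condition_id: int,
            device: Device | str) -> Trial | None:
        dev = Device(device).value
        return self._index.get((subject_id, task_id, condition_id, dev))

    def subjects(self) -> list[str]:
        return sorted({t.subject_id for t in self.trials})

    def tasks(self) -> list[int]:
        return sorted({t.task_id for t in self.trials})

    def conditions(self) -> list[int]:
        return sorted({t.condition_id for t in self.trials})

    def filter(self, *, subject_id: str | None = None, task_id: int | None = None,
               condition_id: int | None = None,
               device: Device | str | None = None) -> "Dataset":
        dev = Device(device) if device is not None else None
        picked = [
            t for t in self.trials
            if (subject_id is None or t.subject_id == subject_id)
            and (task_id is None or t.task_id == task_id)
            and (condition_id is None or t.condition_id == condition_id)
            and (dev is None or t.device is dev)
        ]
        return Dataset(picked)


def _mk2_header(joints: Iterable[str]) -> list[str]:
    return ["frame", "time_s"] + [f"{j}_{a}" for j in joints for a in AXES]


def read_trial_csv(
    path: str | Path,
    *,
    subject_id: str,
    task_id: int,
    condition_id: int,
    device: Device | str,
    units: str = "m",
) -> Trial:
    """Read one trial CSV in the device's dialect.

    MK2 dialect: ``frame,time_s,<Joint>_x,<Joint>_y,<Joint>_z,...``;
    KFP dialect: ``sample,time_s,cop_x,cop_y``.  The time column is validated
    for strict monotonicity and then discarded; empty cells and NaN tokens are
    kept as NaN for :func:`clean_frames` to repair.
    """
    device = Device(device)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if device is Device.KFP:
        expected = ["sample", "time_s", "cop_x", "cop_y"]
        if cols != expected:
            offending = next((c for c, e in zip(cols, expected) if c != e),
                             cols[len(expected):][0] if len(cols) > len(expected)
                             else "<missing>")
            raise FormatError(
                f"{path.name}: KFP header mismatch at column {offending!r}; "
                f"expected {expected}"
            )
        labels = KFP_CHANNELS
        rate = 600.0
    else:
        index_col, time_col = "frame", "time_s"
        if len(cols) < 3 or cols[0] != index_col or cols[1] != time_col:
            raise FormatError(
                f"{path.name}: MK2 header must start with "
                f"'{index_col},{time_col}', got {cols[:2]}"
            )
        chan_cols = cols[2:]
        joints = [c[:-2] for c in chan_cols if c.endswith("_x")]
        expected = [f"{j}_{a}" for j in joints for a in AXES]
        for i, exp in enumerate(expected):
            got = chan_cols[i] if i < len(chan_cols) else "<missing>"
            if got != exp:
                raise FormatError(
                    f"{path.name}: MK2 header mismatch at column {got!r}; "
                    f"expected {exp!r} (joint-major x,y,z order)"
                )
        if len(chan_cols) != len(expected):
            raise FormatError(
                f"{path.name}: unexpected trailing column "
                f"{chan_cols[len(expected)]!r}"
            )
        labels = tuple(chan_cols)
        rate = 30.0

    time = df[cols[1]].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        bad = int(np.argmax(np.diff(time) <= 0)) + 1
        raise ValidationError(
            f"{path.name}: time column not strictly increasing at row {bad}"
        )
    samples = df[list(labels)].to_numpy(dtype=float).T
    if units == "mm":
        samples = samples / 1000.0
    elif units != "m":
        raise ValueError(f"unknown units {units!r}; use 'm' or 'mm'")
    return Trial(
        subject_id=subject_id,
        task_id=task_id,
        condition_id=condition_id,
        device=device,
        channel_labels=labels,
        sample_rate_hz=rate,
        samples=samples,
    )


def write_trial_csv(trial: Trial, path: str | Path) -> None:
    """Write a trial in its device's CSV dialect (inverse of read_trial_csv)."""
    path = Path(path)
    n = trial.n_frames
    t = np.arange(n) / trial.sample_rate_hz
    index_name = "sample" if trial.device is Device.KFP else "frame"
    df = pd.DataFrame({index_name: np.arange(n), "time_s": t})
    for i, lab in enumerate(trial.channel_labels):
        df[lab] = trial.samples[i]
    df.to_csv(path, index=False, float_format="%.17g")


def clean_frames(trial: Trial, max_missing_fraction: float = 0.5) -> Trial:
    """Repair tracking dropouts (NaN samples).

    Interior gaps are filled by per-channel linear interpolation; frames that
    are missing in any channel at the start or end of the recording are
    dropped.  A channel missing more than ``max_missing_fraction`` of its
    frames raises :class:`DataQualityError`.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    x = trial.samples
    missing = np.isnan(x)
    if not missing.any():
        return trial
    frac = missing.mean(axis=1)
    worst = int(np.argmax(frac))
    if frac[worst] > max_missing_fraction:
        raise DataQualityError(
            f"channel {trial.channel_labels[worst]!r} missing "
            f"{frac[worst]:.0%} of frames (limit {max_missing_fraction:.0%})"
        )
    # drop leading/trailing frames missing in any channel
    any_missing = missing.any(axis=0)
    valid = np.flatnonzero(~any_missing)
    if valid.size < 2:
        raise DataQualityError("fewer than 2 fully-tracked frames remain")
    lead = int(valid[0])
    trail = int(x.shape[1] - 1 - valid[-1])
    x = x[:, lead: x.shape[1] - trail]
    out = x.copy()
    frames = np.arange(out.shape[1])
    for ch in range(out.shape[0]):
        nan = np.isnan(out[ch])
        if nan.any():
            out[ch, nan] = np.interp(frames[nan], frames[~nan], out[ch, ~nan])
    return trial.with_samples(out)


def select_channels(trial: Trial, subset: JointSubset) -> Trial:
    """Restrict an MK2 trial to a named joint subset, joint-major order.

    Balance analyses use the 16 joints of the trunk and upper extremities (to
    avoid classifying the imposed leg posture itself) or only the four spinal
    joints; this reorders channels to the subset's canonical order.
    """
    if trial.device is not Device.MK2:
        raise ValidationError("channel selection applies to MK2 trials")
    have = {lab: i for i, lab in enumerate(trial.channel_labels)}
    idx: list[int] = []
    for joint in subset.joints:
        for a in AXES:
            lab = f"{joint}_{a}"
            if lab not in have:
                raise LookupError(f"joint channel {lab!r} not present in trial")
            idx.append(have[lab])
    return replace(
        trial,
        channel_labels=tuple(subset.channel_labels),
        samples=trial.samples[idx],
    )


def read_manifest(
    path: str | Path,
    *,
    max_missing_fraction: float = 0.5,
    units: str = "m",
) -> Dataset:
    """Load every trial listed in a manifest CSV into an indexed Dataset.

    Manifest columns: ``file,subject,task,condition,device``; file paths are
    resolved relative to the manifest's directory.  Each trial is cleaned with
    :func:`clean_frames` on load.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["file", "subject", "task", "condition", "device"]
    if list(df.columns) != required:
        raise FormatError(
            f"manifest columns must be {required}, got {list(df.columns)}"
        )
    if df.empty:
        warnings.warn(f"manifest {path.name} lists no trials", stacklevel=2)
        return Dataset([])
    ds = Dataset([])
    for row in df.itertuples(index=False):
        try:
            device = Device(str(row.device))
        except ValueError:
            raise FormatError(
                f"unknown device token {row.device!r} in manifest"
            ) from None
        trial = read_trial_csv(
            path.parent / str(row.file),
            subject_id=str(row.subject),
            task_id=int(row.task),
            condition_id=int(row.condition),
            device=device,
            units=units,
        )
        ds.add(clean_frames(trial, max_missing_fraction))
    logger.info("loaded %d trials from %s", len(ds), path)
    return ds


def write_manifest(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write every trial plus a manifest CSV into ``out_dir``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in dataset:
        fname = (f"{t.device.value.lower()}_{t.subject_id}"
                 f"_t{t.task_id}_c{t.condition_id}.csv")
        write_trial_csv(t, out_dir / fname)
        rows.append({"file": fname, "subject": t.subject_id, "task": t.task_id,
                     "condition": t.condition_id, "device": t.device.value})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["file", "subject", "task", "condition",
                                "device"]).to_csv(manifest, index=False)
    return manifest
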