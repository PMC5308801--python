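"""Synthetic paired motion-capture / force-plate datasets.

Emulates the statistical structure the classification pipeline assumes for a
seated balance protocol: 12 subjects x 6 tasks x 3 postural conditions, 10 s
trials.  Each task k has a distinctive 48-channel covariance template C_k
(16 upper-body joints x 3 axes).  Increasingly unstable conditions inflate
variance in a fixed low-dimensional "sway subspace" by a factor gamma_c,
modeling the compensatory trunk movements that challenged balance provokes,
so conditions are not separable by total variance alone.  Each subject s
applies an affine channel transform V_s (small rotation and rescaling),
modeling body proportions and sensor placement -- exactly the nuisance the
affine-invariant metric is designed to absorb.

Latent sources are AR(1) with unit stationary variance, so the population
covariance of a trial is exactly V_s L_{k,c} L_{k,c}^T V_s^T and analytic
targets are available for tests.  A 600 Hz center-of-pressure channel pair is
derived from the trunk (SpineMid) lateral/depth motion by linear-interpolation
upsampling plus independent Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from posturekit.datamodel_io import (
    Dataset,
    Device,
    JointSubset,
    Trial,
    UPPER_16_JOINTS,
)
from posturekit.spd_geometry import riemannian_distance

_N_JOINTS = len(UPPER_16_JOINTS)  # 16
_N_CHANNELS = 3 * _N_JOINTS       # 48
_SWAY_DIM = 6

# stream keys for per-purpose seed derivation (see docs/methods.md)
_STRUCTURE_STREAM = 0
_TRIAL_STREAM = 1


class GenerationError(RuntimeError):
    """The requested synthetic structure could not be realized."""


def condition_effects_from_gamma(gamma: float) -> tuple[float, float, float]:
    """Per-condition sway-variance multipliers (1, gamma, gamma^2).

    Geometric spacing: each step up in postural challenge multiplies sway
    variance by the same factor.  gamma = 1 is the null (no condition
    effect); the default gamma = 1.5 gives (1.0, 1.5, 2.25).
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    return (1.0, float(gamma), float(gamma) ** 2)


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters.

    ``condition_effect`` holds the sway-variance multiplier per condition and
    must be non-decreasing; ``ar_coefficient`` is the lag-1 autocorrelation of
    the latent sources; ``subject_transform_scale`` sets the magnitude of the
    per-subject rotation/rescaling; ``cop_noise_sd`` is the standard deviation
    (meters) of the white noise on the derived center-of-pressure channels.
    """

    n_subjects: int = 12
    n_tasks: int = 6
    n_conditions: int = 3
    frames: int = 300
    mk2_rate_hz: float = 30.0
    kfp_rate_hz: float = 600.0
    ar_coefficient: float = 0.95
    condition_effect: tuple[float, ...] = (1.0, 1.5, 2.25)
    subject_transform_scale: float = 0.1
    cop_noise_sd: float = 0.2
    template_separation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_tasks, self.n_conditions) < 1:
            raise ValueError("counts must be positive")
        if self.frames < 2:
            raise ValueError("frames must be >= 2")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if len(self.condition_effect) != self.n_conditions:
            raise ValueError("one condition_effect entry per condition")
        if any(g < 1 for g in self.condition_effect):
            raise ValueError("condition effects must be >= 1")
        if self.subject_transform_scale < 0 or self.cop_noise_sd < 0:
            raise ValueError("scales must be nonnegative")
        if self.template_separation <= 0:
            raise ValueError("template_separation must be positive")
        if self.kfp_rate_hz % self.mk2_rate_hz != 0:
            raise ValueError("kfp rate must be a multiple of the mk2 rate")

    def with_gamma(self, gamma: float) -> "SyntheticConfig":
        return replace(self, condition_effect=condition_effects_from_gamma(gamma))


def _structure_rng(config: SyntheticConfig) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _STRUCTURE_STREAM])
    )


def _trial_rng(config: SyntheticConfig, subject_idx: int, task_id: int,
               condition_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, _TRIAL_STREAM, subject_idx, task_id, condition_id]
        )
    )


def make_task_templates(config: SyntheticConfig) -> list[np.ndarray]:
    """Draw one SPD covariance template per task, pairwise well separated.

    Templates are B_k B_k^T + I with B_k ~ N(0, 1/N) entries; a draw is
    accepted only if every pairwise Riemannian distance between templates is
    at least ``template_separation`` (up to 100 attempts).
    """
    rng = _structure_rng(config)
    n = _N_CHANNELS
    for _ in range(100):
        templates = []
        for _k in range(config.n_tasks):
            b = rng.standard_normal((n, n)) / np.sqrt(n)
            templates.append(b @ b.T + np.eye(n))
        ok = all(
            riemannian_distance(templates[i], templates[j])
            >= config.template_separation
            for i in range(len(templates))
            for j in range(i + 1, len(templates))
        )
        if ok:
            return templates
    raise GenerationError(
        f"could not draw {config.n_tasks} templates with pairwise "
        f"separation >= {config.template_separation} in 100 attempts"
    )


def _symmetric_sqrtm(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (c + c.T))
    return (v * np.sqrt(np.clip(w, 0, None))) @ v.T


@dataclass(frozen=True)
class SyntheticModel:
    """Frozen structural draws of a generator run.

    Holds the task templates, the sway-subspace projector, and the
    per-subject affine transforms, and provides the analytic population
    covariance for any (subject, task, condition) cell.
    """

    config: SyntheticConfig
    templates: list[np.ndarray]
    sway_basis: np.ndarray            # N x 6, orthonormal columns
    subject_transforms: list[np.ndarray]
    joint_offsets: list[np.ndarray]   # per subject, length-N constant offset
    mixings: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_config(cls, config: SyntheticConfig) -> "SyntheticModel":
        templates = make_task_templates(config)
        # subject/subspace draws use a stream disjoint from the template draws
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _STRUCTURE_STREAM, 1])
        )
        n = _N_CHANNELS
        q, _ = np.linalg.qr(rng.standard_normal((n, _SWAY_DIM)))
        transforms = []
        offsets = []
        for _s in range(config.n_subjects):
            g = rng.standard_normal((n, n))
            a = 0.5 * (g - g.T)
            a *= config.subject_transform_scale / max(
                np.linalg.norm(a, 2), 1e-12
            )
            rotation = _expm_skew(a)
            scale = 1.0 + config.subject_transform_scale * rng.uniform(-1, 1)
            transforms.append(scale * rotation)
            # skeletal geometry: constant per-joint offset, shared by x,y,z
            offsets.append(rng.normal(0.0, 0.5, size=n))
        model = cls(
            config=config,
            templates=templates,
            sway_basis=q,
            subject_transforms=transforms,
            joint_offsets=offsets,
        )
        return model

    def mixing(self, task_id: int, condition_id: int) -> np.ndarray:
        """L_{k,c} with L L^T = C_k^{1/2} D_c C_k^{1/2} (symmetric sqrt)."""
        key = (task_id, condition_id)
        if key not in self.mixings:
            c_k = self.templates[task_id - 1]
            gamma = self.config.condition_effect[condition_id - 1]
            d_c = np.eye(_N_CHANNELS) + (gamma - 1.0) * (
                self.sway_basis @ self.sway_basis.T
            )
            half = _symmetric_sqrtm(c_k)
            self.mixings[key] = _symmetric_sqrtm(half @ d_c @ half)
        return self.mixings[key]

    def population_covariance(self, subject_idx: int, task_id: int,
                              condition_id: int) -> np.ndarray:
        """Analytic covariance V_s L L^T V_s^T of the generated signal."""
        v = self.subject_transforms[subject_idx]
        l = self.mixing(task_id, condition_id)
        return v @ (l @ l.T) @ v.T

    def generate_mk2_trial(self, subject_idx: int, task_id: int,
                           condition_id: int,
                           frames: int | None = None) -> Trial:
        """One motion-capture trial: X = V_s L z(t) + per-joint offset.

        z(t) is AR(1) with coefficient phi and innovations scaled by
        sqrt(1 - phi^2), so its stationary covariance is the identity and
        the population covariance of X is exactly V_s L L^T V_s^T.
        """
        cfg = self.config
        frames = cfg.frames if frames is None else frames
        rng = _trial_rng(cfg, subject_idx, task_id, condition_id)
        phi = cfg.ar_coefficient
        n = _N_CHANNELS
        z = np.empty((n, frames))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, frames - 1)) * np.sqrt(1 - phi**2)
        for t in range(1, frames):
            z[:, t] = phi * z[:, t - 1] + innov[:, t - 1]
        v = self.subject_transforms[subject_idx]
        l = self.mixing(task_id, condition_id)
        x = v @ (l @ z) + self.joint_offsets[subject_idx][:, None]
        return Trial(
            subject_id=f"S{subject_idx + 1:02d}",
            task_id=task_id,
            condition_id=condition_id,
            device=Device.MK2,
            channel_labels=tuple(JointSubset.UPPER_16.channel_labels),
            sample_rate_hz=cfg.mk2_rate_hz,
            samples=x,
        )

    def derive_kfp_trial(self, mk2: Trial, subject_idx: int) -> Trial:
        """Center-of-pressure pair read out from the trunk channels.

        The SpineMid lateral (x) and depth (z) trajectories are upsampled to
        the force-plate rate by linear interpolation; independent Gaussian
        noise of sd ``cop_noise_sd`` models plate measurement noise.
        """
        cfg = self.config
        labels = list(mk2.channel_labels)
        src = mk2.samples[[labels.index("SpineMid_x"),
                           labels.index("SpineMid_z")]]
        factor = int(cfg.kfp_rate_hz // cfg.mk2_rate_hz)
        n_out = mk2.n_frames * factor
        t_mk2 = np.arange(mk2.n_frames) / cfg.mk2_rate_hz
        t_kfp = np.arange(n_out) / cfg.kfp_rate_hz
        cop = np.vstack([np.interp(t_kfp, t_mk2, row) for row in src])
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [cfg.seed, _TRIAL_STREAM, subject_idx, mk2.task_id,
                 mk2.condition_id, 1]
            )
        )
        cop = cop + rng.normal(0.0, cfg.cop_noise_sd, size=cop.shape)
        return Trial(
            subject_id=mk2.subject_id,
            task_id=mk2.task_id,
            condition_id=mk2.condition_id,
            device=Device.KFP,
            channel_labels=("cop_x", "cop_y"),
            sample_rate_hz=cfg.kfp_rate_hz,
            samples=cop,
        )


def generate_dataset(config: SyntheticConfig | None = None,
                     **overrides) -> Dataset:
    """Generate the full paired dataset (one MK2 and one KFP trial per cell).

    With defaults: 12 subjects x 6 tasks x 3 conditions = 216 trials per
    device.  Deterministic given ``config.seed``; any single trial is
    reproducible in isolation from (seed, subject, task, condition).
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    model = SyntheticModel.from_config(config)
    ds = Dataset([])
    for s in range(config.n_subjects):
        for k in range(1, config.n_tasks + 1):
            for c in range(1, config.n_conditions + 1):
                mk2 = model.generate_mk2_trial(s, k, c)
                ds.add(mk2)
                ds.add(model.derive_kfp_trial(mk2, s))
    return ds


def empirical_convergence_check(config: SyntheticConfig,
                                long_frames: int = 50_000) -> float:
    """Generator self-test: empirical vs analytic covariance of one long trial.

    Returns max_ij |Chat_ij - C_ij| / max_ij |C_ij| for a single
    ``long_frames``-frame trial of subject 1, task 1, condition 1 (the
    deviation is normalized by the largest-magnitude analytic entry, since
    elementwise ratios are unbounded where C_ij is near zero).
    """
    model = SyntheticModel.from_config(config)
    trial = model.generate_mk2_trial(0, 1, 1, frames=long_frames)
    x = trial.samples
    xc = x - x.mean(axis=1, keepdims=True)
    emp = (xc @ xc.T) / x.shape[1]
    target = model.population_covariance(0, 1, 1)
    return float(np.abs(emp - target).max() / np.abs(target).max())


def _expm_skew(a: np.ndarray) -> np.ndarray:
    """exp of a skew-symmetric matrix (an orthogonal rotation)."""
    import scipy.linalg

    return scipy.linalg.expm(a)
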