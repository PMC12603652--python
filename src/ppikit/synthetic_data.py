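"""Ground-truth simulator for block-design PPI analyses.

Emulates a block-design language paradigm (default TR = 0.9 s, 200 scans,
alternating 18-s task/baseline blocks) with a known task-modulated
coupling from a seed region to a target series:

    neuronal:  z_seed   = g * psy + eta_s
               z_target = alpha * z_seed + gamma * psy
                          + beta_ppi * (psy_c * z_seed) + eta_t
    BOLD:      b = H z + AR(1) noise
    ROI:       V voxel columns = seed BOLD + iid voxel noise

where ``psy`` is the 0/1 task boxcar (main effects respond to the actual
stimulus stream, so their convolved shape matches an analysis design
column exactly, onset ramp included), ``psy_c`` is its mean-centered
version (the interaction modulates coupling around its task-average
``alpha``), ``eta`` are smooth latent AR(1) noises at the neuronal level
(so deconvolution has structure to recover), and H is the canonical-HRF
convolution operator.
The interaction is injected at the *neuronal* level and then convolved —
the premise of deconvolution-based PPI.  ``beta_ppi`` is the ground-truth
interaction amplitude every pipeline is judged against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .core_timeseries import BasisSet, RoiMatrix, TimeSeries
from .errors import InvalidArgumentError
from .hemodynamics import default_operator
from .ppi_design import PsychRegressor

#: AR(1) coefficient of the latent neuronal noise (kept smooth so that the
#: deconvolution step has recoverable structure).
NEURONAL_AR = 0.5


@dataclass(frozen=True)
class GroundTruth:
    """Simulator parameters.

    Attributes
    ----------
    alpha : float
        Seed-to-target physiological coupling (context-independent).
    beta_ppi : float
        Interaction amplitude: change in coupling with task context.
    gamma : float
        Task main effect on the target.
    seed_task_gain : float
        Task main effect on the seed's neuronal signal.
    target_latent_sd : float
        Marginal SD of the target's own latent neuronal noise eta_t
        (activity unrelated to the seed or task); 0 gives a target fully
        determined by seed, task and interaction.
    rho_noise : float
        Lag-1 coefficient of the AR(1) BOLD measurement noise.
    sigma_noise : float
        Marginal (stationary) standard deviation of that noise.
    n_roi_voxels : int
        Number of voxel columns in the simulated ROI.
    voxel_noise_sd : float
        SD of iid measurement noise added independently per voxel.
    tr, n_scans, block_len_s
        Acquisition grid: 0.9 s sampling, 200 scans, 18-s blocks.
    """

    alpha: float = 0.5
    beta_ppi: float = 0.4
    gamma: float = 0.5
    seed_task_gain: float = 1.0
    target_latent_sd: float = 1.0
    rho_noise: float = 0.4
    sigma_noise: float = 0.5
    n_roi_voxels: int = 10
    voxel_noise_sd: float = 0.5
    tr: float = 0.9
    n_scans: int = 200
    block_len_s: float = 18.0

    def __post_init__(self) -> None:
        if not abs(self.rho_noise) < 1:
            raise InvalidArgumentError("|rho_noise| must be < 1")
        if min(self.sigma_noise, self.voxel_noise_sd, self.target_latent_sd) < 0:
            raise InvalidArgumentError("noise SDs must be non-negative")
        if self.n_roi_voxels < 1:
            raise InvalidArgumentError("n_roi_voxels must be >= 1")
        if self.tr <= 0 or self.n_scans < 8:
            raise InvalidArgumentError("tr must be positive and n_scans >= 8")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta_ppi": self.beta_ppi,
            "gamma": self.gamma,
            "seed_task_gain": self.seed_task_gain,
            "target_latent_sd": self.target_latent_sd,
            "rho_noise": self.rho_noise,
            "sigma_noise": self.sigma_noise,
            "n_roi_voxels": self.n_roi_voxels,
            "voxel_noise_sd": self.voxel_noise_sd,
            "tr": self.tr,
            "n_scans": self.n_scans,
            "block_len_s": self.block_len_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass(eq=False)
class SubjectData:
    """One simulated (or loaded) subject: ROI, targets, task, confounds."""

    roi: RoiMatrix
    targets: dict[str, TimeSeries]
    psy: PsychRegressor
    confounds: BasisSet | None
    truth: GroundTruth | None = None
    seed_value: int | None = None

    def __post_init__(self) -> None:
        n = self.roi.n_scans
        if len(self.psy) != n:
            raise InvalidArgumentError("task regressor length must match ROI")
        for name, ts in self.targets.items():
            if ts.n_scans != n:
                raise InvalidArgumentError(f"target {name!r} length must match ROI")
        if self.confounds is not None and self.confounds.n_columns:
            if self.confounds.columns.shape[0] != n:
                raise InvalidArgumentError("confound rows must match ROI timepoints")


def make_block_design(tr: float, n_scans: int, block_len_s: float) -> PsychRegressor:
    """Alternating task/baseline boxcar, starting with task.

    Blocks are ``round(block_len_s / tr)`` samples long; task samples are
    coded 1 and baseline 0.
    """
    if tr <= 0 or n_scans < 2:
        raise InvalidArgumentError("tr must be positive and n_scans >= 2")
    if block_len_s < tr:
        raise InvalidArgumentError("block length must be at least one sample")
    block = int(round(block_len_s / tr))
    if block > n_scans:
        raise InvalidArgumentError("a single block is longer than the whole run")
    idx = np.arange(n_scans) // block
    values = ((idx % 2) == 0).astype(float)
    return PsychRegressor(values=values)


def _ar1_series(rng: np.random.Generator, n: int, rho: float, marginal_sd: float,
                n_cols: int | None = None) -> np.ndarray:
    """Stationary AR(1) draw with the requested marginal SD."""
    shape = (n,) if n_cols is None else (n, n_cols)
    if marginal_sd == 0:
        return np.zeros(shape)
    e = rng.normal(0.0, marginal_sd * np.sqrt(1.0 - rho**2), size=shape)
    first = rng.normal(0.0, marginal_sd, size=shape[1:] if n_cols else ())
    e[0] = first
    return lfilter([1.0], [1.0, -rho], e, axis=0)


def simulate_subject(truth: GroundTruth, seed: int, drift_amplitude: float = 0.0) -> SubjectData:
    """Generate one subject's data; deterministic given ``seed``.

    ``drift_amplitude`` optionally adds a slow sinusoid (60-s period) to
    every measured series and supplies the matching confound column, to
    exercise the nuisance-regression path.
    """
    rng = np.random.default_rng(seed)
    n, tr = truth.n_scans, truth.tr
    psy = make_block_design(tr, n, truth.block_len_s)
    psy_c = psy.values - psy.values.mean()

    eta_s = _ar1_series(rng, n, NEURONAL_AR, 1.0)
    z_seed = truth.seed_task_gain * psy.values + eta_s
    eta_t = _ar1_series(rng, n, NEURONAL_AR, truth.target_latent_sd)
    z_target = (
        truth.alpha * z_seed
        + truth.gamma * psy.values
        + truth.beta_ppi * (psy_c * z_seed)
        + eta_t
    )

    h = default_operator(tr, n).entries
    b_seed = h @ z_seed + _ar1_series(rng, n, truth.rho_noise, truth.sigma_noise)
    b_target = h @ z_target + _ar1_series(rng, n, truth.rho_noise, truth.sigma_noise)

    roi_values = b_seed[:, None] + (
        rng.normal(0.0, truth.voxel_noise_sd, size=(n, truth.n_roi_voxels))
        if truth.voxel_noise_sd > 0
        else np.zeros((n, truth.n_roi_voxels))
    )

    confounds: BasisSet | None = None
    if drift_amplitude != 0.0:
        drift = np.sin(2 * np.pi * np.arange(n) * tr / 60.0)
        roi_values = roi_values + drift_amplitude * drift[:, None]
        b_target = b_target + drift_amplitude * drift
        confounds = BasisSet(drift[:, None], ["drift_sin60"])

    return SubjectData(
        roi=RoiMatrix(roi_values, tr),
        targets={"target": TimeSeries(b_target, tr)},
        psy=psy,
        confounds=confounds,
        truth=truth,
        seed_value=int(seed),
    )


def simulate_cohort(truth: GroundTruth, n_subjects: int,
                    between_subject_sd: float = 0.0, master_seed: int = 0,
                    drift_amplitude: float = 0.0) -> list[SubjectData]:
    """Simulate a cohort with between-subject variation in ``beta_ppi``.

    Per-subject interaction amplitudes are normal with mean
    ``truth.beta_ppi`` and SD ``between_subject_sd``; subject i's data
    seed is ``master_seed + i`` (the amplitude draws use a separate,
    deterministic stream so they never share randomness with the data).
    """
    if n_subjects < 2:
        raise InvalidArgumentError("a cohort needs at least 2 subjects")
    if between_subject_sd < 0:
        raise InvalidArgumentError("between_subject_sd must be non-negative")
    beta_rng = np.random.default_rng([int(master_seed), 0x5EED])
    betas = truth.beta_ppi + between_subject_sd * beta_rng.standard_normal(n_subjects)
    cohort = []
    for i in range(n_subjects):
        subject_truth = replace(truth, beta_ppi=float(betas[i]))
        cohort.append(
            simulate_subject(subject_truth, int(master_seed) + i, drift_amplitude)
        )
    return cohort
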