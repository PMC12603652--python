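"""Seed extraction, interaction construction, and prewhitened PPI fitting.

A psychophysiological interaction (PPI) model asks whether the coupling
between a seed region and a target series changes with psychological
context.  Two specification details decide whether the model is valid:

* **Whitening inversion.**  Standard extraction residualizes the ROI
  against confounds under prewhitening, so the extracted eigenvariate is
  a *whitened* series.  Left uncorrected, the model-fitting stage — which
  prewhitens again — applies W twice to the seed regressor, and the
  deconvolution step operates on a distorted series.  The correction is
  to multiply the extracted series by W^-1 before downstream use.
* **Mean-centering.**  The task regressor must be mean-centered before
  multiplying it with the (deconvolved) neuronal seed; otherwise the
  interaction regressor carries a copy of the seed main effect that an
  imperfect deconvolution cannot cancel, producing spurious interaction
  effects — most tellingly at the seed location itself.

The four canonical pipelines index the two flags:
1 = neither, 2 = inversion only, 3 = centering only, 4 = both (the
recommended, correctly specified model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_timeseries import (
    BasisSet,
    RoiMatrix,
    TimeSeries,
    _data,
    concat_bases,
    dct_highpass_basis,
    first_eigenvariate,
)
from .errors import DegenerateInputError, InvalidArgumentError, RankDeficiencyError
from .hemodynamics import (
    DEFAULT_SHRINKAGE,
    ConvolutionOperator,
    default_operator,
    fast_ridge_deconvolve,
)
from .whitening import apply_whitening, build_whitening_matrix, estimate_ar1, invert_whitening

logger = logging.getLogger(__name__)

#: Pipeline id -> (mean_center, whitening_inversion)
PIPELINE_FLAGS = {
    1: (False, False),
    2: (False, True),
    3: (True, False),
    4: (True, True),
}


@dataclass(eq=False)
class PsychRegressor:
    """Psychological (task) regressor.

    For a two-condition block design the values form a boxcar: task
    samples coded 1, baseline coded 0.  Any two-valued coding is
    accepted; both conditions must be represented.
    """

    values: np.ndarray
    onsets_s: list[float] | None = None
    durations_s: list[float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidArgumentError("psychological regressor must be a vector")
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("psychological regressor must be finite")
        levels = np.unique(v)
        if levels.size != 2:
            raise InvalidArgumentError(
                f"two-condition design requires exactly 2 distinct values, got {levels.size}"
            )
        self.values = v

    def __len__(self) -> int:
        return self.values.size


@dataclass(eq=False)
class NeuronalSeed:
    """Deconvolved, neuronal-level seed estimate (approximately zero mean)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise InvalidArgumentError("neuronal seed must be a finite vector")
        self.values = v


@dataclass(eq=False)
class InteractionRegressor:
    """The reconvolved psychological-by-neuronal product term."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise InvalidArgumentError("interaction regressor must be a finite vector")
        self.values = v


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-pipeline switches.

    Attributes
    ----------
    mean_center : bool
        Center the task regressor before forming the interaction product.
    whitening_inversion : bool
        Undo the extraction-stage prewhitening of the seed series.
    deconvolve : bool
        Form the interaction at the neuronal level (deconvolve, multiply,
        reconvolve).  Off gives the BOLD-level product variant.
    shrinkage : float
        Ridge penalty for deconvolution.
    highpass_cutoff : float
        High-pass filter period in seconds (``inf`` disables).
    """

    mean_center: bool
    whitening_inversion: bool
    deconvolve: bool = True
    shrinkage: float = DEFAULT_SHRINKAGE
    highpass_cutoff: float = 128.0

    @classmethod
    def from_pipeline(cls, pipeline_id: int, **overrides) -> "PipelineConfig":
        if pipeline_id not in PIPELINE_FLAGS:
            raise InvalidArgumentError(f"pipeline id must be 1-4, got {pipeline_id}")
        mc, wi = PIPELINE_FLAGS[pipeline_id]
        return cls(mean_center=mc, whitening_inversion=wi, **overrides)

    @property
    def pipeline_id(self) -> int:
        for pid, flags in PIPELINE_FLAGS.items():
            if flags == (self.mean_center, self.whitening_inversion):
                return pid
        raise AssertionError("unreachable")

    def to_dict(self) -> dict:
        return {
            "pipeline_id": self.pipeline_id,
            "mean_center": self.mean_center,
            "whitening_inversion": self.whitening_inversion,
            "deconvolve": self.deconvolve,
            "shrinkage": self.shrinkage,
            "highpass_cutoff": self.highpass_cutoff,
        }


@dataclass(eq=False)
class PpiDesign:
    """Assembled design matrix with fixed column order.

    Columns: interaction, seed main effect, psychological main effect,
    confounds (if any), intercept.
    """

    columns: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.columns, dtype=float)
        if c.ndim != 2:
            raise InvalidArgumentError("design must be a matrix")
        if len(self.labels) != c.shape[1]:
            raise InvalidArgumentError("label count must match column count")
        if self.labels.count("intercept") != 1:
            raise InvalidArgumentError("design must contain exactly one intercept")
        self.columns = c

    @property
    def n_scans(self) -> int:
        return self.columns.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.columns[:, self.labels.index(label)]


@dataclass(eq=False)
class FitResult:
    """Per-column GLM estimates from a prewhitened fit."""

    labels: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    residual_variance: float
    dof: int
    rho_used: float

    def coef(self, label: str) -> "Coefficient":
        i = self.labels.index(label)
        return Coefficient(
            label=label,
            beta=float(self.beta[i]),
            se=float(self.se[i]),
            t=float(self.t[i]),
            p=float(self.p[i]),
        )

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "coefficients": {
                lab: {
                    "beta": float(self.beta[i]),
                    "se": float(self.se[i]),
                    "t": float(self.t[i]),
                    "p": float(self.p[i]),
                }
                for i, lab in enumerate(self.labels)
            },
            "residual_variance": float(self.residual_variance),
            "dof": int(self.dof),
            "rho_used": float(self.rho_used),
        }


@dataclass(frozen=True)
class Coefficient:
    label: str
    beta: float
    se: float
    t: float
    p: float


def _nuisance_for_extraction(roi: RoiMatrix, confounds: BasisSet | None,
                             cutoff: float) -> np.ndarray:
    hp = dct_highpass_basis(roi.n_scans, roi.tr, cutoff)
    parts = [hp.columns]
    if confounds is not None and confounds.n_columns:
        if confounds.columns.shape[0] != roi.n_scans:
            raise InvalidArgumentError("confound rows must match ROI timepoints")
        parts.append(confounds.columns)
    return np.hstack(parts)


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    if x.shape[1] == 0:
        return y
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def extract_seed(roi: RoiMatrix, confounds: BasisSet | None, cfg: PipelineConfig,
                 force_rho: float | None = None) -> TimeSeries:
    """Extract the seed summary series from an ROI matrix, SPM-style.

    The sequence mirrors standard time-series extraction: build the
    high-pass basis, estimate an AR(1) model from the OLS nuisance
    residuals, whiten data and nuisance, residualize, and take the first
    eigenvariate.  When ``cfg.whitening_inversion`` is set, the same W is
    then inverted on the eigenvariate so the returned series carries the
    original (unwhitened) temporal structure.
    """
    seed, _ = _extract_seed_impl(roi, confounds, cfg, force_rho)
    return seed


def _extract_seed_impl(roi, confounds, cfg, force_rho):
    y = roi.values
    nuisance = _nuisance_for_extraction(roi, confounds, cfg.highpass_cutoff)
    if force_rho is not None:
        rho = float(force_rho)
    else:
        resid = _ols_residuals(y, nuisance)
        # demeaned for AR estimation only; the projector itself keeps the mean
        rho = estimate_ar1(resid - resid.mean(axis=0), demean=False).rho
    w = build_whitening_matrix(rho, roi.n_scans)
    yw = apply_whitening(w, y)
    if nuisance.shape[1]:
        nw = apply_whitening(w, nuisance)
        rw = _ols_residuals(yw, nw)
    else:
        rw = yw
    seed = first_eigenvariate(rw, tr=roi.tr)
    if cfg.whitening_inversion:
        seed = TimeSeries(invert_whitening(w, seed.values), roi.tr)
    logger.debug("seed extraction: rho=%.4f, inversion=%s", rho, cfg.whitening_inversion)
    return seed, rho


def build_interaction(xn: NeuronalSeed, psy: PsychRegressor, mean_center: bool,
                      operator: ConvolutionOperator) -> InteractionRegressor:
    """Form the (re)convolved interaction regressor.

    The neuronal-level product is ``(psy - c) * xn`` with ``c = mean(psy)``
    when ``mean_center`` is on and 0 otherwise; the product is then passed
    through the HRF convolution operator back to BOLD level.
    """
    x = xn.values if isinstance(xn, NeuronalSeed) else np.asarray(xn, float)
    pv = psy.values
    if pv.size != x.size:
        raise InvalidArgumentError("psy and neuronal seed lengths differ")
    c = pv.mean() if mean_center else 0.0
    product = (pv - c) * x
    return InteractionRegressor(operator.entries @ product)


def assemble_ppi_design(interaction: InteractionRegressor, seed_bold: TimeSeries,
                        psy: PsychRegressor, operator: ConvolutionOperator,
                        confounds: BasisSet | None = None) -> PpiDesign:
    """Stack the PPI design: [interaction, seed, psych, confounds..., intercept].

    The seed and the HRF-convolved psychological columns are demeaned
    (the intercept models the mean).  A constant column hiding in the
    confounds would duplicate the intercept and is rejected.
    """
    inter = _data(interaction)
    seed = _data(seed_bold)
    n = inter.size
    if seed.size != n or len(psy) != n:
        raise InvalidArgumentError("all regressors must share the same length")
    psych = operator.entries @ psy.values
    cols = [inter, seed - seed.mean(), psych - psych.mean()]
    labels = ["interaction", "seed", "psych"]
    if confounds is not None and confounds.n_columns:
        cc = confounds.columns
        if cc.shape[0] != n:
            raise InvalidArgumentError("confound rows must match series length")
        spans = np.ptp(cc, axis=0)
        maxima = np.max(np.abs(cc), axis=0)
        if np.any((spans < 1e-12) & (maxima > 1e-12)):
            raise InvalidArgumentError(
                "confounds contain a constant column; the intercept is added automatically"
            )
        cols.extend(cc.T)
        labels.extend(confounds.labels)
    cols.append(np.ones(n))
    labels.append("intercept")
    return PpiDesign(np.column_stack(cols), labels)


def _collinear_columns(xw: np.ndarray, labels: list[str]) -> list[str]:
    """Name columns that lie (numerically) in the span of the others."""
    bad = []
    for j in range(xw.shape[1]):
        others = np.delete(xw, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, xw[:, j], rcond=None)
        resid = xw[:, j] - others @ coef
        scale = np.linalg.norm(xw[:, j])
        if scale < 1e-12 or np.linalg.norm(resid) < 1e-8 * max(scale, 1.0):
            bad.append(labels[j])
    return bad or list(labels)


#: Fixed-point refinements of the AR(1) coefficient during fitting.
AR_REFINE_ITERS = 2


def _estimate_fit_rho(yv: np.ndarray, x: np.ndarray) -> float:
    """AR(1) coefficient for the whitened fit.

    The initial Yule-Walker estimate from OLS residuals is biased toward
    zero when the design contains smooth columns (they absorb
    low-frequency noise), which under-whitens and inflates t-statistics.
    A couple of fixed-point refinements drive the lag-1 autocorrelation of
    the *whitened* residuals to zero, composing successive AR filters via
    ``rho <- (rho + r) / (1 + rho * r)``.
    """
    resid = yv - x @ np.linalg.lstsq(x, yv, rcond=None)[0]
    if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(yv)):
        return 0.0  # (near-)exact fit: nothing to whiten
    rho = estimate_ar1(resid).rho
    for _ in range(AR_REFINE_ITERS):
        w = build_whitening_matrix(rho, yv.shape[0])
        xw = apply_whitening(w, x)
        yw = apply_whitening(w, yv)
        ew = yw - xw @ np.linalg.lstsq(xw, yw, rcond=None)[0]
        if np.linalg.norm(ew) < 1e-10 * max(1.0, np.linalg.norm(yw)):
            break
        r = estimate_ar1(ew).rho
        rho = float(np.clip((rho + r) / (1.0 + rho * r), -0.99, 0.99))
    return rho


def fit_glm_prewhitened(y, design: PpiDesign, force_rho: float | None = None) -> FitResult:
    """Fit a PPI design with AR(1) prewhitening.

    An OLS fit provides residuals for the initial AR(1) estimate (unless
    ``force_rho`` is given), which is refined so the whitened residuals
    are serially uncorrelated; data and design are then whitened and
    refit.  Standard errors come from ``(Xw' Xw)^-1`` scaled by the
    whitened residual variance; p-values are two-sided from the t
    distribution with ``T - rank(Xw)`` degrees of freedom.
    """
    yv = _data(y)
    x = design.columns
    n, p = x.shape
    if yv.shape[0] != n:
        raise InvalidArgumentError("response length must match design rows")
    if n <= p:
        raise InvalidArgumentError(f"need more timepoints ({n}) than columns ({p})")
    if "interaction" in design.labels:
        if np.max(np.abs(design.column("interaction"))) < 1e-12:
            raise DegenerateInputError(
                "interaction regressor is numerically zero; check task coding and seed"
            )
    rho = float(force_rho) if force_rho is not None else _estimate_fit_rho(yv, x)
    w = build_whitening_matrix(rho, n)
    xw = apply_whitening(w, x)
    yw = apply_whitening(w, yv)
    sv = np.linalg.svd(xw, compute_uv=False)
    tol = sv[0] * max(n, p) * np.finfo(float).eps
    rank = int(np.sum(sv > tol))
    if rank < p:
        bad = _collinear_columns(xw, design.labels)
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {', '.join(bad)}"
        )
    gram = xw.T @ xw
    beta = np.linalg.solve(gram, xw.T @ yw)
    resid = yw - xw @ beta
    dof = n - rank
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(gram)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return FitResult(
        labels=list(design.labels),
        beta=beta,
        se=se,
        t=t,
        p=pvals,
        residual_variance=sigma2,
        dof=dof,
        rho_used=rho,
    )


def run_ppi_subject(data, cfg: PipelineConfig, force_rho: float | None = None,
                    include_seed_target: bool = True) -> dict[str, FitResult]:
    """Run the full subject-level PPI pipeline and fit every target.

    Composes seed extraction, (optional) ridge deconvolution, interaction
    construction, design assembly, and the prewhitened GLM fit.  When
    ``include_seed_target`` is on, the mean series across ROI voxels is
    fitted under the key ``"seed"`` — the seed-location fit used by the
    misspecification diagnostic.

    Parameters
    ----------
    data : SubjectData
        Subject inputs (ROI matrix, targets, task regressor, confounds).
    cfg : PipelineConfig
        Pipeline switches; ``PipelineConfig.from_pipeline(4)`` is the
        correctly specified model.
    force_rho : float, optional
        Fix the AR(1) coefficient at extraction and fitting (testing aid).
    """
    roi = data.roi
    tr, n = roi.tr, roi.n_scans
    seed, rho_extract = _extract_seed_impl(roi, data.confounds, cfg, force_rho)
    operator = default_operator(tr, n)
    if cfg.deconvolve:
        if cfg.shrinkage > 0:
            z = fast_ridge_deconvolve(seed.values, tr, cfg.shrinkage)
        else:  # exact least squares; no cached factorization
            from .hemodynamics import DeconvolutionConfig, ridge_deconvolve

            z = ridge_deconvolve(seed.values, operator, DeconvolutionConfig(0.0))
        interaction = build_interaction(NeuronalSeed(z), data.psy, cfg.mean_center, operator)
    else:
        c = data.psy.values.mean() if cfg.mean_center else 0.0
        product = (data.psy.values - c) * (seed.values - seed.values.mean())
        interaction = InteractionRegressor(product)
    hp = dct_highpass_basis(n, tr, cfg.highpass_cutoff)
    design_confounds = concat_bases(data.confounds, hp)
    design = assemble_ppi_design(interaction, seed, data.psy, operator, design_confounds)
    targets = dict(data.targets)
    if include_seed_target:
        targets["seed"] = TimeSeries(roi.values.mean(axis=1), tr)
    logger.debug("subject fit: pipeline=%d rho_extract=%.4f targets=%s",
                 cfg.pipeline_id, rho_extract, sorted(targets))
    return {
        name: fit_glm_prewhitened(series, design, force_rho)
        for name, series in targets.items()
    }
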