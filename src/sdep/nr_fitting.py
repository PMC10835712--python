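"""Reduction of raw count curves and joint multi-contrast model fitting.

Reduction follows R(Q) = [I(Q) - I_B(Q)] / I_0(Q): the background under
the specular condition is the linear interpolation (mean) of the counts
at the two bracketing off-specular positions, and Poisson uncertainties
propagate in quadrature.  Negative net intensities are retained.

Fitting maximizes a joint Gaussian likelihood over all contrast
conditions — structural parameters shared, solvent nSLD free per
contrast — with uniform box priors, then samples the posterior with an
affine-invariant ensemble MCMC.  Convergence is assessed with the
split-chain potential scale reduction statistic (threshold 1.05).
Derived quantities such as the exclusion distance are computed per
posterior sample, never from point estimates alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InvalidInputError
from .reflectometry import (
    CompositionSpaceModel,
    ReflectivityCurve,
    exclusion_distance,
    reflectivity,
    smearing_matrix,
)
from .errors import ExclusionBelowResolutionError

__all__ = [
    "CountCurve",
    "FitResult",
    "reduce_counts",
    "ModelBuilder",
    "joint_fit",
    "exclusion_ci",
]

LN2 = float(np.log(2.0))


@dataclass
class CountCurve:
    """Raw (monitor-normalized) count data on a Q grid: specular counts,
    the two bracketing off-specular background counts, and the incident
    intensity measured through the substrate."""

    Q: np.ndarray
    specular: np.ndarray
    background_low: np.ndarray
    background_high: np.ndarray
    incident: np.ndarray
    dQ: Optional[np.ndarray] = None
    monitor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Q", "specular", "background_low", "background_high",
                     "incident"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.specular < 0) or np.any(self.background_low < 0) \
                or np.any(self.background_high < 0):
            raise InvalidInputError("counts must be non-negative")
        if np.any(self.incident < 0):
            raise InvalidInputError("incident intensity must be non-negative")
        if self.dQ is None:
            self.dQ = 0.025 * self.Q
        else:
            self.dQ = np.asarray(self.dQ, dtype=float)


def reduce_counts(curve: CountCurve) -> ReflectivityCurve:
    """Reduce counts to reflectivity, R = (I - I_B)/I_0.

    The background is the linear interpolation of the two bracketing
    off-specular intensities (their mean, for symmetric brackets);
    Poisson variances add in quadrature, including the incident-beam
    term.  Bins with I_0 = 0 are masked (dropped).
    """
    I = curve.specular
    I0 = curve.incident
    ib = 0.5 * (curve.background_low + curve.background_high)
    good = I0 > 0
    R = np.where(good, (I - ib) / np.where(good, I0, 1.0), np.nan)
    # Poisson: var(I) = I, var(ib) = (b_lo + b_hi)/4, var(I0) = I0;
    # a one-count floor keeps empty bins from claiming zero uncertainty
    var_num = np.maximum(
        I + 0.25 * (curve.background_low + curve.background_high), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dR = np.sqrt(var_num / I0**2 + (R**2) / I0)
    out = ReflectivityCurve.__new__(ReflectivityCurve)
    out.Q = curve.Q[good]
    out.R = R[good]
    out.dR = dR[good]
    out.dQ = curve.dQ[good]
    out.provenance = "reduced counts"
    return out


@dataclass
class FitResult:
    """Posterior summary of a joint fit.

    ``samples`` holds the post-burn-in, thinned posterior draws (one
    column per parameter); ``intervals`` maps parameter -> dict with
    median and central 68%/95% bounds; ``exclusion_samples`` is the
    per-sample exclusion distance (NaN where the sampled E_0 <= ln 2).
    """

    param_names: list[str]
    map_params: np.ndarray
    samples: pd.DataFrame
    chi2_per_curve: list[float]
    converged: bool
    rhat: float
    exclusion_samples: Optional[np.ndarray] = None
    exclusion_censored_fraction: float = 0.0

    def intervals(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in self.param_names:
            s = self.samples[name].to_numpy()
            q = np.percentile(s, [2.5, 16, 50, 84, 97.5])
            out[name] = {"lo95": q[0], "lo68": q[1], "median": q[2],
                         "hi68": q[3], "hi95": q[4]}
        return out


class ModelBuilder:
    """Maps a parameter vector to one CompositionSpaceModel per contrast.

    ``build(theta)`` must return a list of models, one per measured
    curve; ``bounds`` are the uniform prior boxes; ``peg_of(model)``
    gives access to the fitted polymer profile for derived quantities.
    """

    def __init__(self, build: Callable[[np.ndarray], list[CompositionSpaceModel]],
                 param_names: Sequence[str],
                 bounds: Sequence[tuple[float, float]]):
        self.build = build
        self.param_names = list(param_names)
        self.bounds = [tuple(b) for b in bounds]
        if len(self.param_names) != len(self.bounds):
            raise InvalidInputError("one bound per parameter required")


def _model_reflectivity(model: CompositionSpaceModel, Q_fine: np.ndarray,
                        z_span: tuple[float, float],
                        dz_A: float) -> np.ndarray:
    thick, slds, rough = model.slab_model(*z_span, dz_A=dz_A)
    return reflectivity(Q_fine, thick, slds, rough)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction, max over parameters.
    ``chains``: (n_walkers, n_steps, n_params)."""
    nw, ns, npar = chains.shape
    half = ns // 2
    segs = np.concatenate([chains[:, :half, :], chains[:, half:2 * half, :]],
                          axis=0)  # (2 nw, half, npar)
    m, n = segs.shape[0], segs.shape[1]
    means = segs.mean(axis=1)            # (m, npar)
    vars_ = segs.var(axis=1, ddof=1)     # (m, npar)
    W = vars_.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_post = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_post / W)
    return float(np.nanmax(rhat))


def joint_fit(builder: ModelBuilder,
              curves: Sequence[ReflectivityCurve],
              seed: int = 0,
              n_walkers: int = 24,
              n_steps: int = 400,
              burn_fraction: float = 0.5,
              thin: int = 2,
              dz_A: float = 1.0,
              z_span: Optional[tuple[float, float]] = None,
              oversample: int = 4,
              hydrophobic_origin: bool = True,
              rhat_threshold: float = 1.05,
              optimize_first: bool = True) -> FitResult:
    """Joint Gaussian-likelihood fit of all curves, then ensemble MCMC.

    The forward model is evaluated on an oversampled log-Q grid, smeared
    with each curve's dQ, and compared to the data; the likelihood is
    maximized first (trust-region least squares from the prior-box
    center), and the sampler is started in a small ball around the
    optimum.  If the split-chain statistic exceeds ``rhat_threshold`` the
    result is flagged unconverged and interval queries should be treated
    accordingly.
    """
    import emcee
    from scipy.optimize import least_squares

    rng = np.random.default_rng(seed)
    ndim = len(builder.param_names)
    lo = np.array([b[0] for b in builder.bounds])
    hi = np.array([b[1] for b in builder.bounds])

    if z_span is None:
        z_span = (-10.0, 160.0)

    # oversampled forward grid and per-curve smearing matrices
    fine, mats, datas = [], [], []
    for c in curves:
        qf = np.exp(np.linspace(np.log(c.Q[0] * 0.97),
                                np.log(c.Q[-1] * 1.03),
                                oversample * len(c.Q)))
        fine.append(qf)
        mats.append(smearing_matrix(c.Q, c.dQ, qf))
        datas.append((c.R, c.dR))

    def residuals(theta):
        models = builder.build(theta)
        res = []
        for model, qf, W, (R, dR) in zip(models, fine, mats, datas):
            Rm = W @ _model_reflectivity(model, qf, z_span, dz_A)
            res.append((Rm - R) / dR)
        return np.concatenate(res)

    def log_prob(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        try:
            r = residuals(theta)
        except (InvalidInputError, FloatingPointError):
            return -np.inf
        return -0.5 * float(np.dot(r, r))

    x0 = 0.5 * (lo + hi)
    cov = None
    if optimize_first:
        eps = 1e-6 * (hi - lo)
        sol = least_squares(residuals, x0, bounds=(lo + eps, hi - eps),
                            xtol=1e-10, ftol=1e-10)
        x_map = sol.x
        # Laplace approximation of the posterior covariance from the
        # Gauss-Newton Hessian; used to disperse the initial walkers so
        # short chains start essentially equilibrated
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj + 1e-10 * np.eye(ndim)
                                * np.trace(jtj) / ndim)
        except np.linalg.LinAlgError:
            cov = None
    else:
        x_map = x0

    moves = [(emcee.moves.DEMove(), 0.8),
             (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, moves=moves)
    if cov is not None:
        # mildly under-dispersed start on the Laplace ellipsoid; the
        # differential-evolution moves then explore the curved ridges
        p0 = rng.multivariate_normal(x_map, 0.3 * cov, size=n_walkers,
                                     method="svd")
    else:
        p0 = x_map + 1e-3 * (hi - lo) \
            * rng.standard_normal((n_walkers, ndim))
    p0 = np.clip(p0, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)

    burn = int(burn_fraction * n_steps)
    chain = sampler.get_chain()[burn:]          # (steps, walkers, ndim)
    rhat = _split_rhat(np.moveaxis(chain, 0, 1))
    flat = chain[::thin].reshape(-1, ndim)
    samples = pd.DataFrame(flat, columns=builder.param_names)

    # per-curve goodness of fit at the MAP
    models = builder.build(x_map)
    chi2 = []
    for model, qf, W, (R, dR), c in zip(models, fine, mats, datas, curves):
        Rm = W @ _model_reflectivity(model, qf, z_span, dz_A)
        chi2.append(float(np.sum(((Rm - R) / dR) ** 2) / len(R)))

    # derived exclusion distance per posterior sample
    excl = np.full(len(flat), np.nan)
    for i, theta in enumerate(flat):
        model = builder.build(theta)[0]
        if model.peg is None:
            continue
        try:
            excl[i] = exclusion_distance(
                model.peg,
                model.hydrophobic_interface_A if hydrophobic_origin else 0.0)
        except ExclusionBelowResolutionError:
            pass
    censored = float(np.mean(~np.isfinite(excl))) if len(excl) else 1.0

    return FitResult(param_names=builder.param_names, map_params=x_map,
                     samples=samples, chi2_per_curve=chi2,
                     converged=bool(rhat < rhat_threshold), rhat=rhat,
                     exclusion_samples=excl,
                     exclusion_censored_fraction=censored)


def exclusion_ci(result: FitResult) -> dict[str, float | bool]:
    """Median and central 68%/95% intervals of the posterior exclusion
    distance (Å), in the m_-a^+b convention of the summary tables.

    If more than half of the posterior samples have E_0 <= ln 2 (no
    half-density crossing), the interval is flagged censored.
    """
    if result.exclusion_samples is None:
        raise InvalidInputError("fit result carries no exclusion samples")
    excl = result.exclusion_samples
    finite = excl[np.isfinite(excl)]
    censored = result.exclusion_censored_fraction > 0.5
    if len(finite) == 0:
        return {"median": float("nan"), "minus68": float("nan"),
                "plus68": float("nan"), "minus95": float("nan"),
                "plus95": float("nan"), "censored": True}
    q = np.percentile(finite, [2.5, 16, 50, 84, 97.5])
    return {
        "median": float(q[2]),
        "minus68": float(q[2] - q[1]),
        "plus68": float(q[3] - q[2]),
        "minus95": float(q[2] - q[0]),
        "plus95": float(q[4] - q[2]),
        "censored": bool(censored),
    }
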