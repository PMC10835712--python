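"""Post-processing of polymer density / potential-of-mean-force profiles.

Mass-fraction profiles m(z) from simulations (or the synthetic generator)
are converted to free energy via E(z) = -ln[m(z)/m(∞)]; the profile near
a neutral membrane is subtracted from that near a charged membrane to
isolate the dielectrophoretic + counterion-pressure contribution ΔE(z),
which theory predicts decays as exp(-2κz).  A weighted log-linear fit
extracts the decay length (κ⁻¹/2 expected), the amplitude, and the
distance d at which ΔE crosses 1 k_BT; profiles of several molecular
weights give the power-law exponent of ΔE against the hydrodynamic
radius (3 expected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError, NoCrossingError, NumericalError

__all__ = [
    "DensityProfile",
    "DecayFit",
    "massfrac_to_energy",
    "delta_energy",
    "fit_decay",
    "size_scaling",
]


@dataclass
class DensityProfile:
    """A profile on an ascending z grid (Å): mass fraction or free energy
    (k_BT) with optional 1-σ uncertainties.  Censored bins (e.g. where a
    mass fraction of zero maps to infinite energy) are flagged in
    ``censored``."""

    z_A: np.ndarray
    values: np.ndarray
    sigma: Optional[np.ndarray] = None
    kind: str = "mass_fraction"
    censored: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.z_A = np.asarray(self.z_A, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.z_A) <= 0):
            raise InvalidInputError("z grid must be strictly ascending")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.z_A):
                raise InvalidInputError("sigma length mismatch")
        if self.kind == "mass_fraction" and np.any(
                self.values[np.isfinite(self.values)] < 0):
            raise InvalidInputError("mass fractions must be non-negative")
        if self.censored is None:
            self.censored = np.zeros(len(self.z_A), dtype=bool)

    def to_text(self, path) -> None:
        sig = self.sigma if self.sigma is not None \
            else np.zeros_like(self.values)
        np.savetxt(path, np.column_stack([self.z_A, self.values, sig]),
                   header=f"kind: {self.kind}\ncolumns: z_A value sigma")

    @classmethod
    def from_text(cls, path, kind: str = "mass_fraction") -> "DensityProfile":
        data = np.loadtxt(path, comments="#")
        sigma = data[:, 2] if data.shape[1] > 2 else None
        return cls(z_A=data[:, 0], values=data[:, 1], sigma=sigma, kind=kind)


def massfrac_to_energy(profile: DensityProfile,
                       bulk_window: Optional[tuple[float, float]] = None
                       ) -> DensityProfile:
    """Convert a mass-fraction profile to free energy,
    E(z) = -ln[m(z)/m(∞)] in k_BT.

    m(∞) is the average over ``bulk_window`` (z range, Å); the default
    window is the outermost 20% of the grid, where the profile is
    expected to be uniform.  Bins with m = 0 become +inf and are flagged
    censored.  Uncertainties propagate as σ_E = σ_m/m.
    """
    if profile.kind != "mass_fraction":
        raise InvalidInputError("input profile must be a mass fraction")
    z, m = profile.z_A, profile.values
    if bulk_window is None:
        z_lo = z[0] + 0.8 * (z[-1] - z[0])
        bulk_window = (z_lo, z[-1])
    in_bulk = (z >= bulk_window[0]) & (z <= bulk_window[1])
    if not np.any(in_bulk):
        raise InvalidInputError("bulk window contains no grid points")
    m_inf = float(np.mean(m[in_bulk]))
    if not m_inf > 0:
        raise InvalidInputError("bulk mass fraction average must be positive")
    with np.errstate(divide="ignore"):
        e = -np.log(m / m_inf)
    censored = ~np.isfinite(e)
    sigma = None
    if profile.sigma is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma = np.where(m > 0, profile.sigma / m, np.inf)
    return DensityProfile(z_A=z.copy(), values=e, sigma=sigma,
                          kind="free_energy", censored=censored)


def energy_to_massfrac(profile: DensityProfile,
                       m_inf: float = 1.0) -> DensityProfile:
    """Inverse of :func:`massfrac_to_energy` (up to the bulk scale)."""
    if profile.kind != "free_energy":
        raise InvalidInputError("input profile must be a free energy")
    m = m_inf * np.exp(-profile.values)
    sigma = None
    if profile.sigma is not None:
        sigma = np.where(np.isfinite(m), m * profile.sigma, np.nan)
    return DensityProfile(z_A=profile.z_A.copy(), values=m, sigma=sigma,
                          kind="mass_fraction")


def delta_energy(charged: DensityProfile,
                 neutral: DensityProfile) -> DensityProfile:
    """ΔE(z) = E_charged(z) - E_neutral(z) on the intersection grid.

    The neutral-membrane profile carries every contribution that is
    already present without surface charge (sterics, chain confinement),
    so the difference isolates the charge-induced repulsion.  Profiles
    are linearly interpolated onto the overlapping z range; uncertainties
    add in quadrature.
    """
    for p in (charged, neutral):
        if p.kind != "free_energy":
            raise InvalidInputError("both profiles must be free energies")
    lo = max(charged.z_A[0], neutral.z_A[0])
    hi = min(charged.z_A[-1], neutral.z_A[-1])
    if not hi > lo:
        raise InvalidInputError("profiles have disjoint z ranges")
    base = charged.z_A[(charged.z_A >= lo) & (charged.z_A <= hi)]
    with np.errstate(invalid="ignore"):
        ec = np.interp(base, charged.z_A, charged.values)
        en = np.interp(base, neutral.z_A, neutral.values)
    sigma = None
    if charged.sigma is not None and neutral.sigma is not None:
        sc = np.interp(base, charged.z_A, charged.sigma)
        sn = np.interp(base, neutral.z_A, neutral.sigma)
        sigma = np.sqrt(sc**2 + sn**2)
    with np.errstate(invalid="ignore"):
        diff = ec - en
    return DensityProfile(z_A=base, values=diff, sigma=sigma,
                          kind="free_energy")


@dataclass
class DecayFit:
    """Result of an exponential-decay fit ΔE(z) = A exp(-z/λ)."""

    amplitude_kT: float
    decay_length_A: float
    threshold_distance_A: float
    amplitude_err: float
    decay_length_err: float
    threshold_distance_err: float
    n_points: int
    window_A: tuple[float, float]


def fit_decay(profile: DensityProfile,
              fit_window: Optional[tuple[float, float]] = None,
              r_h_A: Optional[float] = None,
              threshold_kT: float = 1.0,
              min_points: int = 5) -> DecayFit:
    """Weighted least squares of log ΔE against z.

    The default window starts at R_h + 2 Å (past the contact regime where
    the exponential form fails; the grid start if R_h is not given) and
    ends where ΔE first falls below 0.1 k_BT.  Non-positive values inside
    the window are dropped with a warning; fewer than ``min_points``
    survivors is an error.  Weights are (value/σ)² where uncertainties
    are available (the variance of log ΔE), else uniform.  The threshold
    distance d solves A exp(-d/λ) = threshold; its uncertainty follows
    from the fit covariance.
    """
    import warnings

    z, v = profile.z_A, profile.values
    if fit_window is None:
        z_lo = z[0] if r_h_A is None else r_h_A + 2.0
        below = z[(v < 0.1) & (z > z_lo)]
        z_hi = float(below[0]) if len(below) else float(z[-1])
        fit_window = (float(z_lo), z_hi)
    sel = (z >= fit_window[0]) & (z <= fit_window[1]) & np.isfinite(v)
    if np.any(sel & (v <= 0)):
        warnings.warn("non-positive values in fit window dropped",
                      stacklevel=2)
        sel &= v > 0
    if sel.sum() < min_points:
        raise NumericalError(
            f"only {int(sel.sum())} usable points in the fit window "
            f"{fit_window}; at least {min_points} required")
    zz, vv = z[sel], v[sel]
    logv = np.log(vv)
    if profile.sigma is not None and np.all(profile.sigma[sel] > 0):
        w = (vv / profile.sigma[sel]) ** 2
    else:  # exact (noise-free) or missing uncertainties: uniform weights
        w = np.ones_like(vv)
    # weighted linear LS: logv = b0 + b1 z
    W = np.diag(w)
    X = np.column_stack([np.ones_like(zz), zz])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ logv)
    b0, b1 = beta
    if b1 >= 0:
        raise NumericalError("fitted profile does not decay with z")
    lam = -1.0 / b1
    A = float(np.exp(b0))
    # d solves b0 + b1 d = ln(threshold)
    d = (np.log(threshold_kT) - b0) / b1
    # gradient of d wrt (b0, b1)
    g = np.array([-1.0 / b1, -(np.log(threshold_kT) - b0) / b1**2])
    d_err = float(np.sqrt(g @ cov @ g))
    a_err = float(A * np.sqrt(cov[0, 0]))
    lam_err = float(np.sqrt(cov[1, 1]) / b1**2)
    return DecayFit(amplitude_kT=A, decay_length_A=float(lam),
                    threshold_distance_A=float(d), amplitude_err=a_err,
                    decay_length_err=lam_err, threshold_distance_err=d_err,
                    n_points=int(sel.sum()), window_A=fit_window)


def size_scaling(profiles: dict[float, DensityProfile],
                 radii_A: dict[float, float],
                 z_eval_A: float) -> tuple[float, float]:
    """Power-law exponent of ΔE(z_eval) against hydrodynamic radius.

    ``profiles`` maps molecular weight -> ΔE profile, ``radii_A`` maps
    molecular weight -> R_h.  Returns (slope, standard error) of
    log ΔE vs log R_h; the closed-form theory gives exactly 3.
    """
    if len(profiles) < 3:
        raise InvalidInputError("at least 3 molecular weights required")
    logs_r, logs_e = [], []
    for mw, prof in sorted(profiles.items()):
        val = float(np.interp(z_eval_A, prof.z_A, prof.values))
        if val <= 0:
            raise InvalidInputError(
                f"ΔE at z={z_eval_A} Å non-positive for MW {mw}")
        logs_r.append(np.log(radii_A[mw]))
        logs_e.append(np.log(val))
    x = np.asarray(logs_r)
    y = np.asarray(logs_e)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    resid = y - (ym + slope * (x - xm))
    if n > 2:
        se = float(np.sqrt(np.sum(resid**2) / (n - 2) / sxx))
    else:
        se = 0.0
    return slope, se
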