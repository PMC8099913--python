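"""Isothermal extraction of Kd from fraction-unfolded vs ligand concentration.

At a fixed temperature the coupled folding/binding equilibria give

    f_u([L]_0) = K_U / (K_U + 1 + [L]_free / K_d),

with the free-ligand concentration from the 1:1 mass balance.  Fitting
this model to the f_u values of a dilution series yields Kd and the
ligand-free unfolding constant K_U at that temperature.  Scanning a grid
of temperatures and keeping the one with the smallest relative Kd fitting
error selects the best-determined estimate, which typically lies near the
apo melting temperature where the f_u dynamic range is largest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .curves import BindingStudy
from .fitting import GlobalFitResult, fu_profile
from .thermo import free_ligand

__all__ = [
    "BindingFit",
    "IsothermalResult",
    "NoConvergenceError",
    "fit_binding_isothermal",
    "scan_temperatures",
]

#: Minimum ligand-dependent spread in f_u below which no thermal shift is
#: considered detectable.
MIN_FU_SPREAD = 0.02

_LKD_BOUNDS = (-12.0, 1.0)   # Kd in [1e-12, 10] M
_LKU_BOUNDS = (-7.0, 7.0)


class NoConvergenceError(RuntimeError):
    """No scanned temperature produced a converged binding fit."""

    def __init__(self, message, diagnostics: pd.DataFrame | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class BindingFit:
    """1:1 binding fit of f_u vs [L]_0 at one temperature."""

    t_celsius: float
    kd: float
    ku: float
    kd_stderr: float
    ku_stderr: float
    kd_rel_error_pct: float
    converged: bool
    flag: str = ""
    n_points: int = 0
    residual_norm: float = float("nan")
    fu_table: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class IsothermalResult:
    """Temperature scan of isothermal binding fits.

    ``table`` has one row per scanned temperature; ``t_sel`` is the scanned
    temperature with the smallest relative Kd fitting error among converged
    fits, and ``best`` the corresponding fit.
    """

    fits: list[BindingFit]
    t_sel: float
    best: BindingFit

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_C": [f.t_celsius for f in self.fits],
                "Kd_M": [f.kd for f in self.fits],
                "Kd_stderr_M": [f.kd_stderr for f in self.fits],
                "Kd_rel_error_pct": [f.kd_rel_error_pct for f in self.fits],
                "Ku": [f.ku for f in self.fits],
                "Ku_stderr": [f.ku_stderr for f in self.fits],
                "converged": [f.converged for f in self.fits],
                "flag": [f.flag for f in self.fits],
            }
        )

    def summary(self) -> dict:
        return {
            "T_sel_C": self.t_sel,
            "Kd_M": self.best.kd,
            "Kd_stderr_M": self.best.kd_stderr,
            "Kd_rel_error_pct": self.best.kd_rel_error_pct,
            "Ku": self.best.ku,
        }


def _fu_model(l0, p0, lkd, lku):
    kd = 10.0 ** lkd
    ku = 10.0 ** lku
    lfree = free_ligand(l0, p0, ku, kd)
    return ku / (ku + 1.0 + lfree / kd)


def fit_binding_isothermal(
    l0,
    fu,
    p0: float,
    t_celsius: float = float("nan"),
    fu_err=None,
    use_weights: bool = False,
) -> BindingFit:
    """Fit Kd and Ku to a fraction-unfolded dilution series.

    Both constants are fitted on a log10 scale for conditioning: Ku starts
    from the apo point's f_u (f_u/(1-f_u), clipped to [1e-4, 1e4]) and Kd
    from the geometric mean of the nonzero ligand concentrations.  Standard
    errors come from the covariance diagonal, back-transformed to linear
    scale; the relative error is 100 * stderr / estimate.
    """
    l0 = np.asarray(l0, dtype=float)
    fu = np.asarray(fu, dtype=float)
    if l0.shape != fu.shape or l0.ndim != 1:
        raise ValueError("l0 and fu must be 1-D arrays of equal length")
    nonzero = l0[l0 > 0]
    if len(np.unique(l0)) < 5 or nonzero.size == 0:
        raise ValueError("need >= 5 distinct ligand concentrations")
    if nonzero.max() / nonzero.min() < 100:
        raise ValueError("ligand concentrations must span >= 2 decades")
    if np.any((fu < -1e-9) | (fu > 1 + 1e-9)):
        raise ValueError("fu values must lie in [0, 1]")
    fu = np.clip(fu, 0.0, 1.0)

    def result(kd, ku, kd_err, ku_err, converged, flag, rnorm=float("nan")):
        rel = 100.0 * kd_err / kd if kd > 0 and np.isfinite(kd_err) else float("nan")
        return BindingFit(
            t_celsius=t_celsius, kd=kd, ku=ku, kd_stderr=kd_err, ku_stderr=ku_err,
            kd_rel_error_pct=rel, converged=converged, flag=flag,
            n_points=len(l0), residual_norm=rnorm,
            fu_table=pd.DataFrame({"L0_M": l0, "fu": fu}),
        )

    if float(fu.max() - fu.min()) < MIN_FU_SPREAD:
        return result(float("nan"), float("nan"), float("nan"), float("nan"),
                      False, "no shift detected")

    apo = np.flatnonzero(l0 == 0)
    if apo.size:
        fu0 = float(np.clip(fu[apo[0]], 1e-6, 1 - 1e-6))
        ku0 = float(np.clip(fu0 / (1.0 - fu0), 1e-4, 1e4))
    else:
        fu_hi = float(np.clip(fu[np.argmin(l0)], 1e-6, 1 - 1e-6))
        ku0 = float(np.clip(fu_hi / (1.0 - fu_hi), 1e-4, 1e4))
    lkd0 = float(np.clip(np.log10(nonzero).mean(), *_LKD_BOUNDS))
    lku0 = float(np.clip(np.log10(ku0), *_LKU_BOUNDS))

    if use_weights and fu_err is not None:
        w = 1.0 / np.clip(np.asarray(fu_err, dtype=float), 1e-6, np.inf)
        w /= w.mean()
    else:
        w = np.ones_like(fu)

    def resid(x):
        return w * (_fu_model(l0, p0, x[0], x[1]) - fu)

    res = least_squares(
        resid, np.array([lkd0, lku0]),
        bounds=(np.array([_LKD_BOUNDS[0], _LKU_BOUNDS[0]]),
                np.array([_LKD_BOUNDS[1], _LKU_BOUNDS[1]])),
        method="trf", x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12,
        max_nfev=2000,
    )
    lkd, lku = res.x
    kd, ku = 10.0 ** lkd, 10.0 ** lku

    from .fitting import _stderr_from_jac  # shared covariance helper

    err = _stderr_from_jac(res.jac, res.cost, len(l0))
    ln10 = np.log(10.0)
    kd_err = kd * ln10 * err[0]
    ku_err = ku * ln10 * err[1]

    flags = []
    converged = bool(res.success)
    if not res.success:
        flags.append(f"optimizer failure: {res.message}")
    edge = 1e-6
    if (lkd - _LKD_BOUNDS[0] < edge or _LKD_BOUNDS[1] - lkd < edge
            or lku - _LKU_BOUNDS[0] < edge or _LKU_BOUNDS[1] - lku < edge):
        converged = False
        flags.append("fit hit a parameter bound")
    if not np.isfinite(kd_err):
        flags.append("singular covariance: errors undefined")
    rel = 100.0 * kd_err / kd
    if np.isfinite(rel) and rel > 100.0:
        # Kd indistinguishable from zero at one sigma: not a usable estimate
        converged = False
        flags.append("relative Kd error exceeds 100%")

    return result(float(kd), float(ku), float(kd_err), float(ku_err),
                  converged, "; ".join(flags), float(np.sqrt(2.0 * res.cost)))


def scan_temperatures(
    fit: GlobalFitResult,
    study: BindingStudy,
    t_grid_celsius,
    use_weights: bool = False,
) -> IsothermalResult:
    """Run the isothermal binding fit on a grid of temperatures.

    The selected temperature T_sel is the argmin of the relative Kd fitting
    error over the converged fits — the numerical fit error serves as the
    quality criterion for where the affinity is best determined.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid_celsius, dtype=float))
    lo, hi = fit.window
    if np.any(t_grid < lo) or np.any(t_grid > hi):
        raise ValueError("temperature grid extends outside the analysis window")

    fits = []
    for t in t_grid:
        prof = fu_profile(fit, float(t))
        bf = fit_binding_isothermal(
            prof["L0_M"].to_numpy(), prof["fu"].to_numpy(), study.p0,
            t_celsius=float(t), fu_err=prof["fu_err"].to_numpy(),
            use_weights=use_weights,
        )
        bf.fu_table = prof
        fits.append(bf)

    ok = [f for f in fits if f.converged and np.isfinite(f.kd_rel_error_pct)]
    if not ok:
        table = pd.DataFrame(
            {"T_C": [f.t_celsius for f in fits], "flag": [f.flag for f in fits]}
        )
        raise NoConvergenceError(
            "no temperature produced a converged isothermal binding fit", table
        )
    best = min(ok, key=lambda f: f.kd_rel_error_pct)
    return IsothermalResult(fits=fits, t_sel=best.t_celsius, best=best)
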