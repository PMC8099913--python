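"""Apparent binding affinities from melting-temperature shifts.

Two dose-response models for Tm vs total ligand concentration are provided
for comparison with the isothermal analysis:

* **Model 1** — an empirical single-site interpolation between the unbound
  melting temperature and a hypothetical upper plateau, driven by the exact
  1:1 bound-protein fraction.  It has no physico-chemical foundation (a Kd
  is only defined at a fixed temperature, and Tm does not converge to a
  plateau); results carry a warning and should not be reported as binding
  affinities.

* **Model 2** — a thermodynamic Tm-shift expression derived from the
  stabilization free energy RT ln(1 + [L]_0/K_d), with the apo melting
  temperature Tm0 and enthalpy ΔH(Tm0) taken from the apo curve fit.  It
  approximates the free ligand by the total ligand, which degrades for
  tight binders ([L]_0 comparable to K_d and protein in excess).

Temperatures are strictly Kelvin inside both models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .fitting import GlobalFitResult, _stderr_from_jac
from .thermo import R_KCAL

__all__ = ["TmSeries", "ApparentKdResult", "fit_model1", "fit_model2"]

MODEL1_WARNING = (
    "model 1 is an empirical interpolation with no physico-chemical "
    "foundation; do not report its Kd,app as a binding affinity"
)

_LKD_BOUNDS = (-12.0, 1.0)


@dataclass
class TmSeries:
    """(L0, Tm) pairs with Tm uncertainties, plus the protein concentration."""

    l0: np.ndarray        # M
    tm: np.ndarray        # K
    tm_err: np.ndarray    # K
    p0: float

    def __post_init__(self):
        self.l0 = np.asarray(self.l0, dtype=float)
        self.tm = np.asarray(self.tm, dtype=float)
        self.tm_err = np.asarray(self.tm_err, dtype=float)
        if not (self.l0.shape == self.tm.shape == self.tm_err.shape):
            raise ValueError("l0, tm and tm_err must have matching shapes")
        if len(self.l0) < 4:
            raise ValueError("need at least 4 (L0, Tm) points")
        if np.count_nonzero(self.l0 == 0) != 1:
            raise ValueError("series must contain exactly one apo (L0 = 0) point")
        if self.p0 <= 0:
            raise ValueError("p0 must be positive")
        if np.any(self.tm < 200):
            raise ValueError("tm looks like °C; TmSeries requires Kelvin")

    @classmethod
    def from_global_fit(cls, fit: GlobalFitResult, p0: float) -> "TmSeries":
        return cls(l0=fit.l0.copy(), tm=fit.tm.copy(), tm_err=fit.tm_err.copy(),
                   p0=p0)

    @property
    def apo_index(self) -> int:
        return int(np.flatnonzero(self.l0 == 0)[0])


@dataclass
class ApparentKdResult:
    """Apparent Kd from a Tm-shift fit, with model-specific parameters."""

    model: int
    kd_app: float          # M
    kd_stderr: float       # M
    kd_rel_error_pct: float
    params: dict
    residual_norm: float
    converged: bool
    warning: str = ""


def _bound_protein_fraction(l0, p0, kd):
    """Bound fraction [PL]/[P]0 from the exact 1:1 quadratic (no unfolding)."""
    return 1.0 - _free_protein_fraction(l0, p0, kd)


def _free_protein_fraction(l0, p0, kd):
    # positive root of the 1:1 quadratic, rationalized in the regime where
    # (p0 - kd - l0 + disc) suffers cancellation (weak binding / excess ligand)
    l0 = np.asarray(l0, dtype=float)
    b = p0 - kd - l0
    disc = np.sqrt((p0 - l0 + kd) ** 2 + 4.0 * kd * l0)
    direct = (b + disc) / (2.0 * p0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stable = 2.0 * kd / (disc - b)
    return np.clip(np.where(b > 0, direct, stable), 0.0, 1.0)


def model1_tm(l0, p0, tm_unbound, tm_upper, kd):
    """Model-1 dose response: Tm interpolated by the bound fraction."""
    return tm_unbound + (tm_upper - tm_unbound) * _bound_protein_fraction(l0, p0, kd)


def model2_tm(l0, tm0, dh0, kd):
    """Model-2 dose response: Tm([L]0) = Tm0 / (1 - (R Tm0/ΔH0) ln(1+[L]0/Kd))."""
    denom = 1.0 - (R_KCAL * tm0 / dh0) * np.log1p(np.asarray(l0, dtype=float) / kd)
    if np.any(denom <= 0):
        raise FloatingPointError("model 2 denominator non-positive")
    return tm0 / denom


def fit_model1(series: TmSeries) -> ApparentKdResult:
    """Fit (Tm_unbound, Tm_upper, Kd) of the empirical single-site model."""
    l0, tm, p0 = series.l0, series.tm, series.p0
    tm_lo0 = float(tm[series.apo_index])
    span = float(tm.max() - tm.min())
    tm_hi0 = float(tm.max() + 0.1 * max(span, 1.0))
    lkd0 = float(np.clip(np.log10(l0[l0 > 0]).mean(), *_LKD_BOUNDS))
    x0 = np.array([tm_lo0, tm_hi0, lkd0])
    lo = [tm.min() - 50.0, tm.min() - 50.0, _LKD_BOUNDS[0]]
    hi = [tm.max() + 100.0, tm.max() + 100.0, _LKD_BOUNDS[1]]

    def resid(x):
        return model1_tm(l0, p0, x[0], x[1], 10.0 ** x[2]) - tm

    res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12,
                        max_nfev=5000)
    tm_unbound, tm_upper, lkd = res.x
    kd = 10.0 ** lkd
    err = _stderr_from_jac(res.jac, res.cost, len(l0))
    kd_err = kd * np.log(10.0) * err[2]
    rel = 100.0 * kd_err / kd if np.isfinite(kd_err) else float("nan")
    return ApparentKdResult(
        model=1, kd_app=float(kd), kd_stderr=float(kd_err),
        kd_rel_error_pct=float(rel),
        params={"tm_unbound_K": float(tm_unbound), "tm_upper_K": float(tm_upper),
                "tm_unbound_err_K": float(err[0]), "tm_upper_err_K": float(err[1])},
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=bool(res.success),
        warning=MODEL1_WARNING,
    )


def fit_model2(
    series: TmSeries,
    dh0: float,
    tm0: float | None = None,
    co_fit_apo: bool = False,
) -> ApparentKdResult:
    """Fit the thermodynamic Tm-shift model.

    By default only Kd is free; ``tm0`` (apo melting temperature, K;
    defaults to the series' apo point) and ``dh0`` (apo unfolding enthalpy,
    kcal/mol) are fixed, which avoids a 3-parameter fit on few points.
    ``co_fit_apo=True`` releases both.
    """
    l0, tm = series.l0, series.tm
    if tm0 is None:
        tm0 = float(tm[series.apo_index])
    if dh0 <= 0:
        raise ValueError("dh0 must be positive")

    lkd0 = float(np.clip(np.log10(l0[l0 > 0]).mean(), *_LKD_BOUNDS))

    if co_fit_apo:
        x0 = np.array([lkd0, tm0, dh0])
        lo = [_LKD_BOUNDS[0], tm0 - 30.0, 1.0]
        hi = [_LKD_BOUNDS[1], tm0 + 30.0, 1000.0]

        def resid(x):
            try:
                return model2_tm(l0, x[1], x[2], 10.0 ** x[0]) - tm
            except FloatingPointError:
                return np.full_like(tm, 1e6)
    else:
        x0 = np.array([lkd0])
        lo, hi = [_LKD_BOUNDS[0]], [_LKD_BOUNDS[1]]

        def resid(x):
            try:
                return model2_tm(l0, tm0, dh0, 10.0 ** x[0]) - tm
            except FloatingPointError:
                return np.full_like(tm, 1e6)

    res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12,
                        max_nfev=5000)
    lkd = res.x[0]
    kd = 10.0 ** lkd
    err = _stderr_from_jac(res.jac, res.cost, len(l0))
    kd_err = kd * np.log(10.0) * err[0]
    rel = 100.0 * kd_err / kd if np.isfinite(kd_err) else float("nan")
    params = {"tm0_K": float(res.x[1]) if co_fit_apo else float(tm0),
              "dh0_kcal_mol": float(res.x[2]) if co_fit_apo else float(dh0),
              "co_fit_apo": co_fit_apo}
    return ApparentKdResult(
        model=2, kd_app=float(kd), kd_stderr=float(kd_err),
        kd_rel_error_pct=float(rel), params=params,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=bool(res.success),
        warning="model 2 approximates free ligand by total ligand; expect "
                "deviations for sub-µM affinities",
    )
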