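"""Local and global least-squares fitting of thermal unfolding curves.

Each curve is modelled as a two-state transition between linear baselines,

    Y(T) = f_u(T) (mu T + bu) + (1 - f_u(T)) (mf T + bf),

with f_u obtained from the Gibbs energy of unfolding parameterized by the
per-curve melting temperature Tm and enthalpy ΔH plus a study-wide heat
capacity change ΔCp.  In a binding study the ligand shifts each curve's
apparent (Tm, ΔH); the ligand term itself is never part of the curve model
— it re-enters later through the isothermal binding fit.

The local fit treats one curve at a time with six free parameters
(Tm, ΔH, mf, bf, mu, bu).  The global fit then ties the baseline slopes
(and optionally ΔCp) across all curves, which stabilizes the baselines of
curves whose transition sits near the window edge.  Both fits run a bounded
trust-region least-squares with analytic Jacobians; parameter standard
errors come from the diagonal of the residual-variance-scaled covariance
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .curves import BindingStudy, MeltingCurve
from .thermo import R_KCAL, BaselineParams, ThermoParams, celsius_to_kelvin

__all__ = [
    "LocalFitResult",
    "GlobalFitResult",
    "fit_local",
    "fit_global",
    "fu_profile",
    "DH_BOUNDS",
    "DCP_BOUNDS",
]

logger = logging.getLogger(__name__)

#: Bounds for the unfolding enthalpy in kcal/mol ("positive" with a
#: generous physical ceiling).
DH_BOUNDS = (1e-6, 1000.0)

#: Default bounds for a fitted heat-capacity change, kcal/(mol K).
#: Negative ΔCp is excluded by default; pass custom bounds to override.
DCP_BOUNDS = (0.0, 20.0)

_LSQ_OPTS = dict(method="trf", x_scale="jac", ftol=1e-10, xtol=1e-10,
                 gtol=1e-10, max_nfev=5000)

MIN_WINDOW_POINTS = 8


def _two_state_parts(tk, tm, dh, dcp):
    """Return (fu, dfu_ddg, ddg_dtm, ddg_ddh, ddg_ddcp) on grid ``tk``."""
    log_ratio = np.log(tk / tm)
    dg = dh * (1.0 - tk / tm) + dcp * (tk - tm - tk * log_ratio)
    u = dg / (R_KCAL * tk)
    # logistic; expit(-u)
    fu = 1.0 / (1.0 + np.exp(np.clip(u, -500, 500)))
    dfu_ddg = -fu * (1.0 - fu) / (R_KCAL * tk)
    ddg_dtm = dh * tk / tm**2 + dcp * (tk / tm - 1.0)
    ddg_ddh = 1.0 - tk / tm
    ddg_ddcp = tk - tm - tk * log_ratio
    return fu, dfu_ddg, ddg_dtm, ddg_ddh, ddg_ddcp


def _model_and_jac(tk, tm, dh, bf, bu, mf, mu, dcp, want_dcp_grad=False):
    fu, dfu_ddg, ddg_dtm, ddg_ddh, ddg_ddcp = _two_state_parts(tk, tm, dh, dcp)
    folded = mf * tk + bf
    unfolded = mu * tk + bu
    y = fu * unfolded + (1.0 - fu) * folded
    dy_dfu = unfolded - folded
    grads = {
        "tm": dy_dfu * dfu_ddg * ddg_dtm,
        "dh": dy_dfu * dfu_ddg * ddg_ddh,
        "bf": 1.0 - fu,
        "bu": fu,
        "mf": (1.0 - fu) * tk,
        "mu": fu * tk,
    }
    if want_dcp_grad:
        grads["dcp"] = dy_dfu * dfu_ddg * ddg_ddcp
    return y, grads


def _stderr_from_jac(jac, cost, n_obs):
    """Standard errors from sqrt(diag) of the covariance matrix.

    Covariance = s^2 (J^T J)^-1 with s^2 the residual variance.  A rank
    deficient Jacobian yields NaN errors while the fitted values stand.
    """
    n_par = jac.shape[1]
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * cost / dof
    try:
        u, sv, vt = np.linalg.svd(jac, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - svd rarely fails
        return np.full(n_par, np.nan)
    if sv[0] == 0 or sv[-1] < sv[0] * 1e-12:
        return np.full(n_par, np.nan)
    cov_diag = ((vt.T / sv) ** 2).sum(axis=1) * s2
    return np.sqrt(cov_diag)


def _window_mask(t_celsius, window):
    lo, hi = window
    return (t_celsius >= lo) & (t_celsius <= hi)


def _baseline_guess(tk, y):
    """Linear regressions over the first/last 15% of the window."""
    n = len(tk)
    k = max(3, int(round(0.15 * n)))
    mf, bf = np.polyfit(tk[:k], y[:k], 1)
    mu, bu = np.polyfit(tk[-k:], y[-k:], 1)
    return mf, bf, mu, bu


def _tm_guesses(tk, y):
    """Candidate melting temperatures from the smoothed derivative dY/dT.

    Both the maximum and the minimum of the derivative are tried: the sign
    of the transition is unknown a priori (ratio signals slope either way,
    and a large ΔCp adds a cold-side feature that can dominate |dY/dT|).
    """
    n = len(tk)
    win = min(7, n if n % 2 else n - 1)
    if win >= 5:
        ys = savgol_filter(y, window_length=win, polyorder=2)
    else:  # pragma: no cover - tiny windows
        ys = y
    dy = np.gradient(ys, tk)
    cands = [float(tk[int(np.argmax(dy))]), float(tk[int(np.argmin(dy))])]
    return sorted(set(cands))


@dataclass
class LocalFitResult:
    """Six-parameter fit of a single melting curve (ΔCp held fixed)."""

    label: str
    l0: float
    params: ThermoParams
    baseline: BaselineParams
    stderr: dict[str, float]
    residual_norm: float
    converged: bool
    message: str = ""
    n_points: int = 0

    @property
    def tm_celsius(self) -> float:
        return self.params.tm - 273.15


@dataclass
class GlobalFitResult:
    """Shared-slope (and optionally shared-ΔCp) fit of a whole study.

    Per-curve arrays are ordered like ``labels``/``l0``.  ``dcp`` is the
    study-wide heat-capacity change actually used, whether fixed or fitted.
    """

    labels: list[str]
    l0: np.ndarray
    tm: np.ndarray          # K
    dh: np.ndarray          # kcal/mol
    bf: np.ndarray
    bu: np.ndarray
    mf: float
    mu: float
    dcp: float
    dcp_fitted: bool
    tm_err: np.ndarray
    dh_err: np.ndarray
    bf_err: np.ndarray
    bu_err: np.ndarray
    mf_err: float
    mu_err: float
    dcp_err: float
    residual_norm: float
    converged: bool
    message: str = ""
    window: tuple[float, float] = (0.0, 0.0)
    n_points: int = 0
    excluded: list[str] = field(default_factory=list)

    @property
    def tm_celsius(self) -> np.ndarray:
        return self.tm - 273.15

    def apo_index(self) -> int:
        idx = np.flatnonzero(self.l0 == 0)
        if idx.size == 0:
            raise ValueError("study has no apo (l0 = 0) curve")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        """Fit table: one row per curve, shared parameters repeated."""
        return pd.DataFrame(
            {
                "label": self.labels,
                "L0_M": self.l0,
                "Tm_C": self.tm_celsius,
                "Tm_err_C": self.tm_err,
                "dH_kcal_mol": self.dh,
                "dH_err": self.dh_err,
                "bf": self.bf,
                "bf_err": self.bf_err,
                "bu": self.bu,
                "bu_err": self.bu_err,
                "mf": self.mf,
                "mu": self.mu,
                "dCp_kcal_molK": self.dcp,
            }
        )


def fit_local(curve: MeltingCurve, window=None, dcp: float = 0.0) -> LocalFitResult:
    """Fit one melting curve with six free parameters at fixed ΔCp.

    The melting temperature is constrained to the analysis window and the
    enthalpy to be positive.  A convergence failure (including the absence
    of any detectable transition) is reported on the result, not raised.
    """
    if window is None:
        window = (float(curve.t_celsius[0]), float(curve.t_celsius[-1]))
    mask = _window_mask(curve.t_celsius, window)
    if mask.sum() < MIN_WINDOW_POINTS:
        raise ValueError(
            f"analysis window {window} covers only {int(mask.sum())} points "
            f"(need >= {MIN_WINDOW_POINTS})"
        )
    tc = curve.t_celsius[mask]
    y = curve.y[mask]
    tk = celsius_to_kelvin(tc)

    mf0, bf0, mu0, bu0 = _baseline_guess(tk, y)
    tm_lo, tm_hi = float(tk[0]), float(tk[-1])
    lower = [tm_lo, DH_BOUNDS[0], -np.inf, -np.inf, -np.inf, -np.inf]
    upper = [tm_hi, DH_BOUNDS[1], np.inf, np.inf, np.inf, np.inf]

    def resid(x):
        ym, _ = _model_and_jac(tk, x[0], x[1], x[2], x[3], x[4], x[5], dcp)
        return ym - y

    def jac(x):
        _, g = _model_and_jac(tk, x[0], x[1], x[2], x[3], x[4], x[5], dcp)
        return np.column_stack([g["tm"], g["dh"], g["bf"], g["bu"], g["mf"], g["mu"]])

    res = None
    for tm0 in _tm_guesses(tk, y):
        tm0 = float(np.clip(celsius_to_kelvin(tm0), tm_lo + 1e-6, tm_hi - 1e-6))
        x0 = np.array([tm0, 100.0, bf0, bu0, mf0, mu0])
        cand = least_squares(resid, x0, jac=jac, bounds=(lower, upper), **_LSQ_OPTS)
        if res is None or cand.cost < res.cost:
            res = cand
    tm, dh, bf, bu, mf, mu = res.x
    stderr_vec = _stderr_from_jac(res.jac, res.cost, len(y))
    stderr = dict(zip(("tm", "dh", "bf", "bu", "mf", "mu"), stderr_vec))

    yrange = float(np.ptp(y))
    amplitude = abs((mu * tm + bu) - (mf * tm + bf))
    line = np.polyval(np.polyfit(tk, y, 1), tk)
    ss_line = float(((y - line) ** 2).sum())
    ss_model = 2.0 * res.cost
    messages = []
    converged = bool(res.success)
    if not res.success:
        messages.append(f"optimizer failure: {res.message}")
    if amplitude <= max(1e-12, 1e-3 * yrange) or (
            ss_line > 0 and ss_model > 0.5 * ss_line):
        # the transition model does not beat a straight line: nothing to fit
        converged = False
        messages.append("no transition detected (negligible unfolding amplitude)")
    if min(tm - tm_lo, tm_hi - tm) < 0.1:
        converged = False
        messages.append("melting temperature pinned at the window edge")

    return LocalFitResult(
        label=curve.label,
        l0=curve.l0,
        params=ThermoParams(tm=float(tm), dh=float(dh), dcp=float(dcp)),
        baseline=BaselineParams(mf=float(mf), bf=float(bf), mu=float(mu), bu=float(bu)),
        stderr=stderr,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=converged,
        message="; ".join(messages),
        n_points=len(y),
    )


def fit_global(
    study: BindingStudy,
    init: list[LocalFitResult],
    fit_dcp: bool = False,
    dcp_fixed: float = 0.0,
    dcp_bounds: tuple[float, float] = DCP_BOUNDS,
) -> GlobalFitResult:
    """Fit all curves of a study jointly with shared baseline slopes.

    The parameter vector is {mf, mu, [ΔCp]} plus per-curve
    {Tm, ΔH, bf, bu}.  Initialization comes from the local fits (shared
    slopes start at the median local slope; a fitted ΔCp starts at 0).
    Curves whose local fit failed are excluded with a warning.

    Because the local fits are run at a fixed ΔCp, their (Tm, ΔH) are
    biased whenever the true ΔCp is large, and the joint problem then has
    a self-consistent local minimum at small ΔCp.  When ΔCp is fitted, the
    optimizer therefore runs short deterministic restarts from a coarse
    ladder of ΔCp values spanning the bounds (0 first) and polishes the
    lowest-residual solution to full precision.
    """
    if len(init) != len(study.curves):
        raise ValueError("need one local fit per curve")
    keep = [i for i, r in enumerate(init) if r.converged]
    excluded = [init[i].label for i in range(len(init)) if i not in keep]
    for lab in excluded:
        logger.warning("excluding curve %r from global fit (local fit failed)", lab)
    if len(keep) < 2:
        raise ValueError("fewer than two curves with usable local fits")

    curves = [study.curves[i] for i in keep]
    locs = [init[i] for i in keep]
    mask = _window_mask(study.t_celsius, study.window)
    tk = celsius_to_kelvin(study.t_celsius[mask])
    ys = np.array([c.y[mask] for c in curves])
    n_curves, m = ys.shape

    mf0 = float(np.median([r.baseline.mf for r in locs]))
    mu0 = float(np.median([r.baseline.mu for r in locs]))
    shared0 = [mf0, mu0] + ([0.0] if fit_dcp else [])
    n_shared = len(shared0)
    per0 = []
    for r in locs:
        per0 += [r.params.tm, r.params.dh, r.baseline.bf, r.baseline.bu]
    x0 = np.array(shared0 + per0)

    tm_lo, tm_hi = float(tk[0]), float(tk[-1])
    lower = [-np.inf, -np.inf] + ([dcp_bounds[0]] if fit_dcp else [])
    upper = [np.inf, np.inf] + ([dcp_bounds[1]] if fit_dcp else [])
    lower += [tm_lo, DH_BOUNDS[0], -np.inf, -np.inf] * n_curves
    upper += [tm_hi, DH_BOUNDS[1], np.inf, np.inf] * n_curves
    x0 = np.minimum(np.maximum(x0, np.array(lower) + 1e-9), np.array(upper) - 1e-9)

    def unpack(x):
        mf, mu = x[0], x[1]
        dcp = x[2] if fit_dcp else dcp_fixed
        per = x[n_shared:].reshape(n_curves, 4)
        return mf, mu, dcp, per

    def resid(x):
        mf, mu, dcp, per = unpack(x)
        out = np.empty(n_curves * m)
        for i, (tm, dh, bf, bu) in enumerate(per):
            ym, _ = _model_and_jac(tk, tm, dh, bf, bu, mf, mu, dcp)
            out[i * m:(i + 1) * m] = ym - ys[i]
        return out

    def jac(x):
        mf, mu, dcp, per = unpack(x)
        J = np.zeros((n_curves * m, len(x)))
        for i, (tm, dh, bf, bu) in enumerate(per):
            _, g = _model_and_jac(tk, tm, dh, bf, bu, mf, mu, dcp,
                                  want_dcp_grad=fit_dcp)
            rows = slice(i * m, (i + 1) * m)
            J[rows, 0] = g["mf"]
            J[rows, 1] = g["mu"]
            if fit_dcp:
                J[rows, 2] = g["dcp"]
            base = n_shared + 4 * i
            J[rows, base] = g["tm"]
            J[rows, base + 1] = g["dh"]
            J[rows, base + 2] = g["bf"]
            J[rows, base + 3] = g["bu"]
        return J

    if fit_dcp:
        lo_d, hi_d = dcp_bounds
        starts = [lo_d + f * (hi_d - lo_d) for f in (0.0, 0.4, 0.8)]
        probe_opts = dict(_LSQ_OPTS, max_nfev=1500)
        best = None
        for d0 in starts:
            xs = x0.copy()
            xs[2] = min(max(d0, lo_d + 1e-9), hi_d - 1e-9)
            cand = least_squares(resid, xs, jac=jac, bounds=(lower, upper),
                                 **probe_opts)
            if best is None or cand.cost < best.cost:
                best = cand
        res = least_squares(resid, best.x, jac=jac, bounds=(lower, upper),
                            **_LSQ_OPTS)
    else:
        res = least_squares(resid, x0, jac=jac, bounds=(lower, upper),
                            **_LSQ_OPTS)
    mf, mu, dcp, per = unpack(res.x)
    stderr = _stderr_from_jac(res.jac, res.cost, n_curves * m)
    mf_err, mu_err = stderr[0], stderr[1]
    dcp_err = stderr[2] if fit_dcp else 0.0
    per_err = stderr[n_shared:].reshape(n_curves, 4)

    return GlobalFitResult(
        labels=[c.label for c in curves],
        l0=np.array([c.l0 for c in curves]),
        tm=per[:, 0].copy(),
        dh=per[:, 1].copy(),
        bf=per[:, 2].copy(),
        bu=per[:, 3].copy(),
        mf=float(mf),
        mu=float(mu),
        dcp=float(dcp),
        dcp_fitted=fit_dcp,
        tm_err=per_err[:, 0].copy(),
        dh_err=per_err[:, 1].copy(),
        bf_err=per_err[:, 2].copy(),
        bu_err=per_err[:, 3].copy(),
        mf_err=float(mf_err),
        mu_err=float(mu_err),
        dcp_err=float(dcp_err),
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=bool(res.success),
        message="" if res.success else res.message,
        window=study.window,
        n_points=n_curves * m,
        excluded=excluded,
    )


def fu_profile(fit: GlobalFitResult, t_iso_celsius: float) -> pd.DataFrame:
    """Fraction unfolded of every curve at one temperature.

    Evaluates the two-state f_u from each curve's fitted (Tm, ΔH) and the
    study ΔCp — the ligand effect is already absorbed in the per-curve
    parameters.  Uncertainties are first-order propagated from the Tm and
    ΔH marginal variances (covariance ignored; see the methods note).
    """
    lo, hi = fit.window
    if not lo <= t_iso_celsius <= hi:
        raise ValueError(
            f"T_iso {t_iso_celsius} °C outside the analysis window {fit.window}"
        )
    tk = float(celsius_to_kelvin(t_iso_celsius))
    fu, dfu_ddg, ddg_dtm, ddg_ddh, _ = _two_state_parts(tk, fit.tm, fit.dh, fit.dcp)
    var = (dfu_ddg * ddg_dtm * fit.tm_err) ** 2 + (dfu_ddg * ddg_ddh * fit.dh_err) ** 2
    return pd.DataFrame(
        {"label": fit.labels, "L0_M": fit.l0, "fu": fu, "fu_err": np.sqrt(var)}
    )
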