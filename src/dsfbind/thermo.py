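"""Closed-form thermodynamics of two-state unfolding coupled to 1:1 ligand binding.

All functions work in Kelvin and molar units and accept scalars or numpy
arrays.  The model: a protein exchanges between folded (F) and unfolded (U)
states with equilibrium constant K_U = [U]/[F]; a ligand L binds only the
folded state with dissociation constant K_d = [F][L]/[FL].  Fluorimetry
distinguishes folded (F + FL) from unfolded (U) protein, so the observable
is the fraction unfolded f_u = [U]/[P]_0.

Ligand binding raises the apparent stability of the folded state by
RT ln(1 + [L]_free / K_d); the free-ligand concentration follows from the
1:1 mass balance in which only the bindable pool [P]_0/(K_u + 1) competes
for ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "R_KCAL",
    "ThermoParams",
    "BaselineParams",
    "Concentrations",
    "EquilibriumConstants",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "dg_unfolding",
    "dg_total",
    "free_ligand",
    "exact_free_ligand",
    "apparent_ku",
    "fraction_unfolded",
    "fraction_unfolded_from_dg",
    "signal",
    "estimate_dcp",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3

#: ΔCp per residue (kcal mol^-1 K^-1 per residue) for the empirical
#: residue-count estimate of the heat-capacity change upon unfolding.
DCP_PER_RESIDUE = 13.88e-3


def celsius_to_kelvin(t_celsius):
    """Convert °C to K (the internal temperature unit)."""
    return np.asarray(t_celsius, dtype=float) + 273.15


def kelvin_to_celsius(t_kelvin):
    """Convert K back to °C for reporting."""
    return np.asarray(t_kelvin, dtype=float) - 273.15


@dataclass(frozen=True)
class ThermoParams:
    """Two-state unfolding parameters of one melting curve.

    Parameters
    ----------
    tm : float
        Melting temperature in K (fraction unfolded = 0.5 in the absence
        of a ligand term).
    dh : float
        van 't Hoff unfolding enthalpy at ``tm`` in kcal/mol. Must be > 0.
    dcp : float
        Heat-capacity change upon unfolding in kcal/(mol K). The unfolding
        entropy at ``tm`` is not independent: ΔS(tm) = dh/tm, which pins
        ΔG(tm) = 0.
    """

    tm: float
    dh: float
    dcp: float = 0.0

    def __post_init__(self):
        if not self.tm > 0:
            raise ValueError(f"tm must be positive (K), got {self.tm}")
        if not self.dh > 0:
            raise ValueError(f"dh must be positive, got {self.dh}")
        if not np.isfinite(self.dcp):
            raise ValueError("dcp must be finite")

    def dg(self, t_kelvin):
        return dg_unfolding(t_kelvin, self.tm, self.dh, self.dcp)


@dataclass(frozen=True)
class BaselineParams:
    """Linear pre-/post-transition fluorescence baselines.

    ``mf``/``bf`` are slope and intercept of the folded-state signal,
    ``mu``/``bu`` of the unfolded-state signal, both on the Kelvin scale.
    No ordering is imposed: the 350/330 nm ratio may slope either way.
    The folded-bound complex is assumed spectrally identical to the free
    folded state.
    """

    mf: float
    bf: float
    mu: float
    bu: float

    def __post_init__(self):
        vals = (self.mf, self.bf, self.mu, self.bu)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"baseline parameters must be finite, got {vals}")

    def folded(self, t_kelvin):
        return self.mf * np.asarray(t_kelvin, dtype=float) + self.bf

    def unfolded(self, t_kelvin):
        return self.mu * np.asarray(t_kelvin, dtype=float) + self.bu


@dataclass(frozen=True)
class Concentrations:
    """Total protein, total ligand and free-ligand concentrations (M)."""

    p0: float
    l0: float
    lfree: float = field(default=0.0)

    def __post_init__(self):
        if not self.p0 > 0:
            raise ValueError("p0 must be positive")
        if self.l0 < 0:
            raise ValueError("l0 must be non-negative")
        if not 0 <= self.lfree <= self.l0 * (1 + 1e-12) + 1e-300:
            raise ValueError("lfree must lie in [0, l0]")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Kd (M), unfolding constant Ku and its ligand-apparent value."""

    kd: float
    ku: float = 0.0
    ku_app: float = 0.0

    def __post_init__(self):
        if not self.kd > 0:
            raise ValueError("kd must be positive")
        if self.ku < 0 or self.ku_app < 0:
            raise ValueError("ku and ku_app must be non-negative")


def _check_positive_temperature(t):
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    return t


def dg_unfolding(t_kelvin, tm, dh, dcp=0.0):
    """Gibbs energy of unfolding ΔG_U(T) in kcal/mol.

    ΔG_U(T) = ΔH(1 - T/Tm) + ΔCp (T - Tm - T ln(T/Tm)),

    the integrated Gibbs-Helmholtz form with ΔS(Tm) = ΔH/Tm, arranged so
    that ΔG_U(Tm) evaluates to exactly zero in floating point for any ΔCp.
    """
    t = _check_positive_temperature(t_kelvin)
    if np.any(np.asarray(tm, dtype=float) <= 0):
        raise ValueError("tm must be positive (Kelvin)")
    tm = np.asarray(tm, dtype=float)
    dh = np.asarray(dh, dtype=float)
    dcp = np.asarray(dcp, dtype=float)
    return dh * (1.0 - t / tm) + dcp * (t - tm - t * np.log(t / tm))


def dg_total(t_kelvin, p: ThermoParams, lfree, kd):
    """Unfolding Gibbs energy including the ligand-coupling penalty.

    ΔG(T, L) = ΔG_U(T) + RT ln(1 + [L]_free / K_d).  Free ligand can only
    stabilize the folded state, so the result is >= ΔG_U with equality at
    [L]_free = 0.
    """
    if np.any(np.asarray(kd, dtype=float) <= 0):
        raise ValueError("kd must be positive")
    lfree = np.asarray(lfree, dtype=float)
    if np.any(lfree < 0):
        raise ValueError("lfree must be non-negative")
    t = _check_positive_temperature(t_kelvin)
    return p.dg(t) + R_KCAL * t * np.log1p(lfree / kd)


def free_ligand(l0, p0, ku, kd):
    """Free-ligand concentration from the 1:1 mass balance (M).

    The bindable protein pool is [P]_0/(K_u + 1) (unfolded protein does not
    bind ligand), leaving [L]_free as the positive root of

        L^2 + ([P]_0/(K_u+1) + K_d - [L]_0) L - K_d [L]_0 = 0.

    The evaluation below is algebraically identical to the textbook
    half-sum-plus-root expression but switches to the rationalized form
    2 Kd L0 / (b + sqrt(b^2 + 4 Kd L0)) when the linear coefficient b is
    positive, which avoids catastrophic cancellation for tiny roots.
    """
    l0 = np.asarray(l0, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    ku = np.asarray(ku, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(l0 < 0) or np.any(p0 < 0) or np.any(ku < 0):
        raise ValueError("l0, p0 and ku must be non-negative")
    if np.any(kd <= 0):
        raise ValueError("kd must be positive")

    with np.errstate(over="ignore"):
        peff = np.where(np.isinf(ku), 0.0, p0 / (ku + 1.0))
    b = peff + kd - l0
    disc = b * b + 4.0 * kd * l0
    # disc = (l0 + peff + kd)^2 - 4 l0 peff >= 0 always; assert for safety
    assert np.all(disc >= 0), "negative discriminant in free-ligand mass balance"
    root = np.sqrt(disc)
    with np.errstate(invalid="ignore", divide="ignore"):
        stable = 2.0 * kd * l0 / (b + root)
    direct = 0.5 * (root - b)
    out = np.where(b > 0, stable, direct)
    out = np.clip(out, 0.0, l0)
    if out.ndim == 0:
        return float(out)
    return out


def exact_free_ligand(l0, p0, ku, kd):
    """Free ligand from the exact three-species (U/F/FL) equilibrium.

    Solves  [L]_0 = L + [P]_0 L / (K_d (K_u + 1) + L)  numerically.  This
    differs slightly from :func:`free_ligand`, whose quadratic treats the
    bindable pool with an unscaled K_d; the exact solution is provided as
    a cross-check utility only and is not used in fitting.
    """
    l0 = float(l0)
    p0 = float(p0)
    ku = float(ku)
    kd = float(kd)
    if l0 == 0.0:
        return 0.0
    kdk = kd * (ku + 1.0)

    def balance(l):
        return l + p0 * l / (kdk + l) - l0

    if balance(l0) <= 0:
        return l0
    return brentq(balance, 0.0, l0, xtol=1e-300, rtol=8.9e-16)


def apparent_ku(dg, t_kelvin):
    """Apparent unfolding constant K'_U(T) = exp(-ΔG/RT)."""
    t = _check_positive_temperature(t_kelvin)
    with np.errstate(over="ignore"):
        return np.exp(-np.asarray(dg, dtype=float) / (R_KCAL * t))


def fraction_unfolded(ku_app):
    """Fraction unfolded f_u = K'_U / (K'_U + 1), mapped to [0, 1]."""
    k = np.asarray(ku_app, dtype=float)
    if np.any(k < 0):
        raise ValueError("ku_app must be non-negative")
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(k), 1.0, k / (k + 1.0))
    if out.ndim == 0:
        return float(out)
    return out


def fraction_unfolded_from_dg(dg, t_kelvin):
    """f_u directly from ΔG via the logistic function (overflow-safe)."""
    t = _check_positive_temperature(t_kelvin)
    return expit(-np.asarray(dg, dtype=float) / (R_KCAL * t))


def signal(t_kelvin, fu, baseline: BaselineParams):
    """Fluorescence signal: folded/unfolded baselines mixed by f_u."""
    fu = np.asarray(fu, dtype=float)
    if np.any(fu < 0) or np.any(fu > 1):
        raise ValueError("fu must lie in [0, 1]")
    t = np.asarray(t_kelvin, dtype=float)
    return fu * baseline.unfolded(t) + (1.0 - fu) * baseline.folded(t)


def estimate_dcp(n_res):
    """Empirical ΔCp from chain length: 13.88 cal/(mol K) per residue.

    Returns kcal/(mol K).  Useful when no calorimetric ΔCp is available.
    """
    if n_res != int(n_res) or int(n_res) <= 0:
        raise ValueError(f"n_res must be a positive integer, got {n_res!r}")
    return DCP_PER_RESIDUE * int(n_res)
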