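"""Virtual nDSF binding studies and the Kd-recovery benchmark.

A virtual study is generated exactly from the forward model: the Gibbs
energy of unfolding of the apo protein (Tm, ΔH, ΔCp), a ligand-coupling
term RT ln(1 + [L]_free/K_d) with the free ligand from the 1:1 mass
balance (K_d temperature-independent for simplicity), the logistic
fraction unfolded, linear folded/unfolded fluorescence baselines, and
i.i.d. Gaussian noise whose standard deviation is a stated percentage of
the dynamic range (max - min) of the whole noiseless study.

The benchmark grid repeats the full analysis pipeline (local fits,
global fit with or without a fitted ΔCp, isothermal temperature scan)
over combinations of K_d, protein concentration, ΔCp and noise level and
records the deviation K_d,fitted / K_d,true per study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import BindingStudy, MeltingCurve
from .thermo import (BaselineParams, R_KCAL, ThermoParams, apparent_ku,
                     celsius_to_kelvin, dg_unfolding, fraction_unfolded,
                     free_ligand, signal)

__all__ = [
    "SimulationSpec",
    "simulate_study",
    "ground_truth_fu",
    "run_benchmark",
    "summarize_benchmark",
    "DEFAULT_L0_SERIES",
    "DEFAULT_BENCHMARK_GRID",
    "FULL_BENCHMARK_GRID",
]

logger = logging.getLogger(__name__)

#: 14 two-fold dilutions from 2 mM plus one apo sample, a typical nDSF
#: dilution series.
DEFAULT_L0_SERIES = tuple([0.0] + [2e-3 / 2 ** k for k in range(14)])

#: Reduced benchmark grid (fast default).
DEFAULT_BENCHMARK_GRID = {
    "kd": (1e-7, 1e-6, 1e-5),
    "p0": (1e-7, 1e-6, 1e-5),
    "dcp": (0.0, 8.0),
    "noise": (0.0, 0.02),
}

#: Full-scale grid covering the decade sweep of affinities and protein
#: concentrations with ΔCp in {0, 4, 8, 12} and noise up to 10%.
FULL_BENCHMARK_GRID = {
    "kd": tuple(10.0 ** e for e in range(-10, 0)),
    "p0": tuple(10.0 ** e for e in range(-10, 0)),
    "dcp": (0.0, 4.0, 8.0, 12.0),
    "noise": (0.0, 0.01, 0.02, 0.05, 0.10),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for one virtual binding study.

    Concentrations in molar, temperatures in °C, energies in kcal/mol,
    ``dcp_true`` in kcal/(mol K), ``noise_pct`` as a fraction (0.02 = 2%)
    of the whole-study dynamic range.
    """

    kd_true: float = 1e-6
    p0: float = 1e-7
    dcp_true: float = 0.0
    noise_pct: float = 0.0
    tm_apo: float = 50.0
    dh_apo: float = 120.0
    baseline: BaselineParams = field(
        default_factory=lambda: BaselineParams(mf=-0.002, bf=1.5, mu=0.001, bu=1.1)
    )
    l0_series: tuple = DEFAULT_L0_SERIES
    t_min: float = 20.0
    t_max: float = 95.0
    t_step: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.noise_pct <= 0.10:
            raise ValueError("noise_pct must lie in [0, 0.10]")
        if self.kd_true <= 0 or self.p0 <= 0:
            raise ValueError("kd_true and p0 must be positive")
        if 0.0 not in self.l0_series:
            raise ValueError("l0_series must include an apo (0) sample")
        if not (self.t_min <= self.tm_apo - 15 and self.t_max >= self.tm_apo + 15):
            raise ValueError("temperature grid must span tm_apo +/- 15 °C")

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.t_step)) + 1
        return self.t_min + self.t_step * np.arange(n)

    @property
    def thermo(self) -> ThermoParams:
        return ThermoParams(tm=float(celsius_to_kelvin(self.tm_apo)),
                            dh=self.dh_apo, dcp=self.dcp_true)


def ground_truth_fu(spec: SimulationSpec, t_celsius, l0: float) -> np.ndarray:
    """Exact fraction unfolded of the forward model at given temperatures."""
    tk = celsius_to_kelvin(t_celsius)
    p = spec.thermo
    dgu = p.dg(tk)
    ku = apparent_ku(dgu, tk)
    lfree = free_ligand(l0, spec.p0, ku, spec.kd_true)
    dg_tot = dgu + R_KCAL * tk * np.log1p(lfree / spec.kd_true)
    return fraction_unfolded(apparent_ku(dg_tot, tk))


def simulate_study(spec: SimulationSpec) -> BindingStudy:
    """Generate a virtual binding study; identical spec and seed are
    bit-reproducible."""
    t_c = spec.t_grid
    tk = celsius_to_kelvin(t_c)
    ys = []
    for l0 in spec.l0_series:
        fu = ground_truth_fu(spec, t_c, l0)
        ys.append(signal(tk, fu, spec.baseline))
    ys = np.array(ys)
    if spec.noise_pct > 0:
        sigma = spec.noise_pct * float(ys.max() - ys.min())
        rng = np.random.default_rng(spec.seed)
        ys = ys + rng.normal(0.0, sigma, size=ys.shape)
    curves = [
        MeltingCurve(t_celsius=t_c.copy(), y=y, l0=float(l0),
                     label="apo" if l0 == 0 else f"L{i:02d}", signal_type="Ratio")
        for i, (l0, y) in enumerate(zip(spec.l0_series, ys))
    ]
    return BindingStudy(curves=curves, p0=spec.p0)


def _child_seed(root_seed: int, *indices) -> int:
    ss = np.random.SeedSequence([int(root_seed)] + [int(i) for i in indices])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_benchmark(
    grid: dict | None = None,
    fit_dcp_options=(False, True),
    reps: int = 5,
    seed: int = 0,
    base_spec: SimulationSpec | None = None,
) -> pd.DataFrame:
    """Kd-recovery benchmark over a (Kd, P0, ΔCp, noise) grid.

    Every cell is simulated ``reps`` times with deterministic per-study
    child seeds, then pushed through the standard analysis pipeline once
    per ΔCp-fitting mode.  Individual failures are recorded as
    non-converged rows; the benchmark continues.
    """
    from .pipeline import analyze_study  # deferred: pipeline imports fitting

    grid = dict(DEFAULT_BENCHMARK_GRID if grid is None else grid)
    base = base_spec or SimulationSpec()
    records = []
    for ik, kd in enumerate(grid["kd"]):
        for ip, p0 in enumerate(grid["p0"]):
            for ic, dcp in enumerate(grid["dcp"]):
                for inz, noise in enumerate(grid["noise"]):
                    for rep in range(reps):
                        child = _child_seed(seed, ik, ip, ic, inz, rep)
                        spec = replace(base, kd_true=kd, p0=p0, dcp_true=dcp,
                                       noise_pct=noise, seed=child)
                        study = simulate_study(spec)
                        for fit_dcp in fit_dcp_options:
                            rec = {
                                "kd_true": kd, "p0": p0, "dcp_true": dcp,
                                "noise_pct": noise, "fit_dcp": fit_dcp,
                                "rep": rep, "seed": child,
                            }
                            try:
                                gfit, iso = analyze_study(study, fit_dcp=fit_dcp)
                                dev = iso.best.kd / kd
                                rec.update(
                                    kd_fitted=iso.best.kd,
                                    deviation=dev,
                                    log10_deviation=float(np.log10(dev)),
                                    dcp_fitted=gfit.dcp if fit_dcp else np.nan,
                                    t_sel_c=iso.t_sel,
                                    converged=True,
                                    message="",
                                )
                            except Exception as exc:  # noqa: BLE001 - keep going
                                logger.warning(
                                    "benchmark cell failed (kd=%g p0=%g dcp=%g "
                                    "noise=%g rep=%d fit_dcp=%s): %s",
                                    kd, p0, dcp, noise, rep, fit_dcp, exc)
                                rec.update(
                                    kd_fitted=np.nan, deviation=np.nan,
                                    log10_deviation=np.nan, dcp_fitted=np.nan,
                                    t_sel_c=np.nan, converged=False,
                                    message=str(exc),
                                )
                            records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize_benchmark(records: pd.DataFrame) -> pd.DataFrame:
    """Group benchmark rows by (Kd, ΔCp, noise, fit mode) as in the
    deviation heat maps: median |log10 deviation| and convergence rate."""
    def agg(g):
        ok = g["converged"]
        return pd.Series({
            "n": len(g),
            "n_converged": int(ok.sum()),
            "median_abs_log10_dev": float(g.loc[ok, "log10_deviation"].abs().median())
            if ok.any() else float("nan"),
            "median_deviation": float(g.loc[ok, "deviation"].median())
            if ok.any() else float("nan"),
        })

    return (records.groupby(["kd_true", "dcp_true", "noise_pct", "fit_dcp"])
            .apply(agg, include_groups=False).reset_index())
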