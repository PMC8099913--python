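"""Shared fixtures.

Heavy global fits are session-scoped so several tests can share one
computation.  All synthetic inputs are generated in memory with fixed
seeds; nothing is read from disk.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from dsfbind import (
    BaselineParams,
    BindingStudy,
    MeltingCurve,
    SimulationSpec,
    analyze_study,
    celsius_to_kelvin,
    dg_unfolding,
    signal,
    simulate_study,
)
from dsfbind.fitting import fit_global, fit_local
from dsfbind.thermo import fraction_unfolded_from_dg

logging.disable(logging.WARNING)

DEFAULT_BASELINE = BaselineParams(mf=-0.002, bf=1.5, mu=0.001, bu=1.1)


def make_two_state_curve(tm_celsius, dh, baseline=DEFAULT_BASELINE, dcp=0.0,
                         l0=0.0, label="", noise=0.0, seed=None,
                         t_lo=20.0, t_hi=95.0, step=0.5):
    """A melting curve generated directly from the per-curve fit model."""
    tc = np.arange(t_lo, t_hi + step / 2, step)
    tk = celsius_to_kelvin(tc)
    fu = fraction_unfolded_from_dg(dg_unfolding(tk, tm_celsius + 273.15, dh, dcp), tk)
    y = signal(tk, fu, baseline)
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise * np.ptp(y), len(y))
    return MeltingCurve(tc, y, l0=l0, label=label)


def make_model_study(n_curves=15, p0=1e-6, dcp=0.0):
    """A study whose curves follow the per-curve two-state model exactly
    (distinct Tm/ΔH per curve, shared baselines), for exact fit round trips."""
    tms = 50.0 + 12.0 * np.linspace(0, 1, n_curves) ** 2
    dhs = 120.0 + 5.0 * np.arange(n_curves)
    curves = [
        make_two_state_curve(tm, dh, dcp=dcp,
                             l0=0.0 if i == 0 else 2e-3 / 2 ** (i - 1),
                             label=f"c{i:02d}")
        for i, (tm, dh) in enumerate(zip(tms, dhs))
    ]
    return BindingStudy(curves, p0=p0), tms, dhs


@pytest.fixture(scope="session")
def spec_noiseless():
    return SimulationSpec(kd_true=1e-6, p0=1e-7, noise_pct=0.0)


@pytest.fixture(scope="session")
def study_noiseless(spec_noiseless):
    return simulate_study(spec_noiseless)


@pytest.fixture(scope="session")
def pipeline_noiseless(study_noiseless):
    """(global fit, isothermal scan) of the noiseless default study."""
    return analyze_study(study_noiseless)


@pytest.fixture(scope="session")
def global_fit_noiseless(pipeline_noiseless):
    return pipeline_noiseless[0]


@pytest.fixture(scope="session")
def study_dcp8_noisy():
    spec = SimulationSpec(kd_true=1e-6, p0=1e-7, dcp_true=8.0, noise_pct=0.02,
                          seed=2024)
    return spec, simulate_study(spec)


@pytest.fixture(scope="session")
def dcp8_fits(study_dcp8_noisy):
    """Global fits of the noisy ΔCp=8 study with ΔCp fixed at 0 and fitted."""
    _, study = study_dcp8_noisy
    locs = [fit_local(c, study.window, dcp=0.0) for c in study.curves]
    fixed = fit_global(study, locs, fit_dcp=False, dcp_fixed=0.0)
    fitted = fit_global(study, locs, fit_dcp=True)
    return fixed, fitted
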