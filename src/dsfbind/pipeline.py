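"""End-to-end analysis pipeline and results bundle.

``analyze_study`` chains the stages on an in-memory study: local fits →
global fit → isothermal temperature scan.  ``run_pipeline`` adds file I/O,
the Tm-shift models, provenance and CSV/JSON output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curves import BindingStudy
from .fitting import GlobalFitResult, LocalFitResult, fit_global, fit_local
from .io import read_curves
from .isothermal import IsothermalResult, scan_temperatures
from .tmshift import ApparentKdResult, TmSeries, fit_model1, fit_model2

__all__ = ["ResultsBundle", "analyze_study", "run_pipeline", "default_scan_grid"]

logger = logging.getLogger(__name__)


def default_scan_grid(apo_tm_celsius: float, window, half_width: float = 10.0,
                      step: float = 1.0) -> np.ndarray:
    """Scan grid around the fitted apo melting temperature, clipped to the
    analysis window."""
    lo = max(window[0], apo_tm_celsius - half_width)
    hi = min(window[1], apo_tm_celsius + half_width)
    n = int(np.floor((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def analyze_study(
    study: BindingStudy,
    fit_dcp: bool = False,
    dcp: float = 0.0,
    scan_grid=None,
) -> tuple[GlobalFitResult, IsothermalResult]:
    """Local fits → global fit → isothermal scan for one study.

    ``dcp`` is the fixed heat-capacity change used when ``fit_dcp`` is
    false; a fitted ΔCp always starts from zero.  The scan grid defaults
    to ±10 °C around the fitted apo melting temperature in 1 °C steps.
    """
    local_dcp = 0.0 if fit_dcp else dcp
    locals_ = [fit_local(c, study.window, dcp=local_dcp) for c in study.curves]
    gfit = fit_global(study, locals_, fit_dcp=fit_dcp, dcp_fixed=dcp)
    if scan_grid is None:
        # reference temperature: apo Tm, or the least-ligand curve if the
        # apo local fit was excluded
        ref = int(np.argmin(gfit.l0))
        scan_grid = default_scan_grid(float(gfit.tm_celsius[ref]), study.window)
    iso = scan_temperatures(gfit, study, scan_grid)
    return gfit, iso


@dataclass
class ResultsBundle:
    """All artifacts of one pipeline run."""

    local_fits: list[LocalFitResult]
    global_fit: GlobalFitResult | None
    isothermal: IsothermalResult | None
    model1: ApparentKdResult | None
    model2: ApparentKdResult | None
    provenance: dict
    ok: bool = True
    errors: list[str] = field(default_factory=list)

    def local_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.local_fits:
            rows.append({
                "label": r.label, "L0_M": r.l0, "Tm_C": r.tm_celsius,
                "Tm_err_C": r.stderr.get("tm", float("nan")),
                "dH_kcal_mol": r.params.dh,
                "dH_err": r.stderr.get("dh", float("nan")),
                "mf": r.baseline.mf, "bf": r.baseline.bf,
                "mu": r.baseline.mu, "bu": r.baseline.bu,
                "residual_norm": r.residual_norm,
                "converged": r.converged, "message": r.message,
            })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out = {"provenance": self.provenance, "ok": self.ok, "errors": self.errors}
        if self.isothermal is not None:
            out["isothermal"] = self.isothermal.summary()
        if self.global_fit is not None:
            out["global_fit"] = {
                "dCp_kcal_molK": self.global_fit.dcp,
                "dCp_err": self.global_fit.dcp_err,
                "dCp_fitted": self.global_fit.dcp_fitted,
                "mf": self.global_fit.mf,
                "mu": self.global_fit.mu,
                "converged": self.global_fit.converged,
            }
        for name, res in (("model1", self.model1), ("model2", self.model2)):
            if res is not None:
                out[name] = {
                    "Kd_app_M": res.kd_app,
                    "Kd_stderr_M": res.kd_stderr,
                    "Kd_rel_error_pct": res.kd_rel_error_pct,
                    "converged": res.converged,
                    "warning": res.warning,
                    "params": res.params,
                }
        return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_t_grid(spec, window):
    if spec is None:
        return None
    if isinstance(spec, str):
        parts = [float(x) for x in spec.split(":")]
        lo, hi = parts[0], parts[1]
        step = parts[2] if len(parts) > 2 else 1.0
        n = int(np.floor((hi - lo) / step))
        return lo + step * np.arange(n + 1)
    return np.asarray(spec, dtype=float)


def run_pipeline(config: dict, out_dir=None) -> ResultsBundle:
    """Run the whole analysis from a configuration mapping.

    Config keys: ``curves`` and ``sheet`` (paths), optional ``dcp``
    ('fit' or a number, overriding the sheet), ``window`` (lo, hi °C),
    ``t_grid`` ('lo:hi:step' or list), ``tm_models`` (bool, default true),
    ``seed`` (recorded in provenance).  Results are written under
    ``out_dir`` when given.  Stage failures yield a partial bundle with
    ``ok = False`` rather than an exception.
    """
    study, sheet = read_curves(config["curves"], config["sheet"])
    if config.get("window"):
        study = BindingStudy(curves=study.curves, p0=study.p0,
                             window=tuple(config["window"]))

    dcp_mode = config.get("dcp", sheet.get("dcp", 0.0))
    fit_dcp = str(dcp_mode).lower() == "fit"
    dcp_fixed = 0.0 if fit_dcp else float(dcp_mode)

    provenance = {
        "version": __version__,
        "inputs": {
            "curves": str(config["curves"]),
            "curves_sha256": _sha256(config["curves"]),
            "sheet": str(config["sheet"]),
            "sheet_sha256": _sha256(config["sheet"]),
        },
        "config": {k: v for k, v in config.items() if k not in ("curves", "sheet")},
        "seed": config.get("seed"),
        "n_curves": len(study),
        "window_C": list(study.window),
    }

    errors: list[str] = []
    local_dcp = 0.0 if fit_dcp else dcp_fixed
    locals_ = [fit_local(c, study.window, dcp=local_dcp) for c in study.curves]

    gfit = iso = model1 = model2 = None
    try:
        gfit = fit_global(study, locals_, fit_dcp=fit_dcp, dcp_fixed=dcp_fixed)
        t_grid = _parse_t_grid(config.get("t_grid", sheet.get("t_grid")),
                               study.window)
        if t_grid is None:
            ref = int(np.argmin(gfit.l0))
            t_grid = default_scan_grid(float(gfit.tm_celsius[ref]), study.window)
        iso = scan_temperatures(gfit, study, t_grid)
    except Exception as exc:  # noqa: BLE001 - partial bundle contract
        logger.error("pipeline stage failed: %s", exc)
        errors.append(str(exc))

    if gfit is not None and config.get("tm_models", True):
        try:
            series = TmSeries.from_global_fit(gfit, study.p0)
            model1 = fit_model1(series)
            apo = gfit.apo_index()
            model2 = fit_model2(series, dh0=float(gfit.dh[apo]),
                                tm0=float(gfit.tm[apo]))
        except Exception as exc:  # noqa: BLE001
            logger.error("Tm-shift models failed: %s", exc)
            errors.append(f"tm_models: {exc}")

    bundle = ResultsBundle(
        local_fits=locals_, global_fit=gfit, isothermal=iso,
        model1=model1, model2=model2, provenance=provenance,
        ok=not errors, errors=errors,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.local_frame().to_csv(out / "local_fits.csv", index=False)
        if gfit is not None:
            gfit.to_frame().to_csv(out / "global_fit.csv", index=False)
        if iso is not None:
            iso.table.to_csv(out / "isothermal_scan.csv", index=False)
            iso.best.fu_table.to_csv(out / "fu_at_t_sel.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(bundle.summary(), fh, indent=2, default=float)
    return bundle
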