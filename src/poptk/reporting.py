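"""Publication-style outputs: parameter table, GOF panel, VPC and dose figures.

Figures are artifacts for humans; every number they display is available
from the underlying tables, which is what tests and downstream tooling
consume.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dosing import ScenarioResult
from .evaluation import BootstrapResult, VPCResult
from .nlme import FitResult
from .pkmodel import cv_percent

__all__ = [
    "report_parameter_table",
    "make_gof_panel",
    "make_vpc_figure",
    "make_dose_figure",
]

_THETA_LABELS = {
    "cl_tv": "CL (L/h)",
    "v1_tv": "V1 (L)",
    "q2_tv": "Q2 (L/h)",
    "v2_tv": "V2 (L)",
    "q3_tv": "Q3 (L/h)",
    "v3_tv": "V3 (L)",
    "inducer_coef": "Inducer ~ CL",
}


def report_parameter_table(
    fit_result: FitResult,
    boot: BootstrapResult | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Final-model parameter table: estimates, RSE%, shrinkage, bootstrap.

    Interindividual variability is reported as %CV via the exponential-IIV
    transform; off-diagonal Omega terms are reported as correlations.
    Bootstrap columns appear only when a bootstrap result is supplied.
    """
    if not fit_result.converged:
        raise ValueError("parameter table requires a converged fit")
    model = fit_result.model
    packer = fit_result._packer
    nat = packer.natural_params(model)
    rse = fit_result.rse or {}
    boot_sum = boot.summary() if boot is not None else None

    def boot_cols(key, transform=lambda v: v):
        if boot_sum is None or key not in boot_sum.index:
            return {}
        row = boot_sum.loc[key]
        return {
            "boot_median": transform(row["median"]),
            "boot_ci_lo": transform(row["ci_lo"]),
            "boot_ci_hi": transform(row["ci_hi"]),
        }

    rows = []
    for key, label in _THETA_LABELS.items():
        if key not in nat:
            continue
        rows.append(
            {
                "parameter": label,
                "estimate": nat[key],
                "rse_pct": rse.get(key, np.nan),
                "shrinkage_pct": np.nan,
                **boot_cols(key),
            }
        )
    for eff in model.covariate_effects:
        key = f"beta_{eff.covariate}_{eff.parameter}"
        rows.append(
            {
                "parameter": f"{eff.covariate} ~ {eff.parameter} ({eff.form})",
                "estimate": nat[key],
                "rse_pct": rse.get(key, np.nan),
                "shrinkage_pct": np.nan,
                **boot_cols(key),
            }
        )
    om = model.omega.matrix
    names = model.omega.names
    for i, nm in enumerate(names):
        key = f"omega2_{nm}"
        rows.append(
            {
                "parameter": f"IIV on {nm.upper()} (CV%)",
                "estimate": cv_percent(om[i, i]),
                "rse_pct": rse.get(key, np.nan),
                "shrinkage_pct": fit_result.shrinkage.get(nm, np.nan),
                **boot_cols(key, lambda v: cv_percent(max(v, 0.0))),
            }
        )
        for j in range(i):
            key = f"omega_{nm}_{names[j]}"
            if key not in nat:
                continue
            corr = om[i, j] / np.sqrt(om[i, i] * om[j, j])
            rows.append(
                {
                    "parameter": f"Correlation ({nm.upper()},{names[j].upper()})",
                    "estimate": corr,
                    "rse_pct": rse.get(key, np.nan),
                    "shrinkage_pct": np.nan,
                    **boot_cols(key),
                }
            )
    if "sigma_prop" in nat:
        rows.append(
            {
                "parameter": "Proportional residual (variance)",
                "estimate": nat["sigma_prop"],
                "rse_pct": rse.get("sigma_prop", np.nan),
                "shrinkage_pct": np.nan,
                **boot_cols("sigma_prop"),
            }
        )
    if "sigma_add" in nat:
        rows.append(
            {
                "parameter": "Additive residual (variance)",
                "estimate": nat["sigma_add"],
                "rse_pct": rse.get("sigma_add", np.nan),
                "shrinkage_pct": np.nan,
                **boot_cols("sigma_add"),
            }
        )
    table = pd.DataFrame(rows)
    if path is not None:
        path = Path(path)
        table.to_csv(path, index=False)
        with open(path.with_suffix(".txt"), "w") as fh:
            fh.write(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    return table


def make_gof_panel(
    fit_result: FitResult, cwres_df: pd.DataFrame, path: str | Path
) -> Path:
    """Four-panel goodness-of-fit figure: CWRES vs PRED, CWRES vs time,
    DV vs PRED, DV vs IPRED."""
    preds = fit_result.predictions
    if len(preds) == 0 or len(cwres_df) == 0:
        raise ValueError("empty predictions")
    merged = preds.merge(cwres_df[["ID", "TIME", "CWRES"]], on=["ID", "TIME"])
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    ax = axes[0, 0]
    ax.scatter(merged["PRED"], merged["CWRES"], s=12, alpha=0.6)
    ax.axhline(0, ls="--", c="k")
    for y in (-2, 2):
        ax.axhline(y, ls=":", c="grey")
    ax.set_xlabel("PRED (mg/L)")
    ax.set_ylabel("CWRES")
    ax = axes[0, 1]
    ax.scatter(merged["TIME"], merged["CWRES"], s=12, alpha=0.6)
    ax.axhline(0, ls="--", c="k")
    ax.set_xlabel("Time (h)")
    ax.set_ylabel("CWRES")
    for ax, xcol in ((axes[1, 0], "PRED"), (axes[1, 1], "IPRED")):
        ax.scatter(preds[xcol], preds["DV"], s=12, alpha=0.6)
        lim = max(preds["DV"].max(), preds[xcol].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k--")
        ax.set_xlabel(f"{xcol} (mg/L)")
        ax.set_ylabel("DV (mg/L)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _plot_vpc_axis(ax, vpc: VPCResult, title: str = "") -> None:
    t = vpc.bin_times
    for key, color in (("p5", "tab:blue"), ("p50", "tab:red"), ("p95", "tab:blue")):
        band = vpc.sim_bands[key]
        ax.fill_between(t, band["lo"], band["hi"], color=color, alpha=0.25)
        ax.plot(t, band["mid"], color="k", ls="--", lw=0.8)
    obs = vpc.obs_percentiles
    ax.plot(t, obs["p50"], color="tab:red", lw=1.5)
    ax.plot(t, obs["p5"], color="tab:red", ls="--", lw=1.0)
    ax.plot(t, obs["p95"], color="tab:red", ls="--", lw=1.0)
    ax.set_xlabel("Time (h)")
    ax.set_ylabel("Prediction-corrected conc. (mg/L)")
    if title:
        ax.set_title(title)


def make_vpc_figure(vpc: VPCResult | dict, path: str | Path) -> Path:
    """pcVPC figure; a stratified result renders one panel per stratum."""
    if isinstance(vpc, dict):
        if not vpc:
            raise ValueError("empty VPC result")
        fig, axes = plt.subplots(1, len(vpc), figsize=(6 * len(vpc), 5), squeeze=False)
        for ax, (val, v) in zip(axes[0], sorted(vpc.items())):
            _plot_vpc_axis(ax, v, title=f"stratum = {val}")
    else:
        fig, ax = plt.subplots(figsize=(7, 5))
        _plot_vpc_axis(ax, vpc)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def make_dose_figure(scenarios: list[ScenarioResult], path: str | Path) -> Path:
    """Overlay of loading-dose profiles on linear and semi-log axes."""
    if not scenarios:
        raise ValueError("no scenarios to plot")
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5))
    for res in scenarios:
        lbl = (
            f"{res.scenario.dose_per_kg:g} mg/kg"
            + (", inducer" if res.scenario.inducer else "")
        )
        col = "conc_mg_per_L" if "conc_mg_per_L" in res.profile else "conc_p50"
        ls = "--" if res.scenario.inducer else "-"
        ax1.plot(res.profile["time_h"], res.profile[col], ls, label=lbl)
        pos = res.profile[col] > 0
        ax2.semilogy(
            res.profile["time_h"][pos], res.profile[col][pos], ls, label=lbl
        )
    for ax in (ax1, ax2):
        ax.set_xlabel("Time (h)")
        ax.set_ylabel("Concentration (mg/L)")
    ax1.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
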