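"""Model qualification: bootstrap, CWRES diagnostics and pcVPC.

* Nonparametric bootstrap: subjects are resampled with replacement to the
  original subject count (unstratified), each replicate is refitted
  (warm-started from the point estimates by default), and per-parameter
  medians and percentile intervals are summarized over converged runs only.
  The convergence rate is always reported.
* CWRES: conditional weighted residuals from a first-order expansion of the
  model about the empirical Bayes mode eta_hat, with residual variance at
  the individual prediction (interaction).  Under a correctly specified
  model they are approximately standard normal.
* pcVPC: prediction-corrected visual predictive check.  Observations and
  simulated replicates are rescaled by bin-median population prediction
  (pcY = Y * median(PRED_bin) / PRED_ij) before comparing observed
  percentiles with simulation-based confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PKDataset
from .nlme import FitResult, PopulationModel, _Design, _Engine, _Packer, fit

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "bootstrap",
    "cwres",
    "pcvpc",
    "point_estimates",
]


def point_estimates(model: PopulationModel, free_offdiags: str = "init") -> dict[str, float]:
    """Natural-scale parameter dictionary of a model (the bootstrap target)."""
    packer = _Packer(model, free_offdiags=free_offdiags)
    return packer.natural_params(model)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    n_requested: int
    n_converged: int
    estimates: pd.DataFrame  # one row per converged replicate
    point: dict[str, float]

    @property
    def convergence_rate(self) -> float:
        return 100.0 * self.n_converged / self.n_requested

    def summary(self) -> pd.DataFrame:
        """Median and 2.5/97.5 percentiles per parameter, converged runs only."""
        rows = []
        for col in self.estimates.columns:
            vals = self.estimates[col].to_numpy()
            rows.append(
                {
                    "parameter": col,
                    "point": self.point.get(col, np.nan),
                    "median": float(np.median(vals)),
                    "ci_lo": float(np.percentile(vals, 2.5)),
                    "ci_hi": float(np.percentile(vals, 97.5)),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


def _resample_subjects(dataset: PKDataset, rng: np.random.Generator) -> PKDataset:
    ids = dataset.subject_ids
    draw = rng.choice(len(ids), size=len(ids), replace=True)
    frames = []
    for new_id, k in enumerate(draw, start=1):
        grp = dataset.subject(ids[k]).copy()
        grp["ID"] = new_id
        frames.append(grp)
    return PKDataset(pd.concat(frames, ignore_index=True))


def bootstrap(
    dataset: PKDataset,
    model: PopulationModel,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    fit_kwargs: dict | None = None,
) -> BootstrapResult:
    """Nonparametric (subject-resampling) bootstrap of the fitted model.

    ``model`` carries the point estimates; every replicate refit starts
    from them, which is also the common runtime-saving practice.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fit_kwargs = dict(fit_kwargs or {})
    packer = _Packer(model, free_offdiags=fit_kwargs.get("free_offdiags", "init"))
    rows = []
    n_conv = 0
    for _ in range(n):
        boot_ds = _resample_subjects(dataset, rng)
        try:
            res = fit(boot_ds, model, **fit_kwargs)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"bootstrap replicate failed: {exc}")
            continue
        if res.converged:
            n_conv += 1
            rows.append(packer.natural_params(res.model))
    estimates = pd.DataFrame(rows)
    return BootstrapResult(
        n_requested=n,
        n_converged=n_conv,
        estimates=estimates,
        point=packer.natural_params(model),
    )


# ---------------------------------------------------------------------------
# CWRES


def cwres(dataset: PKDataset, fit_result: FitResult) -> pd.DataFrame:
    """Conditional weighted residuals, one row per likelihood observation.

    Per subject, with J = df/deta at eta_hat and interaction variance
    V = J Omega J' + diag(sigma(f_hat)):

        CWRES = V^(-1/2) (y - [f(eta_hat) - J eta_hat])

    Subjects with a non-invertible V are flagged with a warning and their
    residuals omitted.
    """
    model = fit_result.model
    design: _Design = fit_result._design
    if design is None:
        design = _Design(dataset)
    engine = _Engine(design, model)
    eta = fit_result.eta_hat[None, ...]
    f_hat = engine._f(eta)
    d = len(model.omega.names)
    h = 1e-5
    J = np.empty(f_hat.shape + (d,))
    for k in range(d):
        ek = np.zeros(d)
        ek[k] = h
        J[..., k] = (engine._f(eta + ek) - f_hat) / h
    om = model.omega.matrix
    rows = []
    flagged = []
    for i, sid in enumerate(design.subject_ids):
        m = int(design.n_obs_per_subject[i])
        Ji = J[0, i, :m, :]
        fi = f_hat[0, i, :m]
        yi = design.y[i, :m]
        ti = design.times[i, :m]
        V = Ji @ om @ Ji.T + np.diag(model.residual_variance(fi))
        w, Q = np.linalg.eigh(V)
        if w.min() <= 1e-12 * max(w.max(), 1e-300):
            flagged.append(sid)
            continue
        V_isqrt = (Q * (1.0 / np.sqrt(w))) @ Q.T
        e_lin = fi - Ji @ fit_result.eta_hat[i]
        res = V_isqrt @ (yi - e_lin)
        for j in range(m):
            rows.append((sid, ti[j], yi[j], fi[j], res[j]))
    if flagged:
        warnings.warn(f"CWRES omitted for subjects with singular covariance: {flagged}")
    return pd.DataFrame(rows, columns=["ID", "TIME", "DV", "IPRED", "CWRES"])


# ---------------------------------------------------------------------------
# pcVPC


@dataclass
class VPCResult:
    """Binned observed percentiles and simulated confidence bands."""

    bin_times: np.ndarray  # representative (median) time per bin
    bin_n_obs: np.ndarray
    obs_percentiles: pd.DataFrame  # columns p5, p50, p95; one row per bin
    sim_bands: dict[str, pd.DataFrame]  # 'p5'/'p50'/'p95' -> lo, mid, hi per bin
    n_replicates: int
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0)
    prediction_corrected: bool = True
    stratum: object = None
    merged_bins: list = field(default_factory=list)


def _assign_bins(times: np.ndarray, bins) -> np.ndarray:
    if bins is None:
        # one bin per nominal sampling time (rich nominal-time design)
        uniq = np.unique(times)
        return np.searchsorted(uniq, times)
    edges = np.asarray(bins, dtype=float)
    return np.clip(np.digitize(times, edges) - 1, 0, len(edges) - 2)


def _merge_small_bins(bin_idx: np.ndarray, min_n: int = 2):
    """Merge bins holding fewer than ``min_n`` observations into a neighbor."""
    merged = []
    while True:
        ids, counts = np.unique(bin_idx, return_counts=True)
        small = ids[counts < min_n]
        if small.size == 0:
            break
        b = small[0]
        others = ids[ids != b]
        if others.size == 0:
            break
        target = others[np.argmin(np.abs(others - b))]
        bin_idx = np.where(bin_idx == b, target, bin_idx)
        merged.append((int(b), int(target)))
    # re-densify ids
    ids = np.unique(bin_idx)
    remap = {int(v): k for k, v in enumerate(ids)}
    return np.array([remap[int(v)] for v in bin_idx]), merged


def _vpc_one_stratum(
    times, y, pred, sim, pcts, bins, n_sim, ci, pred_correct, stratum
) -> VPCResult:
    bin_idx = _assign_bins(times, bins)
    bin_idx, merged = _merge_small_bins(bin_idx)
    if merged:
        warnings.warn(f"VPC bins merged (too few observations): {merged}")
    nb = bin_idx.max() + 1
    pc_fac = np.ones_like(pred)
    if pred_correct:
        for b in range(nb):
            sel = bin_idx == b
            pc_fac[sel] = np.median(pred[sel]) / pred[sel]
    y_pc = y * pc_fac
    sim_pc = sim * pc_fac  # (R, n_obs)
    alpha = 100.0 - ci * 100.0
    obs_rows, bin_times, bin_n = [], [], []
    band = {f"p{int(p)}": {"lo": [], "mid": [], "hi": []} for p in pcts}
    for b in range(nb):
        sel = bin_idx == b
        bin_times.append(float(np.median(times[sel])))
        bin_n.append(int(sel.sum()))
        obs_rows.append([float(np.percentile(y_pc[sel], p)) for p in pcts])
        sim_p = np.percentile(sim_pc[:, sel], pcts, axis=1)  # (3, R)
        for k, p in enumerate(pcts):
            key = f"p{int(p)}"
            band[key]["lo"].append(float(np.percentile(sim_p[k], alpha / 2.0)))
            band[key]["mid"].append(float(np.percentile(sim_p[k], 50.0)))
            band[key]["hi"].append(float(np.percentile(sim_p[k], 100.0 - alpha / 2.0)))
    obs = pd.DataFrame(obs_rows, columns=[f"p{int(p)}" for p in pcts])
    bands = {k: pd.DataFrame(v) for k, v in band.items()}
    return VPCResult(
        bin_times=np.asarray(bin_times),
        bin_n_obs=np.asarray(bin_n),
        obs_percentiles=obs,
        sim_bands=bands,
        n_replicates=n_sim,
        percentiles=tuple(pcts),
        prediction_corrected=pred_correct,
        stratum=stratum,
        merged_bins=merged,
    )


def pcvpc(
    dataset: PKDataset,
    model: PopulationModel,
    n_sim: int = 1000,
    bins=None,
    seed: int | np.random.Generator = 0,
    stratify: str | None = None,
    ci: float = 0.95,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
    prediction_corrected: bool = True,
) -> VPCResult | dict[int, VPCResult]:
    """Prediction-corrected visual predictive check.

    Simulates ``n_sim`` replicate studies under the original design (same
    subjects, doses, sampling times, covariates), optionally stratified by a
    0/1 covariate column (e.g. 'INDUCER'), and compares observed
    percentiles with the across-replicate confidence bands of the simulated
    percentiles.
    """
    design = _Design(dataset)
    engine = _Engine(design, model)
    rng = np.random.default_rng(seed)
    d = len(model.omega.names)
    S = design.n_subjects
    eta = rng.multivariate_normal(np.zeros(d), model.omega.matrix, size=(n_sim, S))
    f_sim = engine._f(eta)  # (n_sim, S, M)
    v = model.residual_variance(f_sim)
    y_sim = f_sim + np.sqrt(v) * rng.standard_normal(f_sim.shape)
    y_sim = np.maximum(y_sim, 0.0)
    pred_all = engine._f(np.zeros((1, S, d)))[0]

    mask = design.mask
    times = design.times[mask]
    y = design.y[mask]
    pred = pred_all[mask]
    sim = y_sim[:, mask]
    if stratify is None:
        return _vpc_one_stratum(
            times, y, pred, sim, percentiles, bins, n_sim, ci,
            prediction_corrected, None,
        )
    strat_sub = getattr(design, stratify.lower())
    strat_obs = np.broadcast_to(strat_sub[:, None], mask.shape)[mask]
    out = {}
    for val in np.unique(strat_obs):
        sel = strat_obs == val
        out[int(val)] = _vpc_one_stratum(
            times[sel], y[sel], pred[sel], sim[:, sel], percentiles, bins,
            n_sim, ci, prediction_corrected, int(val),
        )
    return out
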