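"""Nonlinear mixed-effects estimation for the compartmental infusion model.

The marginal likelihood of each subject's concentration vector is
approximated by the Laplace method with interaction: the per-subject joint
objective

    g_i(eta) = sum_j [ log(2 pi v_ij) + (y_ij - f_ij(eta))^2 / v_ij ]
               + eta' Omega^-1 eta + log det(2 pi Omega),

with residual variance v evaluated at the individual prediction
(v = sigma_add + sigma_prop * f(eta)^2, the "interaction" convention of
conditional estimation), is minimized over eta by a damped Gauss-Newton
inner loop, and the approximate -2 log marginal likelihood is

    OFV_i = g_i(eta_hat) - d log(2 pi) + log det(H_i / 2),

where H_i is the Hessian of g_i at the mode.  Two curvature conventions are
supported: ``laplace_hessian='gn'`` (default) uses the Gauss-Newton
first-order expansion of the model — the conditional-estimation flavor —
and ``'fd'`` uses a full central-difference Hessian.  Both are validated
against an adaptive-quadrature oracle in the test suite.

The population objective OFV = sum_i OFV_i is minimized over fixed effects
(log scale), the Cholesky factor of Omega and log residual variances by
L-BFGS-B with finite-difference gradients.  Everything is evaluated in
batched form over (models x subjects): the whole finite-difference gradient
of the outer problem is computed in a single vectorized pass, which is what
makes bootstrap and stepwise workflows affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .data import PKDataset
from .pkmodel import (
    _HAVE_COMPILED,
    CovariateEffect,
    OmegaMatrix,
    ThetaVector,
    _conc_batch,
    _conc_batch_compiled,
    _covariate_multipliers,
    _disposition,
)

if _HAVE_COMPILED:
    from .pkmodel import _inner_newton_compiled

_PARAM_ORDER = ("cl", "v1", "q2", "v2", "q3", "v3")

__all__ = ["PopulationModel", "FitResult", "ofv", "fit", "standard_errors"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, random-effect covariance and residual-error model."""

    theta: ThetaVector
    omega: OmegaMatrix
    sigma_prop: float = 0.02  # proportional residual variance (dimensionless)
    sigma_add: float = 0.0  # additive residual variance ((mg/L)^2)
    error_model: str = "proportional"
    structure: int = 3
    covariate_effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.error_model not in ("proportional", "additive", "combined"):
            raise ValueError("error_model must be proportional/additive/combined")
        if self.error_model in ("proportional", "combined") and self.sigma_prop <= 0:
            raise ValueError("sigma_prop must be > 0 for this error model")
        if self.error_model in ("additive", "combined") and self.sigma_add <= 0:
            raise ValueError("sigma_add must be > 0 for this error model")
        if self.structure not in (1, 2, 3):
            raise ValueError("structure must be 1, 2 or 3 compartments")

    def residual_variance(self, f: np.ndarray) -> np.ndarray:
        v = np.zeros_like(f)
        if self.error_model in ("proportional", "combined"):
            v = v + self.sigma_prop * f * f
        if self.error_model in ("additive", "combined"):
            v = v + self.sigma_add
        return np.maximum(v, 1e-14)


@dataclass
class FitResult:
    """Estimates, objective value and per-subject quantities from a fit."""

    model: PopulationModel
    ofv: float
    converged: bool
    n_params: int
    eta_hat: np.ndarray  # (S, d) posterior modes, rows follow subject_ids
    subject_ids: list
    predictions: object  # DataFrame: ID, TIME, DV, PRED, IPRED
    shrinkage: dict[str, float]
    message: str = ""
    inner_failures: list = field(default_factory=list)
    se: dict[str, float] | None = None
    rse: dict[str, float] | None = None
    _design: object = field(default=None, repr=False)
    _packer: object = field(default=None, repr=False)
    _x: np.ndarray | None = field(default=None, repr=False)
    _laplace_hessian: str = field(default="gn", repr=False)


# ---------------------------------------------------------------------------
# dataset packing


class _Design:
    """Padded per-subject arrays for batched likelihood evaluation."""

    def __init__(self, dataset: PKDataset):
        subs, dropped = [], []
        for sid, grp in dataset.iter_subjects():
            obs = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
            if len(obs) == 0:
                dropped.append(sid)
                continue
            doses = grp[grp["EVID"] == 1]
            subs.append((sid, grp, obs, doses))
        if dropped:
            warnings.warn(f"subjects with no usable observations excluded: {dropped}")
        if not subs:
            raise ValueError("no subjects with usable observations")
        self.dropped = dropped
        self.subject_ids = [s[0] for s in subs]
        S = len(subs)
        M = max(len(s[2]) for s in subs)
        D = max(len(s[3]) for s in subs)
        self.n_subjects = S
        self.times = np.zeros((S, M))
        self.y = np.ones((S, M))
        self.mask = np.zeros((S, M), dtype=bool)
        self.dstart = np.zeros((S, D))
        self.ddur = np.ones((S, D))
        self.damt = np.zeros((S, D))
        self.dmask = np.zeros((S, D))
        for c in ("wt", "inducer", "age", "sex", "crcl"):
            setattr(self, c, np.zeros(S))
        for i, (sid, grp, obs, doses) in enumerate(subs):
            m = len(obs)
            self.times[i, :m] = obs["TIME"].to_numpy()
            self.y[i, :m] = obs["DV"].to_numpy()
            self.mask[i, :m] = True
            nd = len(doses)
            self.dstart[i, :nd] = doses["TIME"].to_numpy()
            amt = doses["AMT"].to_numpy(dtype=float)
            rate = doses["RATE"].to_numpy(dtype=float)
            self.ddur[i, :nd] = amt / rate
            self.damt[i, :nd] = amt
            self.dmask[i, :nd] = 1.0
            first = grp.iloc[0]
            self.wt[i] = first["WT"]
            self.inducer[i] = first["INDUCER"]
            self.age[i] = first["AGE"]
            self.sex[i] = first["SEX"]
            self.crcl[i] = first["CRCL"]
        self.n_obs_per_subject = self.mask.sum(axis=1)
        self.n_obs = int(self.mask.sum())

    def covariate_arrays(self) -> dict[str, np.ndarray]:
        return {
            "wt": self.wt,
            "inducer": self.inducer,
            "age": self.age,
            "sex": self.sex,
            "crcl": self.crcl,
        }


def _base_params(model: PopulationModel, design: _Design) -> dict[str, np.ndarray]:
    """Typical individual parameters (eta = 0) for every subject, shape (S,)."""
    th = model.theta
    fcl = (design.wt / 70.0) ** 0.75
    fv = design.wt / 70.0
    cov = design.covariate_arrays()
    eff = model.covariate_effects
    return {
        "cl": th.cl_tv
        * fcl
        * th.inducer_coef**design.inducer
        * _covariate_multipliers(eff, "cl", cov),
        "v1": th.v1_tv * fv * _covariate_multipliers(eff, "v1", cov),
        "q2": th.q2_tv * fcl * np.ones_like(fcl),
        "v2": th.v2_tv * fv * np.ones_like(fv),
        "q3": th.q3_tv * fcl * np.ones_like(fcl),
        "v3": th.v3_tv * fv * np.ones_like(fv),
    }


# ---------------------------------------------------------------------------
# the Laplace/FOCE-interaction engine (batched over models x subjects)


class _Engine:
    """Evaluate the approximate marginal likelihood for a batch of models.

    All arrays carry a leading model axis B; a single model is the B=1 case.
    Batching the models makes a finite-difference outer gradient one pass.
    """

    def __init__(
        self,
        design: _Design,
        models: PopulationModel | Sequence[PopulationModel],
        laplace_hessian: str = "gn",
    ):
        if isinstance(models, PopulationModel):
            models = [models]
        if laplace_hessian not in ("gn", "fd"):
            raise ValueError("laplace_hessian must be 'gn' or 'fd'")
        self.design = design
        self.models = list(models)
        self.laplace_hessian = laplace_hessian
        m0 = self.models[0]
        self.names = m0.omega.names
        self.d = len(self.names)
        self.structure = m0.structure
        self.error_model = m0.error_model
        B = len(self.models)
        self.B = B
        S = design.n_subjects
        base_keys = ("cl", "v1", "q2", "v2", "q3", "v3")
        self.base = {k: np.empty((B, S)) for k in base_keys}
        self.om_inv = np.empty((B, self.d, self.d))
        self.logdet_om = np.empty(B)
        self.sig_prop = np.zeros((B, 1, 1))
        self.sig_add = np.zeros((B, 1, 1))
        for b, m in enumerate(self.models):
            if m.omega.names != self.names or m.structure != self.structure:
                raise ValueError("batched models must share omega names and structure")
            bp = _base_params(m, design)
            for k in base_keys:
                self.base[k][b] = bp[k]
            om = m.omega.matrix
            jitter = 1e-12 * max(np.trace(om) / self.d, 1.0)
            try:
                L = np.linalg.cholesky(om + jitter * np.eye(self.d))
            except np.linalg.LinAlgError:
                raise ValueError("omega matrix must be positive definite for estimation")
            self.om_inv[b] = np.linalg.inv(om + jitter * np.eye(self.d))
            self.logdet_om[b] = 2.0 * np.sum(np.log(np.diag(L)))
            if m.error_model in ("proportional", "combined"):
                self.sig_prop[b] = m.sigma_prop
            if m.error_model in ("additive", "combined"):
                self.sig_add[b] = m.sigma_add

    # -- likelihood pieces -------------------------------------------------

    def _variance(self, f: np.ndarray) -> np.ndarray:
        return np.maximum(self.sig_add + self.sig_prop * f * f, 1e-14)

    def _f(self, eta: np.ndarray) -> np.ndarray:
        """(B, S, M) predicted concentrations at eta (B, S, d)."""
        eta = np.clip(eta, -15.0, 15.0)
        mult = {k: 1.0 for k in ("cl", "v1", "q2", "v2", "q3", "v3")}
        for k, name in enumerate(self.names):
            mult[name] = np.exp(eta[..., k])
        b = self.base
        d = self.design
        # the leading axis may be the model batch B or, for B = 1 engines,
        # an arbitrary replicate batch (e.g. VPC simulation draws)
        lead = max(self.B, eta.shape[0] if eta.ndim == 3 else 1)
        parts = {
            k: np.ascontiguousarray(
                np.broadcast_to(b[k] * mult[k], (lead, d.n_subjects))
            )
            for k in ("cl", "v1", "q2", "v2", "q3", "v3")
        }
        if _HAVE_COMPILED:
            return _conc_batch_compiled(
                parts["cl"], parts["v1"], parts["q2"], parts["v2"],
                parts["q3"], parts["v3"],
                d.dstart, d.ddur, d.damt, d.dmask, d.times, self.structure,
            )
        lams, coefs = _disposition(
            parts["cl"], parts["v1"], parts["q2"], parts["v2"],
            parts["q3"], parts["v3"], self.structure,
        )
        return _conc_batch(lams, coefs, d.dstart, d.ddur, d.damt, d.dmask, d.times)

    def _g(self, eta: np.ndarray, f: np.ndarray | None = None) -> np.ndarray:
        """(B, S) joint objective -2 log p(y, eta)."""
        d = self.design
        if f is None:
            f = self._f(eta)
        v = self._variance(f)
        res = (d.y - f) ** 2 / v
        data_part = np.where(d.mask, np.log(2.0 * np.pi * v) + res, 0.0).sum(axis=-1)
        quad = np.einsum("bsi,bij,bsj->bs", eta, self.om_inv, eta)
        return data_part + quad + self.logdet_om[:, None] + self.d * _LOG2PI

    def _grad_hess(self, eta: np.ndarray, f0: np.ndarray):
        """Gradient of g and its Gauss-Newton Hessian, batched."""
        d = self.design
        h = 1e-5
        J = np.empty(f0.shape + (self.d,))
        for k in range(self.d):
            ek = np.zeros(self.d)
            ek[k] = h
            J[..., k] = (self._f(eta + ek) - f0) / h
        v = self._variance(f0)
        r = d.y - f0
        vp = 2.0 * self.sig_prop * f0
        w = vp / v - 2.0 * r / v - r * r * vp / (v * v)
        w = np.where(d.mask, w, 0.0)
        grad = np.einsum("bsmk,bsm->bsk", J, w) + 2.0 * np.einsum(
            "bij,bsj->bsi", self.om_inv, eta
        )
        Jm = J * np.where(d.mask, 1.0 / v, 0.0)[..., None]
        H = 2.0 * np.einsum("bsmi,bsmj->bsij", J, Jm) + 2.0 * self.om_inv[:, None]
        return grad, H, J

    # -- inner problem -----------------------------------------------------

    def _newton(
        self,
        eta: np.ndarray,
        max_iter: int = 60,
        tol: float = 1e-10,
    ):
        """Batched damped Newton for the per-subject posterior modes."""
        B, S, d = self.B, self.design.n_subjects, self.d
        eta = eta.copy()
        # a stale start must never poison the evaluation
        bad = ~np.isfinite(eta).all(axis=-1) | (np.abs(eta).max(axis=-1) > 5.0)
        eta[bad] = 0.0
        f0 = self._f(eta)
        g0 = self._g(eta, f0)
        done = np.zeros((B, S), dtype=bool)
        for _ in range(max_iter):
            grad, H, _ = self._grad_hess(eta, f0)
            grad = np.clip(np.where(np.isfinite(grad), grad, 0.0), -1e12, 1e12)
            H = np.clip(np.where(np.isfinite(H), H, 0.0), -1e12, 1e12)
            # per-subject ridge keeps ill-scaled or zeroed blocks solvable
            diag_max = np.abs(H.reshape(H.shape[:-2] + (-1,))).max(axis=-1)
            ridge = (1e-9 * diag_max + 1e-12)[..., None, None] * np.eye(d)
            step = np.linalg.solve(H + ridge, -grad[..., None])[..., 0]
            norm = np.linalg.norm(step, axis=-1, keepdims=True)
            step = np.where(norm > 5.0, step * (5.0 / norm), step)
            decrement = -0.5 * np.einsum("bsk,bsk->bs", grad, step)
            done = done | (decrement < tol * (1.0 + np.abs(g0)))
            if done.all():
                break
            accepted = done.copy()
            best, best_g = eta, g0
            for frac in (1.0, 0.5, 0.25, 0.1, 0.03):
                trial = np.where(accepted[..., None], best, eta + frac * step)
                trial = np.clip(trial, -15.0, 15.0)
                g_t = self._g(trial)
                improve = ~accepted & (g_t <= g0 + 1e-12 * np.abs(g0))
                best = np.where(improve[..., None], trial, best)
                best_g = np.where(improve, g_t, best_g)
                accepted |= improve
                if accepted.all():
                    break
            # a subject that improved nowhere along a descent ray is stuck
            # (flat spot or bad basin); stop iterating it here — rescue below
            done = done | ~accepted
            eta, g0 = best, best_g
            f0 = self._f(eta)
        return eta, f0, g0

    def inner(
        self,
        eta0: np.ndarray | None = None,
        max_iter: int = 60,
        tol: float = 1e-10,
    ):
        """Posterior modes eta_hat for every (model, subject).

        With ``eta0`` given, the Newton run tracks that basin — used to
        keep finite-difference model perturbations on the same branch as
        their base model.  Otherwise the deterministic zero start is used.
        """
        B, S, d = self.B, self.design.n_subjects, self.d
        if eta0 is not None:
            start = np.broadcast_to(np.asarray(eta0), (B, S, d)).astype(float)
        else:
            start = np.zeros((B, S, d))
        if _HAVE_COMPILED:
            eta, g0, H_gn, gnorm, f0 = self._inner_compiled(start, max_iter, tol)
            self._last_H_gn = H_gn
        else:
            eta, f0, g0 = self._newton(start, max_iter, tol)
            self._last_H_gn = None
            grad, H_gn, _ = self._grad_hess(eta, f0)
            grad = np.where(np.isfinite(grad), grad, np.inf)
            gnorm = np.abs(grad).max(axis=-1)
        not_ok = gnorm > 1e-3 * (1.0 + np.abs(g0))
        failures = [
            self.design.subject_ids[s] for s in range(S) if not_ok[0, s]
        ]
        return eta, f0, g0, failures

    def _inner_compiled(self, start, max_iter, tol):
        d = self.design
        S = d.n_subjects
        base_arr = np.empty((self.B, S, 6))
        for j, nm in enumerate(_PARAM_ORDER):
            base_arr[:, :, j] = self.base[nm]
        eta_map = np.array(
            [_PARAM_ORDER.index(nm) for nm in self.names], dtype=np.int64
        )
        return _inner_newton_compiled(
            base_arr,
            np.ascontiguousarray(start),
            eta_map,
            self.om_inv,
            self.logdet_om,
            self.sig_prop[:, 0, 0].copy(),
            self.sig_add[:, 0, 0].copy(),
            d.dstart, d.ddur, d.damt, d.dmask,
            d.times, d.y, d.mask,
            self.structure, max_iter, tol,
        )

    def _hess_fd(self, eta: np.ndarray) -> np.ndarray:
        """Central-difference Hessian of g at eta, (B, S, d, d)."""
        d, h = self.d, 1e-3
        B, S = eta.shape[:2]
        H = np.zeros((B, S, d, d))
        g0 = self._g(eta)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h
            gp = self._g(eta + ei)
            gm = self._g(eta - ei)
            H[..., i, i] = (gp + gm - 2.0 * g0) / h**2
            for j in range(i + 1, d):
                ej = np.zeros(d)
                ej[j] = h
                gpp = self._g(eta + ei + ej)
                gpm = self._g(eta + ei - ej)
                gmp = self._g(eta - ei + ej)
                gmm = self._g(eta - ei - ej)
                H[..., i, j] = H[..., j, i] = (gpp - gpm - gmp + gmm) / (4.0 * h**2)
        return H

    def ofv_components(self, eta0: np.ndarray | None = None):
        """(per-subject OFV (B, S), eta_hat, ipred, failures)."""
        eta, f0, g0, failures = self.inner(eta0)
        if getattr(self, "_last_H_gn", None) is not None:
            H_gn = self._last_H_gn
        else:
            _, H_gn, _ = self._grad_hess(eta, f0)
        if self.laplace_hessian == "fd":
            H = self._hess_fd(eta)
            sign, logdet = np.linalg.slogdet(H / 2.0)
            bad = sign <= 0
            if bad.any():
                _, ld = np.linalg.slogdet(H_gn[bad] / 2.0)
                logdet[bad] = ld
        else:
            _, logdet = np.linalg.slogdet(H_gn / 2.0)
        ofv_bs = g0 - self.d * _LOG2PI + logdet
        return ofv_bs, eta, f0, failures


def ofv(
    dataset: PKDataset, model: PopulationModel, laplace_hessian: str = "gn"
) -> float:
    """-2 log approximate marginal likelihood of the dataset under the model."""
    design = _Design(dataset)
    engine = _Engine(design, model, laplace_hessian)
    ofv_bs, _, _, _ = engine.ofv_components()
    return float(ofv_bs[0].sum())


# ---------------------------------------------------------------------------
# parameter packing for the outer optimization


_THETA_BY_STRUCTURE = {
    1: ("cl_tv", "v1_tv"),
    2: ("cl_tv", "v1_tv", "q2_tv", "v2_tv"),
    3: ("cl_tv", "v1_tv", "q2_tv", "v2_tv", "q3_tv", "v3_tv"),
}


class _Packer:
    """Bijection between a PopulationModel and the internal vector x.

    Fixed effects and residual variances are log-transformed; Omega is
    parameterized by its Cholesky factor (log diagonal, free off-diagonal
    entries when the correlation structure is open); covariate power
    exponents are untransformed.
    """

    def __init__(
        self,
        init: PopulationModel,
        fixed: Sequence[str] = (),
        estimate_inducer: bool | None = None,
        free_offdiags: str = "init",
    ):
        self.init = init
        fixed = set(fixed)
        names: list[str] = []
        for nm in _THETA_BY_STRUCTURE[init.structure]:
            if nm not in fixed:
                names.append(nm)
        if estimate_inducer is None:
            estimate_inducer = init.theta.inducer_coef != 1.0
        if estimate_inducer and "inducer_coef" not in fixed:
            names.append("inducer_coef")
        for eff in init.covariate_effects:
            nm = f"beta_{eff.covariate}_{eff.parameter}"
            if nm not in fixed:
                names.append(nm)
        d = len(init.omega.names)
        off = init.omega.matrix[~np.eye(d, dtype=bool)]
        if free_offdiags == "init":
            self.full_omega = bool(np.any(off != 0.0))
        elif free_offdiags in ("full", "none"):
            self.full_omega = free_offdiags == "full"
        else:
            raise ValueError("free_offdiags must be 'init', 'full' or 'none'")
        if "omega" not in fixed:
            for i in range(d):
                names.append(f"omega_chol_{i}_{i}")
                if self.full_omega:
                    for j in range(i):
                        names.append(f"omega_chol_{i}_{j}")
        if "sigma" not in fixed:
            if init.error_model in ("proportional", "combined"):
                names.append("sigma_prop")
            if init.error_model in ("additive", "combined"):
                names.append("sigma_add")
        self.names = names
        self.d_omega = d

    @property
    def n_free(self) -> int:
        return len(self.names)

    def pack(self, model: PopulationModel) -> np.ndarray:
        d = self.d_omega
        L = np.linalg.cholesky(model.omega.matrix + 1e-12 * np.eye(d))
        betas = {
            f"beta_{e.covariate}_{e.parameter}": e for e in model.covariate_effects
        }
        x = []
        for nm in self.names:
            if nm.startswith("omega_chol_"):
                i, j = (int(s) for s in nm.split("_")[2:])
                x.append(np.log(max(L[i, i], 1e-8)) if i == j else L[i, j])
            elif nm == "sigma_prop":
                x.append(np.log(model.sigma_prop))
            elif nm == "sigma_add":
                x.append(np.log(model.sigma_add))
            elif nm.startswith("beta_"):
                eff = betas[nm]
                x.append(np.log(eff.value) if eff.form == "factor" else eff.value)
            else:
                x.append(np.log(getattr(model.theta, nm)))
        return np.asarray(x)

    def unpack(self, x: np.ndarray) -> PopulationModel:
        init = self.init
        d = self.d_omega
        theta_kw = {
            f: getattr(init.theta, f)
            for f in (
                "cl_tv",
                "v1_tv",
                "q2_tv",
                "v2_tv",
                "q3_tv",
                "v3_tv",
                "inducer_coef",
            )
        }
        L = np.linalg.cholesky(init.omega.matrix + 1e-12 * np.eye(d))
        if not self.full_omega:
            L = np.diag(np.diag(L))
        sigma_prop, sigma_add = init.sigma_prop, init.sigma_add
        effects = list(init.covariate_effects)
        for nm, val in zip(self.names, x):
            if nm.startswith("omega_chol_"):
                i, j = (int(s) for s in nm.split("_")[2:])
                L[i, j] = np.exp(val) if i == j else val
            elif nm == "sigma_prop":
                sigma_prop = float(np.exp(val))
            elif nm == "sigma_add":
                sigma_add = float(np.exp(val))
            elif nm.startswith("beta_"):
                for k, e in enumerate(effects):
                    if f"beta_{e.covariate}_{e.parameter}" == nm:
                        new_val = (
                            float(np.exp(val)) if e.form == "factor" else float(val)
                        )
                        effects[k] = replace(e, value=new_val)
            else:
                theta_kw[nm] = float(np.exp(val))
        omega = OmegaMatrix(matrix=L @ L.T, names=init.omega.names)
        return replace(
            init,
            theta=ThetaVector(**theta_kw),
            omega=omega,
            sigma_prop=sigma_prop,
            sigma_add=sigma_add,
            covariate_effects=tuple(effects),
        )

    def bounds(self, x0: np.ndarray) -> list[tuple[float, float]]:
        out = []
        for nm, v0 in zip(self.names, x0):
            if nm.startswith("omega_chol_"):
                i, j = (int(s) for s in nm.split("_")[2:])
                out.append((np.log(1e-5), np.log(10.0)) if i == j else (-3.0, 3.0))
            elif nm.startswith("sigma"):
                out.append((np.log(1e-8), np.log(100.0)))
            elif nm.startswith("beta_"):
                out.append((-10.0, 10.0))
            else:
                out.append((v0 - 7.0, v0 + 7.0))
        return out

    def natural_params(self, model: PopulationModel) -> dict[str, float]:
        """Reportable natural-scale parameters (for tables, SEs, bootstrap)."""
        out: dict[str, float] = {}
        for nm in _THETA_BY_STRUCTURE[model.structure]:
            out[nm] = getattr(model.theta, nm)
        if model.theta.inducer_coef != 1.0 or "inducer_coef" in self.names:
            out["inducer_coef"] = model.theta.inducer_coef
        for e in model.covariate_effects:
            out[f"beta_{e.covariate}_{e.parameter}"] = e.value
        for i, a in enumerate(model.omega.names):
            out[f"omega2_{a}"] = float(model.omega.matrix[i, i])
            if self.full_omega:
                for j in range(i):
                    b = model.omega.names[j]
                    out[f"omega_{a}_{b}"] = float(model.omega.matrix[i, j])
        if model.error_model in ("proportional", "combined"):
            out["sigma_prop"] = model.sigma_prop
        if model.error_model in ("additive", "combined"):
            out["sigma_add"] = model.sigma_add
        return out


# ---------------------------------------------------------------------------
# fitting


def _predictions_frame(design, engine, eta, ipred):
    import pandas as pd

    f_pred = engine._f(np.zeros_like(eta))
    rows = []
    for i, sid in enumerate(design.subject_ids):
        m = int(design.n_obs_per_subject[i])
        for j in range(m):
            rows.append(
                (sid, design.times[i, j], design.y[i, j], f_pred[0, i, j], ipred[0, i, j])
            )
    return pd.DataFrame(rows, columns=["ID", "TIME", "DV", "PRED", "IPRED"])


def fit(
    dataset: PKDataset,
    init: PopulationModel,
    fixed: Sequence[str] = (),
    estimate_inducer: bool | None = None,
    free_offdiags: str = "init",
    laplace_hessian: str = "gn",
    max_outer_iter: int = 500,
    ftol: float = 1e-12,
    gtol: float = 2e-3,
    verbose: bool = False,
) -> FitResult:
    """Maximize the approximate marginal likelihood starting from ``init``.

    ``fixed`` holds parameter names (or the groups 'omega'/'sigma') at their
    initial values.  Returns partial results with ``converged=False`` when
    the optimizer fails rather than raising.
    """
    design = _Design(dataset)
    packer = _Packer(init, fixed, estimate_inducer, free_offdiags)
    if design.n_obs < packer.n_free:
        raise ValueError(
            f"{design.n_obs} observations cannot identify {packer.n_free} parameters"
        )
    x0 = packer.pack(init)
    n = packer.n_free
    h = 1e-5

    # the inner problem is re-solved from eta = 0 on every call: the
    # objective stays a deterministic, history-free function of x, which
    # the quasi-Newton line search requires.  The forward-difference
    # gradient is one batched engine pass over n+1 models.
    def value_and_grad(x: np.ndarray):
        base_model = packer.unpack(x)
        base_engine = _Engine(design, base_model, laplace_hessian)
        _, eta_base, _, _ = base_engine.ofv_components()
        models = [base_model]
        for k in range(n):
            xk = x.copy()
            xk[k] += h
            models.append(packer.unpack(xk))
        engine = _Engine(design, models, laplace_hessian)
        # every perturbed model tracks the base model's posterior basin so
        # the finite differences stay on one smooth branch
        ofv_bs, _, _, _ = engine.ofv_components(eta_base[0])
        vals = ofv_bs.sum(axis=1)
        vals = np.where(np.isfinite(vals), vals, 1e10)
        return vals[0], (vals[1:] - vals[0]) / h

    def value_only(x: np.ndarray) -> float:
        engine = _Engine(design, packer.unpack(x), laplace_hessian)
        ofv_bs, _, _, _ = engine.ofv_components()
        val = float(ofv_bs[0].sum())
        return val if np.isfinite(val) else 1e10

    bounds = packer.bounds(x0)

    def _descent_rescue(x_start, f_start, g_start, max_steps=10):
        # plain backtracking gradient descent: walks out of the narrow
        # curved valley where the quasi-Newton line search stalls at its
        # very first step.  Trial points are evaluated value-only (single
        # model); the gradient is recomputed only on accepted steps.
        x_cur, f_cur, g_cur = x_start.copy(), f_start, g_start
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        for _ in range(max_steps):
            gmax = max(float(np.max(np.abs(g_cur))), 1e-12)
            alpha = 0.3 / gmax  # first trial moves no parameter more than 0.3
            improved = False
            while alpha * gmax > 1e-10:
                trial = np.clip(x_cur - alpha * g_cur, lo, hi)
                f_t = value_only(trial)
                if f_t < f_cur - 1e-10:
                    x_cur, f_cur = trial, f_t
                    g_cur = value_and_grad(trial)[1]
                    improved = True
                    break
                alpha /= 3.0
            if not improved:
                break
        return x_cur, f_cur, g_cur

    if n == 0:
        res_x, res_fun = x0, value_only(x0)
        success, msg = True, "nothing free"
    else:
        x_start = x0.copy()
        best_x, best_fun = None, np.inf
        success, msg, res_fun, res_x = False, "", np.inf, x0
        for attempt in range(6):
            res = minimize(
                value_and_grad,
                x_start,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": max_outer_iter,
                    "ftol": ftol,
                    "gtol": gtol,
                    "maxcor": 20,
                    "maxls": 40,
                },
            )
            res_x, res_fun = res.x, res.fun
            msg = str(res.message)
            # convergence is judged by the projected gradient, not by the
            # optimizer's own flag: a line-search abort at the
            # finite-difference noise floor is a successful minimization,
            # while an "ftol" exit after a stalled first step is not
            if res.jac is not None:
                pg = np.asarray(res.jac, dtype=float).copy()
                for k, (lo_k, hi_k) in enumerate(bounds):
                    if res.x[k] <= lo_k + 1e-12 and pg[k] > 0:
                        pg[k] = 0.0
                    if res.x[k] >= hi_k - 1e-12 and pg[k] < 0:
                        pg[k] = 0.0
                gmax = float(np.max(np.abs(pg)))
            else:
                gmax = np.inf
            success = bool(np.isfinite(res_fun)) and gmax < 5.0
            if res_fun < best_fun:
                best_x, best_fun = np.asarray(res_x, dtype=float), float(res_fun)
            if verbose:
                print(
                    f"attempt {attempt}: iterations={res.nit}, ofv={res_fun:.4f}, "
                    f"gmax={gmax:.3g}, {msg}"
                )
            if success:
                break
            # stalled or aborted: walk downhill explicitly, then retry
            f_here, g_here = value_and_grad(np.asarray(res_x, dtype=float))
            x_new, f_new, _ = _descent_rescue(np.asarray(res_x, dtype=float), f_here, g_here)
            if f_new < best_fun:
                best_x, best_fun = x_new.copy(), float(f_new)
            if np.max(np.abs(x_new - np.asarray(res_x))) < 1e-12:
                break  # cannot improve further from here
            if f_here - f_new < 0.05 and attempt > 1:
                break  # descent has flattened out; accept the best point
            x_start = x_new
        if best_fun < res_fun:
            res_x, res_fun = best_x, best_fun

    model_hat = packer.unpack(np.asarray(res_x))
    engine = _Engine(design, model_hat, laplace_hessian)
    ofv_bs, eta, ipred, failures = engine.ofv_components()
    eta0 = eta[0]
    shr = {}
    for k, nm in enumerate(model_hat.omega.names):
        om = np.sqrt(model_hat.omega.matrix[k, k])
        sd = eta0[:, k].std(ddof=1) if eta0.shape[0] > 1 else 0.0
        shr[nm] = float(100.0 * (1.0 - sd / om)) if om > 0 else float("nan")
    return FitResult(
        model=model_hat,
        ofv=float(ofv_bs[0].sum()),
        converged=success,
        n_params=n,
        eta_hat=eta0,
        subject_ids=design.subject_ids,
        predictions=_predictions_frame(design, engine, eta, ipred),
        shrinkage=shr,
        message=msg,
        inner_failures=failures,
        _design=design,
        _packer=packer,
        _x=np.asarray(res_x, dtype=float),
        _laplace_hessian=laplace_hessian,
    )


def standard_errors(
    dataset: PKDataset, fit_result: FitResult, step: float = 1e-3
) -> tuple[dict[str, float] | None, dict[str, float] | None]:
    """Asymptotic SEs from the inverse finite-difference Hessian of OFV/2.

    RSE% = 100 * SE / |estimate| on the natural scale (delta method through
    the internal transform).  On a singular or indefinite Hessian a warning
    is issued and (None, None) is returned — SEs are never fabricated.
    """
    if not fit_result.converged:
        raise ValueError("standard errors require a converged fit")
    packer: _Packer = fit_result._packer
    design: _Design = fit_result._design
    x = fit_result._x
    lh = fit_result._laplace_hessian
    n = x.size

    eta_base = _Engine(design, packer.unpack(x), lh).ofv_components()[1][0]

    def batch_ofv(xs: list[np.ndarray]) -> np.ndarray:
        engine = _Engine(design, [packer.unpack(xx) for xx in xs], lh)
        return engine.ofv_components(eta_base)[0].sum(axis=1)

    # central-difference Hessian of OFV, evaluated in batched passes
    H = np.zeros((n, n))
    f0 = batch_ofv([x])[0]
    pts, idx = [], []
    for i in range(n):
        for s in (step, -step):
            xi = x.copy()
            xi[i] += s
            pts.append(xi)
    vals = batch_ofv(pts)
    fp = vals[0::2]
    fm = vals[1::2]
    for i in range(n):
        H[i, i] = (fp[i] + fm[i] - 2 * f0) / step**2
    pts, pairs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                xij = x.copy()
                xij[i] += si * step
                xij[j] += sj * step
                pts.append(xij)
            pairs.append((i, j))
    if pts:
        vals = batch_ofv(pts)
        for k, (i, j) in enumerate(pairs):
            fpp, fpm, fmp, fmm = vals[4 * k : 4 * k + 4]
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step**2)
    H /= 2.0  # OFV = -2 log L, so the information matrix is Hessian(OFV)/2
    ev = np.linalg.eigvalsh(H)
    if ev.min() <= 0:
        warnings.warn("Hessian not positive definite: standard errors unavailable")
        return None, None
    cov_x = np.linalg.inv(H)
    # delta method to the natural scale
    nat0 = packer.natural_params(packer.unpack(x))
    keys = list(nat0)
    J = np.zeros((len(keys), n))
    hh = 1e-6
    for i in range(n):
        xi = x.copy()
        xi[i] += hh
        nat_i = packer.natural_params(packer.unpack(xi))
        for r, k in enumerate(keys):
            J[r, i] = (nat_i[k] - nat0[k]) / hh
    cov_nat = J @ cov_x @ J.T
    se = {k: float(np.sqrt(max(cov_nat[r, r], 0.0))) for r, k in enumerate(keys)}
    rse = {
        k: float(100.0 * se[k] / abs(nat0[k])) if nat0[k] != 0 else float("nan")
        for k in keys
    }
    fit_result.se, fit_result.rse = se, rse
    return se, rse


def initial_model(
    dataset: PKDataset,
    structure: int = 3,
    error_model: str = "proportional",
    eta_names: tuple[str, ...] = ("cl", "v1", "v2"),
    full_omega: bool = True,
) -> PopulationModel:
    """Data-informed starting values for a fit.

    Typical clearance from the median of dose/AUC(0-last) (trapezoid),
    central volume from dose over the peak concentration, and generic
    multiples for the peripheral parameters; Omega starts diagonal at 0.1
    (with tiny off-diagonal seeds when the correlation structure is open)
    and the proportional residual variance at 0.04.  Values are normalized
    to the 70 kg reference using each subject's weight.
    """
    cls, v1s = [], []
    for sid, grp in dataset.iter_subjects():
        obs = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
        doses = grp[grp["EVID"] == 1]
        if len(obs) < 2 or len(doses) == 0:
            continue
        dose = float(doses["AMT"].sum())
        t = obs["TIME"].to_numpy()
        y = obs["DV"].to_numpy()
        auc_last = float(np.trapezoid(y, t))
        wt = float(grp.iloc[0]["WT"])
        fcl = (wt / 70.0) ** 0.75
        fv = wt / 70.0
        if auc_last > 0:
            cls.append(dose / auc_last / fcl)
        if y.max() > 0:
            v1s.append(dose / y.max() / fv)
    if not cls or not v1s:
        raise ValueError("dataset too sparse for heuristic initialization")
    cl0 = float(np.median(cls))
    v10 = float(np.median(v1s))
    d = len(eta_names)
    om = 0.1 * np.eye(d)
    if full_omega:
        om += 0.01 * (np.ones((d, d)) - np.eye(d))
    theta = ThetaVector(
        cl_tv=cl0,
        v1_tv=v10,
        q2_tv=5.0 * cl0 if structure >= 2 else 0.0,
        v2_tv=3.0 * v10 if structure >= 2 else 1.0,
        q3_tv=0.5 * cl0 if structure == 3 else 0.0,
        v3_tv=v10 if structure == 3 else 1.0,
        inducer_coef=1.0,
    )
    return PopulationModel(
        theta=theta,
        omega=OmegaMatrix(om, eta_names),
        sigma_prop=0.04,
        error_model=error_model,
        structure=structure,
    )
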