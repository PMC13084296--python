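"""Mammillary compartmental infusion models in closed form.

The structural model is a one-, two- or three-compartment mammillary model
with linear elimination from the central compartment and zero-order
(constant-rate infusion) input.  Concentrations are obtained analytically as
a sum of exponentials: the disposition eigenvalues are the roots of the
characteristic polynomial of the micro-constant rate matrix (k10 = CL/V1,
k12 = Q2/V1, k21 = Q2/V2, k13 = Q3/V1, k31 = Q3/V3), and the infusion
response follows by exact convolution of the unit-impulse response with the
zero-order input.  The analytic route is preferred over naive ODE
integration because realistic parameter sets are stiff (fast shallow
distribution, Q2/V1 ~ 20 /h, against a slow deep compartment, Q3/V3 ~ 0.07
/h); a tightly-toleranced implicit ODE integrator is kept as an independent
cross-check (:func:`predict_conc_ode`).

Covariates enter the individual-parameter map with fixed allometric weight
scaling (exponent 0.75 on clearances, 1 on volumes, reference 70 kg), a
multiplicative enzyme-inducer factor on clearance, and log-normal
interindividual random effects theta_i = theta_TV * exp(eta_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "ThetaVector",
    "OmegaMatrix",
    "StructuralParams",
    "DoseEvent",
    "CovariateEffect",
    "cv_percent",
    "omega_sq_from_cv",
    "individual_params",
    "predict_conc",
    "predict_conc_ode",
    "compartment_amounts",
    "terminal_half_life",
    "auc",
]

_ALLOMETRIC_REF_WT = 70.0
_CL_EXPONENT = 0.75
_V_EXPONENT = 1.0


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ThetaVector:
    """Typical (population) values for a 70 kg non-induced subject.

    ``inducer_coef`` is the multiplicative enzyme-inducer effect on CL
    (1.0 = no effect).
    """

    cl_tv: float
    v1_tv: float
    q2_tv: float = 0.0
    v2_tv: float = 1.0
    q3_tv: float = 0.0
    v3_tv: float = 1.0
    inducer_coef: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl_tv", "v1_tv", "v2_tv", "v3_tv", "inducer_coef"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.q2_tv < 0 or self.q3_tv < 0:
            raise ValueError("intercompartmental clearances must be >= 0")


@dataclass(frozen=True)
class OmegaMatrix:
    """Covariance matrix of the log-scale interindividual random effects.

    ``names`` lists the structural parameters carrying IIV (default CL, V1,
    V2, matching the final model).  Off-diagonal inputs may be given either
    as correlations (default) or directly as covariances.
    """

    matrix: np.ndarray
    names: tuple[str, ...] = ("cl", "v1", "v2")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.names), len(self.names)):
            raise ValueError("omega matrix shape does not match names")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("omega matrix must be symmetric")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("omega matrix must be positive semi-definite")

    @classmethod
    def from_cv(
        cls,
        cv_percents: dict[str, float],
        offdiags: dict[tuple[str, str], float] | None = None,
        offdiag: str = "correlation",
    ) -> "OmegaMatrix":
        """Build Omega from %CV values and optional off-diagonal terms.

        ``offdiag`` selects whether ``offdiags`` values are correlations
        (default) or covariances of the log-scale effects.
        """
        names = tuple(cv_percents)
        d = len(names)
        m = np.zeros((d, d))
        for i, n in enumerate(names):
            m[i, i] = omega_sq_from_cv(cv_percents[n])
        for (a, b), val in (offdiags or {}).items():
            i, j = names.index(a), names.index(b)
            if offdiag == "correlation":
                cov = val * np.sqrt(m[i, i] * m[j, j])
            elif offdiag == "covariance":
                cov = val
            else:
                raise ValueError("offdiag must be 'correlation' or 'covariance'")
            m[i, j] = m[j, i] = cov
        return cls(matrix=m, names=names)

    @property
    def variances(self) -> dict[str, float]:
        return {n: float(self.matrix[i, i]) for i, n in enumerate(self.names)}

    @property
    def cv_percents(self) -> dict[str, float]:
        return {n: cv_percent(v) for n, v in self.variances.items()}


@dataclass(frozen=True)
class StructuralParams:
    """One subject's realized micro-parameters (after covariates and eta)."""

    cl: float
    v1: float
    q2: float = 0.0
    v2: float = 1.0
    q3: float = 0.0
    v3: float = 1.0

    def __post_init__(self) -> None:
        if self.cl < 0 or self.v1 <= 0 or self.v2 <= 0 or self.v3 <= 0:
            raise ValueError("invalid structural parameters")
        if self.q2 < 0 or self.q3 < 0:
            raise ValueError("intercompartmental clearances must be >= 0")


@dataclass(frozen=True)
class DoseEvent:
    """A zero-order infusion: ``amount`` mg over ``duration`` h from ``start`` h."""

    start: float
    duration: float
    amount: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("infusion duration must be > 0")
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship.

    ``form='power'``: multiply the parameter by ``(cov/ref)**value``.
    ``form='factor'``: multiply by ``value**flag`` (0/1 covariate).
    """

    covariate: str
    parameter: str = "cl"
    form: str = "power"
    value: float = 0.0
    ref: float = 1.0


# ---------------------------------------------------------------------------
# %CV transform


def cv_percent(omega_sq: float | np.ndarray) -> float | np.ndarray:
    """%CV of a log-normal random effect: 100*sqrt(exp(omega^2) - 1)."""
    om = np.asarray(omega_sq, dtype=float)
    if np.any(om < 0):
        raise ValueError("omega_sq must be non-negative")
    out = 100.0 * np.sqrt(np.expm1(om))
    return float(out) if out.ndim == 0 else out


def omega_sq_from_cv(cv_pct: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`cv_percent`: omega^2 = log(1 + (cv/100)^2)."""
    cv = np.asarray(cv_pct, dtype=float)
    if np.any(cv < 0):
        raise ValueError("cv_pct must be non-negative")
    out = np.log1p((cv / 100.0) ** 2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# covariate / random-effect map


def _covariate_multipliers(
    effects: Sequence[CovariateEffect],
    parameter: str,
    covariates: dict[str, float | np.ndarray],
):
    mult = 1.0
    for eff in effects:
        if eff.parameter != parameter:
            continue
        x = np.asarray(covariates[eff.covariate], dtype=float)
        if eff.form == "power":
            mult = mult * (x / eff.ref) ** eff.value
        elif eff.form == "factor":
            mult = mult * eff.value**x
        else:
            raise ValueError(f"unknown covariate form {eff.form!r}")
    return mult


def individual_params(
    theta: ThetaVector,
    wt: float,
    inducer: int,
    eta: Sequence[float] = (0.0, 0.0, 0.0),
    covariate_effects: Sequence[CovariateEffect] = (),
    covariates: dict[str, float] | None = None,
) -> StructuralParams:
    """Realize one subject's parameters from typical values, covariates and eta.

    Clearances (CL, Q2, Q3) scale as (WT/70)^0.75, volumes as WT/70; the
    enzyme-inducer factor multiplies CL; eta = (eta_CL, eta_V1, eta_V2)
    enters exponentially.  Parameters without IIV take eta = 0.
    """
    if wt <= 0:
        raise ValueError("weight must be strictly positive")
    eta_cl, eta_v1, eta_v2 = (float(e) for e in eta)
    fcl = (wt / _ALLOMETRIC_REF_WT) ** _CL_EXPONENT
    fv = wt / _ALLOMETRIC_REF_WT
    cov = dict(covariates or {})
    cov.setdefault("inducer", inducer)
    cl = (
        theta.cl_tv
        * fcl
        * theta.inducer_coef**inducer
        * _covariate_multipliers(covariate_effects, "cl", cov)
        * np.exp(eta_cl)
    )
    v1 = (
        theta.v1_tv
        * fv
        * _covariate_multipliers(covariate_effects, "v1", cov)
        * np.exp(eta_v1)
    )
    return StructuralParams(
        cl=float(cl),
        v1=float(v1),
        q2=theta.q2_tv * fcl,
        v2=float(theta.v2_tv * fv * np.exp(eta_v2)),
        q3=theta.q3_tv * fcl,
        v3=theta.v3_tv * fv,
    )


# ---------------------------------------------------------------------------
# disposition eigenvalues and exponential coefficients (vectorized)


def _real_cubic_roots(p, q, r):
    """Roots of x^3 - p x^2 + q x - r with three real roots (trig method).

    Vectorized; inputs broadcast.  The mammillary rate matrix always yields
    real non-negative roots.
    """
    p = np.asarray(p, dtype=float)
    a = -p
    b = np.asarray(q, dtype=float)
    c = -np.asarray(r, dtype=float)
    Q = (a * a - 3.0 * b) / 9.0
    R = (2.0 * a**3 - 9.0 * a * b + 27.0 * c) / 54.0
    Q = np.maximum(Q, 1e-300)
    arg = np.clip(R / Q**1.5, -1.0, 1.0)
    th = np.arccos(arg)
    sq = np.sqrt(Q)
    k = np.arange(3.0).reshape((3,) + (1,) * np.ndim(a))
    roots = -2.0 * sq * np.cos((th + 2.0 * np.pi * k) / 3.0) - a / 3.0
    return np.moveaxis(roots, 0, -1)  # (..., 3)


def _separate_roots(lams: np.ndarray) -> np.ndarray:
    """Nudge numerically coincident eigenvalues apart.

    The partial-fraction coefficients divide by pairwise eigenvalue
    differences; a tiny relative perturbation regularizes the (measure-zero)
    repeated-root case without visible effect elsewhere.
    """
    lams = np.sort(lams, axis=-1)[..., ::-1]
    scale = np.maximum(np.abs(lams[..., :1]), 1e-30)
    for i in range(1, lams.shape[-1]):
        gap = lams[..., i - 1] - lams[..., i]
        floor = 1e-9 * scale[..., 0]
        lams[..., i] = np.where(gap < floor, lams[..., i - 1] - floor, lams[..., i])
    return lams


def _disposition(cl, v1, q2, v2, q3, v3, ncomp: int):
    """Eigen-rates ``lams`` and unit-bolus concentration coefficients ``coefs``.

    C_bolus(t) = sum_i coefs_i * exp(-lams_i * t), with C(0) = 1/V1.
    Shapes broadcast; returns arrays with a trailing axis of length ncomp.
    """
    cl, v1, q2, v2, q3, v3 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (cl, v1, q2, v2, q3, v3))
    )
    k10 = cl / v1
    if ncomp == 1:
        lams = k10[..., None]
        coefs = (1.0 / v1)[..., None]
        return lams, coefs
    k12 = q2 / v1
    k21 = q2 / v2
    if ncomp == 2:
        s = k10 + k12 + k21
        prod = k10 * k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * prod, 0.0))
        lams = np.stack([(s + disc) / 2.0, (s - disc) / 2.0], axis=-1)
        lams = _separate_roots(lams)
        num = k21[..., None] - lams
    elif ncomp == 3:
        k13 = q3 / v1
        k31 = q3 / v3
        p = k10 + k12 + k21 + k13 + k31
        q_ = k10 * k21 + k10 * k31 + k12 * k31 + k13 * k21 + k21 * k31
        r = k10 * k21 * k31
        lams = _separate_roots(np.maximum(_real_cubic_roots(p, q_, r), 0.0))
        num = (k21[..., None] - lams) * (k31[..., None] - lams)
    else:
        raise ValueError("ncomp must be 1, 2 or 3")
    denom = np.ones_like(lams)
    n = lams.shape[-1]
    for j in range(n):
        for i in range(n):
            if i != j:
                denom[..., j] = denom[..., j] * (lams[..., i] - lams[..., j])
    coefs = num / (v1[..., None] * denom)
    return lams, coefs


def _infusion_primitive(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
    """(1 - exp(-lam*t)) / lam with the t -> limit at lam = 0."""
    x = lam * t
    small = np.abs(x) < 1e-12
    lam_safe = np.where(small, 1.0, lam)
    out = -np.expm1(-x) / lam_safe
    return np.where(small, t * (1.0 - 0.5 * x), out)


def _conc_batch(lams, coefs, dose_start, dose_dur, dose_amt, dose_mask, times):
    """Central concentration for batches of parameter sets and infusions.

    lams, coefs: (..., n); dose arrays: (..., D); times: (..., T).
    Returns (..., T).
    """
    t = times[..., :, None, None]  # (..., T, 1, 1)
    s = dose_start[..., None, :, None]
    tau = dose_dur[..., None, :, None]
    rate = (dose_amt / dose_dur)[..., None, :, None]
    lam = lams[..., None, None, :]
    coef = coefs[..., None, None, :]
    trel = t - s
    active = np.minimum(np.maximum(trel, 0.0), tau)
    decay = np.maximum(trel - tau, 0.0)
    contrib = rate * coef * _infusion_primitive(lam, active) * np.exp(-lam * decay)
    contrib = contrib * dose_mask[..., None, :, None]
    return np.maximum(contrib.sum(axis=(-1, -2)), 0.0)


def _dose_arrays(doses: Iterable[DoseEvent]):
    doses = list(doses)
    if not doses:
        raise ValueError("at least one dose event is required")
    start = np.array([d.start for d in doses], dtype=float)
    dur = np.array([d.duration for d in doses], dtype=float)
    amt = np.array([d.amount for d in doses], dtype=float)
    return start, dur, amt, np.ones_like(amt)


def predict_conc(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
    ncomp: int = 3,
) -> np.ndarray:
    """Central-compartment concentration (mg/L) at the requested times (h).

    Superposition over dose events of the exact zero-order-input solution.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    lams, coefs = _disposition(
        params.cl, params.v1, params.q2, params.v2, params.q3, params.v3, ncomp
    )
    start, dur, amt, mask = _dose_arrays(doses)
    out = _conc_batch(lams, coefs, start, dur, amt, mask, times)
    if np.any(~np.isfinite(out)):
        raise FloatingPointError("non-finite concentration computed")
    return out


def _rate_matrix(params: StructuralParams, ncomp: int) -> np.ndarray:
    k10 = params.cl / params.v1
    if ncomp == 1:
        return np.array([[-k10]])
    k12 = params.q2 / params.v1
    k21 = params.q2 / params.v2
    if ncomp == 2:
        return np.array([[-(k10 + k12), k21], [k12, -k21]])
    k13 = params.q3 / params.v1
    k31 = params.q3 / params.v3
    return np.array(
        [
            [-(k10 + k12 + k13), k21, k31],
            [k12, -k21, 0.0],
            [k13, 0.0, -k31],
        ]
    )


def predict_conc_ode(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
    ncomp: int = 3,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Stiff-ODE reference solution (Radau), for verification against
    :func:`predict_conc`.  Integrates piecewise between dose-event breakpoints
    so the discontinuous input is handled exactly.
    """
    times = np.asarray(times, dtype=float)
    A = _rate_matrix(params, ncomp)
    breaks = sorted({0.0} | {d.start for d in doses} | {d.start + d.duration for d in doses})
    t_end = max(float(times.max()), breaks[-1]) if times.size else breaks[-1]

    def rate_in(t: float) -> float:
        return sum(d.rate for d in doses if d.start <= t < d.start + d.duration)

    y = np.zeros(A.shape[0])
    order = np.argsort(times)
    out = np.zeros_like(times)
    seg_edges = breaks + [t_end + 1.0]
    t_prev = 0.0
    idx = 0
    for seg_start, seg_end in zip(seg_edges[:-1], seg_edges[1:]):
        seg_end = min(seg_end, t_end)
        if seg_end <= seg_start:
            continue
        r = rate_in((seg_start + seg_end) / 2.0)

        def rhs(t, yy, r=r):
            dy = A @ yy
            dy[0] += r
            return dy

        t_eval = [t for t in times[order[idx:]] if seg_start <= t <= seg_end]
        sol = solve_ivp(
            rhs,
            (seg_start, seg_end),
            y,
            method="Radau",
            t_eval=sorted(set(t_eval)) or None,
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        for t in times[order[idx:]]:
            if seg_start <= t <= seg_end:
                out[order[idx]] = sol.sol(t)[0] / params.v1
                idx += 1
            else:
                break
        y = sol.y[:, -1] if sol.t[-1] == seg_end else sol.sol(seg_end)
        t_prev = seg_end
        if seg_end >= t_end:
            break
    out[times == 0.0] = 0.0
    return np.maximum(out, 0.0)


def compartment_amounts(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
    ncomp: int = 3,
) -> np.ndarray:
    """Amounts (mg) in every compartment at the requested times.

    Uses the augmented matrix exponential, which remains exact when the rate
    matrix is singular (e.g. CL = 0, the mass-balance check).
    Returns an array of shape (len(times), ncomp).
    """
    times = np.asarray(times, dtype=float)
    A = _rate_matrix(params, ncomp)
    n = A.shape[0]
    out = np.zeros((times.size, n))
    for it, t in enumerate(times):
        y = np.zeros(n)
        segs = []
        for d in doses:
            segs.extend([d.start, d.start + d.duration])
        breaks = sorted({0.0, t} | {s for s in segs if s < t})
        for a, b in zip(breaks[:-1], breaks[1:]):
            r = sum(d.rate for d in doses if d.start <= (a + b) / 2 < d.start + d.duration)
            M = np.zeros((n + 1, n + 1))
            M[:n, :n] = A * (b - a)
            M[:n, n] = r * (b - a) * np.eye(n)[0]
            E = expm(M)
            y = E[:n, :n] @ y + E[:n, n]
        out[it] = y
    return out


def terminal_half_life(params: StructuralParams, ncomp: int = 3) -> float:
    """Terminal half-life ln2 / lambda_z from the disposition eigenvalues.

    lambda_z is the smallest-magnitude nonzero eigenvalue; degenerate
    configurations (e.g. Q2 = Q3 = 0) reduce to the one-compartment ln2*V/CL.
    """
    ev = np.linalg.eigvals(_rate_matrix(params, ncomp))
    mags = np.abs(ev.real)
    nonzero = mags[mags > 1e-12 * max(mags.max(), 1e-30)]
    if nonzero.size == 0:
        return float("inf")
    return float(np.log(2.0) / nonzero.min())


def auc(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    t_end: float | None = None,
    ncomp: int = 3,
) -> float:
    """Exact AUC (mg*h/L) of the analytic profile from 0 to ``t_end``.

    ``t_end=None`` gives AUC to infinity, which equals total dose / CL for
    linear kinetics.
    """
    total_dose = sum(d.amount for d in doses)
    if t_end is None:
        if params.cl <= 0:
            raise ValueError("AUC to infinity requires CL > 0")
        return float(total_dose / params.cl)
    lams, coefs = _disposition(
        params.cl, params.v1, params.q2, params.v2, params.q3, params.v3, ncomp
    )
    lams, coefs = lams.ravel(), coefs.ravel()
    total = 0.0
    for d in doses:
        r = d.rate
        t1 = min(max(t_end - d.start, 0.0), d.duration)
        t2 = max(t_end - d.start - d.duration, 0.0)
        for lam, c in zip(lams, coefs):
            # integral during the active part of the infusion
            total += r * c * (t1 - _infusion_primitive(lam, np.array(t1))) / max(lam, 1e-300)
            # integral of the washout tail
            amt_factor = _infusion_primitive(lam, np.array(min(t1, d.duration)))
            total += r * c * amt_factor * _infusion_primitive(lam, np.array(t2))
    return float(total)


# ---------------------------------------------------------------------------
# compiled fast path for the batched concentration evaluation
#
# The estimation engine evaluates the model for (models x subjects x times)
# thousands of times per fit; the scalarized kernel below removes the numpy
# kernel-launch overhead.  The numpy implementation above remains the
# reference; the two are asserted equal in the test suite.

try:  # pragma: no cover - exercised indirectly
    import numba as _numba

    @_numba.njit(cache=False, fastmath=False)
    def _conc_batch_compiled(cl, v1, q2, v2, q3, v3, dstart, ddur, damt, dmask,
                             times, ncomp):
        B, S = cl.shape
        M = times.shape[1]
        D = dstart.shape[1]
        out = np.zeros((B, S, M))
        lams = np.zeros(3)
        coefs = np.zeros(3)
        for b in range(B):
            for s in range(S):
                k10 = cl[b, s] / v1[b, s]
                n = ncomp
                if n == 1:
                    lams[0] = k10
                    coefs[0] = 1.0 / v1[b, s]
                else:
                    k12 = q2[b, s] / v1[b, s]
                    k21 = q2[b, s] / v2[b, s]
                    if n == 2:
                        ssum = k10 + k12 + k21
                        disc = ssum * ssum - 4.0 * k10 * k21
                        if disc < 0.0:
                            disc = 0.0
                        root = np.sqrt(disc)
                        lams[0] = 0.5 * (ssum + root)
                        lams[1] = 0.5 * (ssum - root)
                    else:
                        k13 = q3[b, s] / v1[b, s]
                        k31 = q3[b, s] / v3[b, s]
                        p = k10 + k12 + k21 + k13 + k31
                        q_ = (k10 * k21 + k10 * k31 + k12 * k31
                              + k13 * k21 + k21 * k31)
                        r = k10 * k21 * k31
                        a = -p
                        bq = q_
                        c = -r
                        Q = (a * a - 3.0 * bq) / 9.0
                        if Q < 1e-300:
                            Q = 1e-300
                        R = (2.0 * a * a * a - 9.0 * a * bq + 27.0 * c) / 54.0
                        arg = R / Q**1.5
                        if arg > 1.0:
                            arg = 1.0
                        elif arg < -1.0:
                            arg = -1.0
                        th = np.arccos(arg)
                        sq = np.sqrt(Q)
                        for k in range(3):
                            lams[k] = (-2.0 * sq
                                       * np.cos((th + 2.0 * np.pi * k) / 3.0)
                                       - a / 3.0)
                            if lams[k] < 0.0:
                                lams[k] = 0.0
                    # sort descending and separate coincident roots
                    for i in range(n):
                        for j in range(i + 1, n):
                            if lams[j] > lams[i]:
                                tmp = lams[i]
                                lams[i] = lams[j]
                                lams[j] = tmp
                    scale = abs(lams[0])
                    if scale < 1e-30:
                        scale = 1e-30
                    floor = 1e-9 * scale
                    for i in range(1, n):
                        if lams[i - 1] - lams[i] < floor:
                            lams[i] = lams[i - 1] - floor
                    for i in range(n):
                        if n == 2:
                            num = k21 - lams[i]
                        else:
                            num = (k21 - lams[i]) * (k31 - lams[i])
                        den = 1.0
                        for j in range(n):
                            if j != i:
                                den *= lams[j] - lams[i]
                        coefs[i] = num / (v1[b, s] * den)
                for m in range(M):
                    t = times[s, m]
                    acc = 0.0
                    for dd in range(D):
                        if dmask[s, dd] == 0.0:
                            continue
                        trel = t - dstart[s, dd]
                        if trel <= 0.0:
                            continue
                        tau = ddur[s, dd]
                        rate = damt[s, dd] / tau
                        active = trel if trel < tau else tau
                        decay = trel - tau if trel > tau else 0.0
                        for i in range(n):
                            lam = lams[i]
                            x = lam * active
                            if abs(x) < 1e-12:
                                prim = active * (1.0 - 0.5 * x)
                            else:
                                prim = -np.expm1(-x) / lam
                            acc += (rate * coefs[i] * prim
                                    * np.exp(-lam * decay))
                    out[b, s, m] = acc if acc > 0.0 else 0.0
        return out

    _HAVE_COMPILED = True
except Exception:  # pragma: no cover
    _HAVE_COMPILED = False
    _conc_batch_compiled = None


if _HAVE_COMPILED:

    @_numba.njit(cache=False, fastmath=True)
    def _conc_one_compiled(cl, v1, q2, v2, q3, v3, dstart, ddur, damt, dmask,
                           times, ncomp, out):
        """Concentration profile of one subject into ``out`` (len M)."""
        lams = np.zeros(3)
        coefs = np.zeros(3)
        n = ncomp
        k10 = cl / v1
        if n == 1:
            lams[0] = k10
            coefs[0] = 1.0 / v1
        else:
            k12 = q2 / v1
            k21 = q2 / v2
            if n == 2:
                ssum = k10 + k12 + k21
                disc = ssum * ssum - 4.0 * k10 * k21
                if disc < 0.0:
                    disc = 0.0
                root = np.sqrt(disc)
                lams[0] = 0.5 * (ssum + root)
                lams[1] = 0.5 * (ssum - root)
                k31 = 0.0
            else:
                k13 = q3 / v1
                k31 = q3 / v3
                p = k10 + k12 + k21 + k13 + k31
                q_ = k10 * k21 + k10 * k31 + k12 * k31 + k13 * k21 + k21 * k31
                r = k10 * k21 * k31
                a = -p
                Q = (a * a - 3.0 * q_) / 9.0
                if Q < 1e-300:
                    Q = 1e-300
                R = (2.0 * a * a * a - 9.0 * a * q_ - 27.0 * r) / 54.0
                arg = R / Q**1.5
                if arg > 1.0:
                    arg = 1.0
                elif arg < -1.0:
                    arg = -1.0
                th = np.arccos(arg)
                sq = np.sqrt(Q)
                for k in range(3):
                    lams[k] = (-2.0 * sq * np.cos((th + 2.0 * np.pi * k) / 3.0)
                               - a / 3.0)
                    if lams[k] < 0.0:
                        lams[k] = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    if lams[j] > lams[i]:
                        tmp = lams[i]
                        lams[i] = lams[j]
                        lams[j] = tmp
            scale = abs(lams[0])
            if scale < 1e-30:
                scale = 1e-30
            floor = 1e-9 * scale
            for i in range(1, n):
                if lams[i - 1] - lams[i] < floor:
                    lams[i] = lams[i - 1] - floor
            for i in range(n):
                if n == 2:
                    num = k21 - lams[i]
                else:
                    num = (k21 - lams[i]) * (k31 - lams[i])
                den = 1.0
                for j in range(n):
                    if j != i:
                        den *= lams[j] - lams[i]
                coefs[i] = num / (v1 * den)
        M = times.shape[0]
        D = dstart.shape[0]
        for m in range(M):
            t = times[m]
            acc = 0.0
            for dd in range(D):
                if dmask[dd] == 0.0:
                    continue
                trel = t - dstart[dd]
                if trel <= 0.0:
                    continue
                tau = ddur[dd]
                rate = damt[dd] / tau
                active = trel if trel < tau else tau
                decay = trel - tau if trel > tau else 0.0
                for i in range(ncomp):
                    lam = lams[i]
                    x = lam * active
                    if abs(x) < 1e-12:
                        prim = active * (1.0 - 0.5 * x)
                    else:
                        prim = -np.expm1(-x) / lam
                    acc += rate * coefs[i] * prim * np.exp(-lam * decay)
            out[m] = acc if acc > 0.0 else 0.0

    @_numba.njit(cache=False, fastmath=True)
    def _inner_newton_compiled(base, eta0, eta_map, om_inv, logdet_om,
                               sig_prop, sig_add, dstart, ddur, damt, dmask,
                               times, y, mask, ncomp, max_iter, tol):
        """Per-(model, subject) damped Gauss-Newton for the posterior modes.

        base: (B, S, 6) structural params at eta = 0 (cl, v1, q2, v2, q3, v3);
        eta_map: (d,) index of the structural param each eta multiplies.
        Returns (eta, g, H_gn, gnorm, f_hat).
        """
        B, S, _ = base.shape
        d = eta_map.shape[0]
        M = times.shape[1]
        LOG2PI = np.log(2.0 * np.pi)
        eta_out = np.zeros((B, S, d))
        g_out = np.zeros((B, S))
        H_out = np.zeros((B, S, d, d))
        gn_out = np.zeros((B, S))
        f_out = np.zeros((B, S, M))
        h_fd = 1e-5
        for b in range(B):
            for s in range(S):
                pars = np.empty(6)
                f0 = np.empty(M)
                f_pert = np.empty((d, M))
                eta = np.empty(d)
                for k in range(d):
                    e0 = eta0[b, s, k]
                    if not np.isfinite(e0) or abs(e0) > 5.0:
                        e0 = 0.0
                    eta[k] = e0

                def conc_at(eta_loc, out_arr):
                    for j in range(6):
                        pars[j] = base[b, s, j]
                    for k in range(d):
                        ek = eta_loc[k]
                        if ek > 15.0:
                            ek = 15.0
                        elif ek < -15.0:
                            ek = -15.0
                        pars[eta_map[k]] *= np.exp(ek)
                    _conc_one_compiled(pars[0], pars[1], pars[2], pars[3],
                                       pars[4], pars[5],
                                       dstart[s], ddur[s], damt[s], dmask[s],
                                       times[s], ncomp, out_arr)

                def g_of(eta_loc, f_arr):
                    conc_at(eta_loc, f_arr)
                    tot = 0.0
                    n_obs = 0
                    for m in range(M):
                        if not mask[s, m]:
                            continue
                        n_obs += 1
                        f = f_arr[m]
                        v = sig_add[b] + sig_prop[b] * f * f
                        if v < 1e-14:
                            v = 1e-14
                        r = y[s, m] - f
                        tot += np.log(2.0 * np.pi * v) + r * r / v
                    quad = 0.0
                    for i in range(d):
                        for j in range(d):
                            quad += eta_loc[i] * om_inv[b, i, j] * eta_loc[j]
                    return tot + quad + logdet_om[b] + d * LOG2PI

                g0 = g_of(eta, f0)
                grad = np.zeros(d)
                H = np.zeros((d, d))
                step = np.zeros(d)
                trial = np.zeros(d)
                f_trial = np.empty(M)
                for _ in range(max_iter):
                    # FD Jacobian of f wrt eta
                    for k in range(d):
                        for i in range(d):
                            trial[i] = eta[i]
                        trial[k] += h_fd
                        conc_at(trial, f_pert[k])
                    for i in range(d):
                        grad[i] = 0.0
                        for j in range(d):
                            H[i, j] = 2.0 * om_inv[b, i, j]
                    for m in range(M):
                        if not mask[s, m]:
                            continue
                        f = f0[m]
                        v = sig_add[b] + sig_prop[b] * f * f
                        if v < 1e-14:
                            v = 1e-14
                        r = y[s, m] - f
                        vp = 2.0 * sig_prop[b] * f
                        w = vp / v - 2.0 * r / v - r * r * vp / (v * v)
                        for i in range(d):
                            Ji = (f_pert[i, m] - f) / h_fd
                            grad[i] += Ji * w
                            for j in range(d):
                                Jj = (f_pert[j, m] - f) / h_fd
                                H[i, j] += 2.0 * Ji * Jj / v
                    for i in range(d):
                        grad[i] += 2.0 * (om_inv[b, i] * eta).sum()
                        if not np.isfinite(grad[i]):
                            grad[i] = 0.0
                        for j in range(d):
                            if not np.isfinite(H[i, j]):
                                H[i, j] = 0.0
                    # ridge and solve H step = -grad (Gauss elimination)
                    dmax = 0.0
                    for i in range(d):
                        for j in range(d):
                            if abs(H[i, j]) > dmax:
                                dmax = abs(H[i, j])
                    A = np.empty((d, d + 1))
                    for i in range(d):
                        for j in range(d):
                            A[i, j] = H[i, j]
                        A[i, i] += 1e-9 * dmax + 1e-12
                        A[i, d] = -grad[i]
                    for col in range(d):
                        piv = col
                        for i in range(col + 1, d):
                            if abs(A[i, col]) > abs(A[piv, col]):
                                piv = i
                        if piv != col:
                            for j in range(d + 1):
                                tmp = A[col, j]
                                A[col, j] = A[piv, j]
                                A[piv, j] = tmp
                        pv = A[col, col]
                        if pv == 0.0:
                            pv = 1e-30
                        for i in range(col + 1, d):
                            fac = A[i, col] / pv
                            for j in range(col, d + 1):
                                A[i, j] -= fac * A[col, j]
                    for i in range(d - 1, -1, -1):
                        acc = A[i, d]
                        for j in range(i + 1, d):
                            acc -= A[i, j] * step[j]
                        pv = A[i, i]
                        if pv == 0.0:
                            pv = 1e-30
                        step[i] = acc / pv
                    snorm = 0.0
                    for i in range(d):
                        snorm += step[i] * step[i]
                    snorm = np.sqrt(snorm)
                    if snorm > 5.0:
                        for i in range(d):
                            step[i] *= 5.0 / snorm
                    decr = 0.0
                    for i in range(d):
                        decr -= 0.5 * grad[i] * step[i]
                    if decr < tol * (1.0 + abs(g0)):
                        break
                    improved = False
                    frac = 1.0
                    for _ls in range(5):
                        for i in range(d):
                            t_i = eta[i] + frac * step[i]
                            if t_i > 15.0:
                                t_i = 15.0
                            elif t_i < -15.0:
                                t_i = -15.0
                            trial[i] = t_i
                        g_t = g_of(trial, f_trial)
                        if g_t <= g0 + 1e-12 * abs(g0):
                            for i in range(d):
                                eta[i] = trial[i]
                            g0 = g_t
                            for m in range(M):
                                f0[m] = f_trial[m]
                            improved = True
                            break
                        if _ls == 0:
                            frac = 0.5
                        elif _ls == 1:
                            frac = 0.25
                        elif _ls == 2:
                            frac = 0.1
                        else:
                            frac = 0.03
                    if not improved:
                        break
                # final gradient / GN Hessian at the mode
                for k in range(d):
                    for i in range(d):
                        trial[i] = eta[i]
                    trial[k] += h_fd
                    conc_at(trial, f_pert[k])
                for i in range(d):
                    grad[i] = 0.0
                    for j in range(d):
                        H[i, j] = 2.0 * om_inv[b, i, j]
                for m in range(M):
                    if not mask[s, m]:
                        continue
                    f = f0[m]
                    v = sig_add[b] + sig_prop[b] * f * f
                    if v < 1e-14:
                        v = 1e-14
                    r = y[s, m] - f
                    vp = 2.0 * sig_prop[b] * f
                    w = vp / v - 2.0 * r / v - r * r * vp / (v * v)
                    for i in range(d):
                        Ji = (f_pert[i, m] - f) / h_fd
                        grad[i] += Ji * w
                        for j in range(d):
                            Jj = (f_pert[j, m] - f) / h_fd
                            H[i, j] += 2.0 * Ji * Jj / v
                for i in range(d):
                    grad[i] += 2.0 * (om_inv[b, i] * eta).sum()
                gmax = 0.0
                for i in range(d):
                    gi = abs(grad[i])
                    if not np.isfinite(gi):
                        gi = 1e30
                    if gi > gmax:
                        gmax = gi
                for i in range(d):
                    eta_out[b, s, i] = eta[i]
                    for j in range(d):
                        H_out[b, s, i, j] = H[i, j]
                g_out[b, s] = g0
                gn_out[b, s] = gmax
                for m in range(M):
                    f_out[b, s, m] = f0[m]
        return eta_out, g_out, H_out, gn_out, f_out
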