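"""Stepwise covariate model building on likelihood-ratio thresholds.

Forward inclusion adds, one candidate at a time, the covariate effect with
the largest significant OFV drop (default alpha 0.05, one parameter, so
Delta-OFV >= 3.84); backward elimination then removes, one at a time, any
retained effect whose removal raises the OFV by less than the stricter
backward threshold (default alpha 0.01, Delta-OFV 6.63).  Continuous
covariates (age, creatinine clearance) enter as power functions normalized
to the population median; binary covariates (sex, enzyme-inducer flag) as
multiplicative factors.  Candidates are screened on clearance by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2

from .data import PKDataset
from .nlme import FitResult, PopulationModel, fit
from .pkmodel import CovariateEffect

__all__ = [
    "CovariateCandidate",
    "StepRecord",
    "StepwiseTrace",
    "lrt_threshold",
    "stepwise",
    "aic",
]

_CONTINUOUS = {"age", "crcl", "wt"}


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """Delta-OFV cutoff: the (1 - alpha) quantile of chi-square with df."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.ppf(1.0 - alpha, df))


def aic(fit_result: FitResult) -> float:
    """Akaike information criterion: OFV + 2 * number of estimated parameters."""
    if not fit_result.converged:
        raise ValueError("AIC requires a converged fit")
    return float(fit_result.ofv + 2.0 * fit_result.n_params)


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate-parameter pair to screen.

    ``form`` defaults by covariate type: power for continuous covariates,
    multiplicative factor for binary flags.
    """

    covariate: str
    parameter: str = "cl"
    form: str | None = None

    def resolved_form(self) -> str:
        if self.form is not None:
            return self.form
        return "power" if self.covariate in _CONTINUOUS else "factor"


@dataclass(frozen=True)
class StepRecord:
    phase: str  # 'forward' or 'backward'
    step: int
    candidate: CovariateCandidate
    delta_ofv: float
    threshold: float
    decision: str  # 'added', 'removed', 'kept', 'rejected', 'skipped'


@dataclass
class StepwiseTrace:
    steps: list[StepRecord]
    final_model: PopulationModel
    final_fit: FitResult
    base_fit: FitResult

    @property
    def selected(self) -> list[CovariateCandidate]:
        """Candidates present in the final model."""
        chosen: list[CovariateCandidate] = []
        for rec in self.steps:
            if rec.decision == "added":
                chosen.append(rec.candidate)
            elif rec.decision == "removed":
                chosen = [
                    c
                    for c in chosen
                    if (c.covariate, c.parameter)
                    != (rec.candidate.covariate, rec.candidate.parameter)
                ]
        return chosen


def _null_effect(cand: CovariateCandidate, dataset: PKDataset) -> CovariateEffect:
    form = cand.resolved_form()
    if form == "power":
        ref = float(dataset.covariates()[cand.covariate.upper()].median())
        return CovariateEffect(cand.covariate, cand.parameter, "power", 0.0, ref)
    return CovariateEffect(cand.covariate, cand.parameter, "factor", 1.0, 1.0)


def _with_effect(model: PopulationModel, eff: CovariateEffect) -> PopulationModel:
    return replace(model, covariate_effects=model.covariate_effects + (eff,))


def _without_effect(model: PopulationModel, cand: CovariateCandidate) -> PopulationModel:
    keep = tuple(
        e
        for e in model.covariate_effects
        if (e.covariate, e.parameter) != (cand.covariate, cand.parameter)
    )
    return replace(model, covariate_effects=keep)


def stepwise(
    dataset: PKDataset,
    base: PopulationModel,
    candidates: list[CovariateCandidate],
    alpha_fwd: float = 0.05,
    alpha_bwd: float = 0.01,
    fit_kwargs: dict | None = None,
) -> StepwiseTrace:
    """Forward-inclusion / backward-elimination covariate search.

    Candidate fits are warm-started from the current model's estimates;
    a candidate whose fit does not converge is skipped with a warning and
    recorded in the trace.  Ties on Delta-OFV break by input order.
    """
    fit_kwargs = dict(fit_kwargs or {})
    thr_fwd = lrt_threshold(alpha_fwd, 1)
    thr_bwd = lrt_threshold(alpha_bwd, 1)
    steps: list[StepRecord] = []
    fitted_cache: dict[tuple, FitResult] = {}

    def _key(model: PopulationModel) -> tuple:
        return tuple(sorted((e.covariate, e.parameter) for e in model.covariate_effects))

    base_fit = fit(dataset, base, **fit_kwargs)
    fitted_cache[_key(base)] = base_fit
    if not base_fit.converged:
        raise RuntimeError("base model fit did not converge")
    current_model, current_fit = base_fit.model, base_fit

    # forward inclusion
    remaining = list(candidates)
    step_no = 0
    while remaining:
        step_no += 1
        results = []
        for cand in remaining:
            extended = _with_effect(current_model, _null_effect(cand, dataset))
            try:
                cand_fit = fit(dataset, extended, **fit_kwargs)
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"candidate {cand.covariate} failed: {exc}")
                cand_fit = None
            if cand_fit is None or not cand_fit.converged:
                steps.append(
                    StepRecord("forward", step_no, cand, float("nan"), thr_fwd, "skipped")
                )
                continue
            fitted_cache[_key(cand_fit.model)] = cand_fit
            results.append((cand, cand_fit, current_fit.ofv - cand_fit.ofv))
        if not results:
            break
        best_cand, best_fit, best_delta = max(results, key=lambda r: r[2])
        for cand, _, delta in results:
            if cand is not best_cand:
                steps.append(
                    StepRecord("forward", step_no, cand, delta, thr_fwd, "rejected")
                )
        if best_delta >= thr_fwd:
            steps.append(
                StepRecord("forward", step_no, best_cand, best_delta, thr_fwd, "added")
            )
            current_model, current_fit = best_fit.model, best_fit
            remaining = [c for c in remaining if c is not best_cand]
        else:
            steps.append(
                StepRecord("forward", step_no, best_cand, best_delta, thr_fwd, "rejected")
            )
            break

    # backward elimination
    included = [
        CovariateCandidate(e.covariate, e.parameter, e.form)
        for e in current_model.covariate_effects
        if any(
            (c.covariate, c.parameter) == (e.covariate, e.parameter)
            for c in candidates
        )
    ]
    changed = True
    while changed and included:
        changed = False
        step_no += 1
        removals = []
        for cand in included:
            reduced = _without_effect(current_model, cand)
            cached = fitted_cache.get(_key(reduced))
            red_fit = cached if cached is not None else fit(dataset, reduced, **fit_kwargs)
            if not red_fit.converged:
                steps.append(
                    StepRecord("backward", step_no, cand, float("nan"), thr_bwd, "skipped")
                )
                continue
            removals.append((cand, red_fit, red_fit.ofv - current_fit.ofv))
        if not removals:
            break
        weakest, weak_fit, weak_delta = min(removals, key=lambda r: r[2])
        if weak_delta < thr_bwd:
            steps.append(
                StepRecord("backward", step_no, weakest, weak_delta, thr_bwd, "removed")
            )
            current_model, current_fit = weak_fit.model, weak_fit
            included = [
                c
                for c in included
                if (c.covariate, c.parameter) != (weakest.covariate, weakest.parameter)
            ]
            changed = True
        else:
            for cand, _, delta in removals:
                steps.append(
                    StepRecord("backward", step_no, cand, delta, thr_bwd, "kept")
                )
    return StepwiseTrace(
        steps=steps,
        final_model=current_model,
        final_fit=current_fit,
        base_fit=base_fit,
    )
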