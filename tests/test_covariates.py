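"""Likelihood-ratio thresholds, AIC and the stepwise search mechanics."""

import dataclasses

import numpy as np
import pytest

from poptk.covariates import (
    CovariateCandidate,
    aic,
    lrt_threshold,
    stepwise,
)
from poptk.nlme import fit
from poptk.synthetic import generate_rich_recovery_set


class TestLrtThreshold:
    @pytest.mark.parametrize(
        "alpha,df,expected",
        [(0.05, 1, 3.84), (0.01, 1, 6.63), (0.05, 2, 5.99), (0.001, 1, 10.83)],
    )
    def test_chi_square_quantiles(self, alpha, df, expected):
        assert lrt_threshold(alpha, df) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            lrt_threshold(alpha, 1)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            lrt_threshold(0.05, 0)


class TestAic:
    def test_definition(self, fit20):
        assert aic(fit20) == pytest.approx(fit20.ofv + 2 * fit20.n_params)

    def test_extra_null_parameter_costs_two(self, fit20):
        # same OFV, one more parameter -> AIC up by exactly 2
        shadow = dataclasses.replace(fit20, n_params=fit20.n_params + 1)
        assert aic(shadow) - aic(fit20) == pytest.approx(2.0)

    def test_three_compartment_preferred_on_three_compartment_data(
        self, rich50, truth
    ):
        """Model selection recovers the generating structure."""
        fit3 = fit(rich50.dataset, truth)
        init2 = dataclasses.replace(
            truth,
            theta=dataclasses.replace(truth.theta, q3_tv=0.0, v3_tv=1.0),
            structure=2,
        )
        fit2 = fit(rich50.dataset, init2)
        assert fit3.converged and fit2.converged
        assert aic(fit3) < aic(fit2)


class TestStepwise:
    def test_empty_candidate_list_is_noop(self, study20, truth):
        base = dataclasses.replace(
            truth, theta=dataclasses.replace(truth.theta, inducer_coef=1.0)
        )
        trace = stepwise(study20.dataset, base, [])
        assert trace.steps == []
        assert trace.final_fit.ofv == trace.base_fit.ofv
        assert trace.selected == []

    def test_finds_true_inducer_effect(self, truth):
        """With a real 1.63-fold inducer effect and null age/sex/CrCL, the
        search should retain inducer-on-CL and nothing else."""
        study = generate_rich_recovery_set(truth, 50, seed=101)
        base = dataclasses.replace(
            truth, theta=dataclasses.replace(truth.theta, inducer_coef=1.0)
        )
        cands = [CovariateCandidate(c) for c in ("age", "sex", "inducer", "crcl")]
        trace = stepwise(
            study.dataset, base, cands,
            fit_kwargs={"gtol": 2e-2, "max_outer_iter": 60},
        )
        selected = {c.covariate for c in trace.selected}
        assert selected == {"inducer"}
        ind_eff = [e for e in trace.final_model.covariate_effects
                   if e.covariate == "inducer"]
        assert 1.12 <= ind_eff[0].value <= 2.30

    def test_trace_reproducible(self, truth):
        study = generate_rich_recovery_set(truth, 30, seed=55)
        base = dataclasses.replace(
            truth, theta=dataclasses.replace(truth.theta, inducer_coef=1.0)
        )
        kw = {"gtol": 2e-2, "max_outer_iter": 60}
        t1 = stepwise(study.dataset, base, [CovariateCandidate("inducer")], fit_kwargs=kw)
        t2 = stepwise(study.dataset, base, [CovariateCandidate("inducer")], fit_kwargs=kw)
        assert [(s.phase, s.decision) for s in t1.steps] == [
            (s.phase, s.decision) for s in t2.steps
        ]
        assert t1.final_fit.ofv == pytest.approx(t2.final_fit.ofv, abs=1e-9)

    def test_backward_keeps_strong_effects(self, truth):
        """An effect whose removal costs more than 6.63 OFV units survives."""
        study = generate_rich_recovery_set(truth, 50, seed=101)
        base = dataclasses.replace(
            truth, theta=dataclasses.replace(truth.theta, inducer_coef=1.0)
        )
        trace = stepwise(
            study.dataset, base, [CovariateCandidate("inducer")],
            fit_kwargs={"gtol": 2e-2, "max_outer_iter": 60},
        )
        kept = [s for s in trace.steps if s.phase == "backward" and s.decision == "kept"]
        assert kept and all(s.delta_ofv >= s.threshold for s in kept)
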