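"""Bootstrap, CWRES and pcVPC behavior."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from poptk.data import PKDataset
from poptk.evaluation import bootstrap, cwres, pcvpc, point_estimates
from poptk.nlme import fit

FAST_FIT = {"gtol": 1e-2, "max_outer_iter": 120}


class TestBootstrap:
    def test_seed_determinism(self, study20, fit20):
        b1 = bootstrap(study20.dataset, fit20.model, n=3, seed=9, fit_kwargs=FAST_FIT)
        b2 = bootstrap(study20.dataset, fit20.model, n=3, seed=9, fit_kwargs=FAST_FIT)
        pd.testing.assert_frame_equal(b1.estimates, b2.estimates)
        assert b1.convergence_rate == b2.convergence_rate

    def test_degenerate_bootstrap_recovers_point_estimate(self, truth, study20):
        """If every resample reproduces the original data (all subjects
        identical), the bootstrap median equals the point estimate."""
        df1 = study20.dataset.subject(study20.dataset.subject_ids[0])
        clones = [df1.assign(ID=i) for i in range(1, 4)]
        ds = PKDataset(pd.concat(clones, ignore_index=True))
        model = fit(ds, truth, fixed=["omega", "sigma"]).model
        b = bootstrap(ds, model, n=2, seed=1,
                      fit_kwargs=dict(FAST_FIT, fixed=["omega", "sigma"]))
        point = point_estimates(model)
        summ = b.summary()
        for key in ("cl_tv", "v1_tv"):
            assert summ.loc[key, "median"] == pytest.approx(point[key], rel=0.02)

    def test_invalid_n_rejected(self, study20, fit20):
        with pytest.raises(ValueError):
            bootstrap(study20.dataset, fit20.model, n=0)

    def test_convergence_rate_always_reported(self, study20, fit20):
        b = bootstrap(study20.dataset, fit20.model, n=2, seed=3, fit_kwargs=FAST_FIT)
        assert 0.0 <= b.convergence_rate <= 100.0
        assert b.n_requested == 2


class TestCwres:
    def test_distribution_under_correct_model(self, study20, fit20):
        """Self-simulated data: CWRES should be ~N(0,1) at ~240 residuals."""
        cw = cwres(study20.dataset, fit20)
        assert len(cw) == study20.dataset.n_obs
        assert abs(cw["CWRES"].mean()) < 0.1
        assert 0.8 < cw["CWRES"].var() < 1.2

    def test_detects_gross_misspecification(self, study20, fit20):
        """A tenfold clearance error leaves large systematic residuals."""
        th = dataclasses.replace(fit20.model.theta, cl_tv=fit20.model.theta.cl_tv * 10)
        wrong = dataclasses.replace(fit20.model, theta=th)
        bad_fit = fit(study20.dataset, wrong,
                      fixed=["cl_tv", "v1_tv", "q2_tv", "v2_tv", "q3_tv", "v3_tv",
                             "inducer_coef", "omega", "sigma"])
        cw = cwres(study20.dataset, bad_fit)
        assert cw["CWRES"].abs().mean() > 2.0

    def test_scalar_case_reduces_to_standardized_residual(self, truth):
        """One observation, no eta influence: CWRES = (y - E)/sd."""
        from poptk.nlme import _Design, _Engine
        import poptk.pkmodel as pk

        df = pd.DataFrame(
            [
                dict(ID=1, TIME=0.0, AMT=25.0, RATE=150.0, EVID=1, MDV=1, DV=np.nan,
                     WT=70.0, INDUCER=0, AGE=40.0, SEX=0, CRCL=100.0),
                dict(ID=1, TIME=24.0, AMT=np.nan, RATE=np.nan, EVID=0, MDV=0, DV=0.25,
                     WT=70.0, INDUCER=0, AGE=40.0, SEX=0, CRCL=100.0),
            ]
        )
        ds = PKDataset(df)
        res = fit(ds, truth, fixed=["cl_tv", "v1_tv", "q2_tv", "v2_tv", "q3_tv",
                                    "v3_tv", "inducer_coef", "omega", "sigma"])
        cw = cwres(ds, res)
        assert len(cw) == 1
        # independent computation of the linearized mean and variance
        eta_hat = res.eta_hat[0]
        design = _Design(ds)
        engine = _Engine(design, res.model)
        f = engine._f(eta_hat[None, None, :])[0, 0, 0]
        h = 1e-5
        J = np.array([
            (engine._f((eta_hat + h * np.eye(3)[k])[None, None, :])[0, 0, 0] - f) / h
            for k in range(3)
        ])
        e_lin = f - J @ eta_hat
        var = J @ res.model.omega.matrix @ J + res.model.sigma_prop * f * f
        expected = (0.25 - e_lin) / np.sqrt(var)
        assert cw["CWRES"].iloc[0] == pytest.approx(expected, rel=1e-6)


class TestPcVpc:
    def test_bins_partition_observations(self, study20, truth):
        v = pcvpc(study20.dataset, truth, n_sim=50, seed=4)
        assert v.bin_n_obs.sum() == study20.dataset.n_obs
        assert len(v.bin_times) == 12  # one bin per nominal sampling time

    def test_prediction_correction_identity_when_pred_constant(self, truth):
        """All subjects identical -> PRED constant in a bin -> pc is a no-op."""
        from poptk.synthetic import StudyConfig, generate_study

        cfg = StudyConfig(n_subjects=6, wt_log_sd=1e-9, inducer_fraction=0.0)
        study = generate_study(truth, cfg, seed=8)
        v_pc = pcvpc(study.dataset, truth, n_sim=40, seed=5)
        v_raw = pcvpc(study.dataset, truth, n_sim=40, seed=5,
                      prediction_corrected=False)
        pd.testing.assert_frame_equal(v_pc.obs_percentiles, v_raw.obs_percentiles,
                                      atol=1e-9)

    def test_invariant_to_subject_relabeling(self, study20, truth):
        df = study20.dataset.df.copy()
        relabeled = PKDataset(df.assign(ID=df["ID"].map(lambda i: f"S{100 - i}")))
        v1 = pcvpc(study20.dataset, truth, n_sim=60, seed=6)
        v2 = pcvpc(relabeled, truth, n_sim=60, seed=6)
        pd.testing.assert_frame_equal(v1.obs_percentiles, v2.obs_percentiles,
                                      atol=1e-12)

    def test_stratified_union_covers_all_observations(self, study20, truth):
        strata = pcvpc(study20.dataset, truth, n_sim=50, seed=7, stratify="INDUCER")
        assert set(strata) == {0, 1}
        total = sum(v.bin_n_obs.sum() for v in strata.values())
        assert total == study20.dataset.n_obs

    def test_small_bins_merged(self, truth):
        """Single-subject study: one observation per nominal time, so bins
        must merge until each holds at least two observations."""
        from poptk.synthetic import StudyConfig, generate_study

        study = generate_study(truth, StudyConfig(n_subjects=1, inducer_fraction=0.0,
                                                  female_fraction=0.0), seed=2)
        with pytest.warns(UserWarning, match="merged"):
            v = pcvpc(study.dataset, truth, n_sim=30, seed=3)
        assert v.bin_n_obs.sum() == study.dataset.n_obs
        assert np.all(v.bin_n_obs >= 2)
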