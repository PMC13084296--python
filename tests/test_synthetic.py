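"""Virtual-study generator: design fidelity, stochastic structure, truths."""

import dataclasses

import numpy as np
import pytest

from poptk.pkmodel import OmegaMatrix, StructuralParams, DoseEvent, predict_conc
from poptk.synthetic import (
    SCHEDULED_POSTDOSE,
    StudyConfig,
    generate_rich_recovery_set,
    generate_study,
    reference_model,
)


class TestReferenceModel:
    def test_typical_values(self, truth):
        th = truth.theta
        assert (th.cl_tv, th.v1_tv, th.q2_tv, th.v2_tv, th.q3_tv, th.v3_tv) == (
            1.31, 9.84, 197.0, 39.1, 0.6, 9.01,
        )
        assert th.inducer_coef == 1.63
        assert truth.sigma_prop == 0.02

    def test_iiv_matches_published_cv(self, truth):
        cvs = truth.omega.cv_percents
        assert cvs["cl"] == pytest.approx(33.5, abs=0.05)
        assert cvs["v1"] == pytest.approx(18.1, abs=0.05)
        assert cvs["v2"] == pytest.approx(19.3, abs=0.05)

    def test_covariance_reading_of_offdiagonals_is_not_psd(self):
        """The printed off-diagonal 0.06 exceeds the largest covariance the
        CL/V1 variances allow, so only the correlation reading yields a
        valid Omega."""
        with pytest.raises(ValueError):
            reference_model(offdiag="covariance")


class TestGenerateStudy:
    def test_default_design(self, study20):
        ds = study20.dataset
        assert ds.n_subjects == 20
        assert ds.n_obs == 20 * len(SCHEDULED_POSTDOSE)
        cov = ds.covariates()
        assert cov["INDUCER"].sum() == 7  # 35% of 20
        assert cov["SEX"].sum() == 13  # 65% female
        doses = ds.df[ds.df["EVID"] == 1]
        assert (doses["AMT"] == 25.0).all()
        np.testing.assert_allclose(doses["RATE"], 150.0, rtol=1e-9)

    def test_covariates_respect_truncation(self, truth):
        for seed in range(5):
            cov = generate_study(truth, seed=seed).dataset.covariates()
            assert cov["WT"].between(54.5, 150.3).all()
            assert cov["AGE"].between(18.0, 80.0).all()
            assert cov["CRCL"].between(46.0, 206.0).all()

    def test_no_randomness_gives_identical_profiles(self, truth):
        """Omega = 0 and sigma = 0-ish: subjects with equal weight and
        inducer status have identical concentration profiles."""
        frozen = dataclasses.replace(
            truth,
            omega=OmegaMatrix(np.zeros((3, 3)), truth.omega.names),
            sigma_prop=1e-30,
        )
        cfg = StudyConfig(n_subjects=4, wt_log_sd=1e-12, inducer_fraction=0.0)
        study = generate_study(frozen, cfg, seed=3)
        obs = study.dataset.observations
        profiles = obs.pivot_table(index="ID", columns="TIME", values="DV").to_numpy()
        np.testing.assert_allclose(
            profiles, np.broadcast_to(profiles[0], profiles.shape), rtol=1e-6
        )

    def test_truth_table_matches_generated_parameters(self, study20, truth):
        """Realized CL in the sidecar equals the covariate/eta map exactly."""
        cov = study20.dataset.covariates().set_index("ID")
        for row in study20.truth.itertuples(index=False):
            c = cov.loc[row.ID]
            expected = (
                1.31 * (c.WT / 70) ** 0.75 * 1.63**c.INDUCER * np.exp(row.eta_cl)
            )
            assert row.cl == pytest.approx(expected, rel=1e-12)

    def test_eta_sd_matches_omega(self, truth):
        """Monte-Carlo moment check of the clearance random effect."""
        cfg = StudyConfig(n_subjects=10000, sampling_times_h=(1.0,))
        study = generate_study(truth, cfg, seed=19)
        sd = study.truth["eta_cl"].std(ddof=1)
        assert sd == pytest.approx(np.sqrt(truth.omega.matrix[0, 0]), rel=0.02)

    def test_proportional_error_sd(self, truth):
        """Residual scatter of y/f - 1 reproduces sigma."""
        cfg = StudyConfig(n_subjects=2000, sampling_times_h=(0.5, 2.0, 12.0))
        study = generate_study(truth, cfg, seed=23)
        resid = _residuals(study, truth)
        assert np.std(resid, ddof=1) == pytest.approx(np.sqrt(0.02), rel=0.02)

    def test_negative_draws_redrawn_and_counted(self, truth):
        noisy = dataclasses.replace(truth, sigma_prop=0.5)
        study = generate_study(noisy, StudyConfig(n_subjects=50), seed=31)
        assert study.n_negative_redrawn > 0
        assert (study.dataset.observations["DV"] >= 0).all()


def _residuals(study, truth):
    """y/f - 1 for every observation, with f rebuilt from the truth table."""
    cov = study.dataset.covariates().set_index("ID")
    dose = [DoseEvent(0.0, 1 / 6, 25.0)]
    out = []
    tr = study.truth.set_index("ID")
    for sid, grp in study.dataset.observations.groupby("ID"):
        c = cov.loc[sid]
        fv = c.WT / 70.0
        fcl = fv**0.75
        p = StructuralParams(
            cl=tr.loc[sid, "cl"],
            v1=tr.loc[sid, "v1"],
            q2=197.0 * fcl,
            v2=tr.loc[sid, "v2"],
            q3=0.6 * fcl,
            v3=9.01 * fv,
        )
        f = predict_conc(p, dose, grp["TIME"].to_numpy())
        out.extend(grp["DV"].to_numpy() / f - 1.0)
    return np.asarray(out)


class TestRichRecoverySet:
    def test_full_schedule_no_missingness(self, rich50):
        assert rich50.dataset.n_subjects == 50
        assert rich50.dataset.n_obs == 50 * len(SCHEDULED_POSTDOSE)

    def test_design_identical_across_seeds_dv_differs(self, truth):
        a = generate_rich_recovery_set(truth, 10, seed=1).dataset.df
        b = generate_rich_recovery_set(truth, 10, seed=2).dataset.df
        design_cols = ["ID", "TIME", "AMT", "RATE", "EVID", "MDV"]
        assert a[design_cols].equals(b[design_cols])
        assert not np.allclose(
            a.loc[a.EVID == 0, "DV"].fillna(0), b.loc[b.EVID == 0, "DV"].fillna(0)
        )

    def test_null_inducer_effect_uncorrelated_with_cl(self, truth):
        null = dataclasses.replace(
            truth, theta=dataclasses.replace(truth.theta, inducer_coef=1.0)
        )
        study = generate_rich_recovery_set(null, 1000, seed=5)
        merged = study.truth.merge(study.dataset.covariates(), on="ID")
        log_cl_resid = np.log(merged["cl"]) - 0.75 * np.log(merged["WT"] / 70.0)
        r = np.corrcoef(merged["INDUCER"], log_cl_resid)[0, 1]
        assert abs(r) < 0.1

    def test_too_few_subjects_rejected(self, truth):
        with pytest.raises(ValueError):
            generate_rich_recovery_set(truth, 1)
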