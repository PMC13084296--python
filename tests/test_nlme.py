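"""Estimator checks: quadrature oracle, degenerate limits, SEs, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from poptk.data import PKDataset
from poptk.nlme import (
    PopulationModel,
    _Packer,
    fit,
    initial_model,
    ofv,
    standard_errors,
)
from poptk.pkmodel import (
    DoseEvent,
    OmegaMatrix,
    StructuralParams,
    ThetaVector,
    predict_conc,
)

TOY_OM2 = 0.1
TOY_SIG2 = 0.01
TOY_TIMES = [0.5, 4.0, 24.0]


def _toy_dataset(seed: int) -> PKDataset:
    """Two subjects, three observations each, 1-compartment, eta on CL."""
    rng = np.random.default_rng(seed)
    rows = []
    for sid in (1, 2):
        eta = rng.normal(0, np.sqrt(TOY_OM2))
        p = StructuralParams(cl=1.3 * np.exp(eta), v1=10.0)
        f = predict_conc(p, [DoseEvent(0, 1 / 6, 25)], TOY_TIMES, ncomp=1)
        rows.append(dict(ID=sid, TIME=0.0, AMT=25.0, RATE=150.0, EVID=1, MDV=1,
                         DV=np.nan, WT=70.0, INDUCER=0, AGE=40.0, SEX=0, CRCL=100.0))
        for t, ff in zip(TOY_TIMES, f):
            y = ff * (1 + rng.normal(0, np.sqrt(TOY_SIG2)))
            rows.append(dict(ID=sid, TIME=t, AMT=np.nan, RATE=np.nan, EVID=0, MDV=0,
                             DV=y, WT=70.0, INDUCER=0, AGE=40.0, SEX=0, CRCL=100.0))
    return PKDataset(pd.DataFrame(rows))


def _toy_model(om2: float = TOY_OM2) -> PopulationModel:
    return PopulationModel(
        theta=ThetaVector(cl_tv=1.3, v1_tv=10.0),
        omega=OmegaMatrix(np.array([[om2]]), ("cl",)),
        sigma_prop=TOY_SIG2,
        structure=1,
    )


def _neg2ll_by_quadrature(ds: PKDataset, model: PopulationModel) -> float:
    """Oracle: -2 log marginal likelihood by adaptive 1-D integration."""
    om2 = float(model.omega.matrix[0, 0])
    total = 0.0
    for sid in ds.subject_ids:
        obs = ds.df[(ds.df.ID == sid) & (ds.df.EVID == 0) & (ds.df.MDV == 0)]
        y, t = obs.DV.to_numpy(), obs.TIME.to_numpy()

        def integrand(eta):
            p = StructuralParams(cl=model.theta.cl_tv * np.exp(eta), v1=model.theta.v1_tv)
            f = predict_conc(p, [DoseEvent(0, 1 / 6, 25)], t, ncomp=1)
            v = model.sigma_prop * f * f
            ll = -0.5 * np.sum(np.log(2 * np.pi * v) + (y - f) ** 2 / v)
            ll += -0.5 * (np.log(2 * np.pi * om2) + eta**2 / om2)
            return np.exp(ll)

        val, _ = quad(integrand, -3.5, 3.5, limit=400)
        total += -2.0 * np.log(val)
    return total


class TestObjectiveFunction:
    @pytest.mark.parametrize("seed", [0, 1, 2, 42])
    @pytest.mark.parametrize("flavor", ["gn", "fd"])
    def test_matches_quadrature_oracle(self, seed, flavor):
        ds = _toy_dataset(seed)
        model = _toy_model()
        exact = _neg2ll_by_quadrature(ds, model)
        assert ofv(ds, model, laplace_hessian=flavor) == pytest.approx(exact, abs=0.1)

    def test_vanishing_omega_gives_pooled_likelihood(self):
        """As Omega -> 0 the marginal collapses onto eta = 0."""
        ds = _toy_dataset(7)
        tiny = ofv(ds, _toy_model(om2=1e-10))
        # pooled -2LL with eta = 0 computed directly
        pooled = 0.0
        for sid in (1, 2):
            obs = ds.df[(ds.df.ID == sid) & (ds.df.EVID == 0) & (ds.df.MDV == 0)]
            y, t = obs.DV.to_numpy(), obs.TIME.to_numpy()
            f = predict_conc(StructuralParams(cl=1.3, v1=10.0),
                             [DoseEvent(0, 1 / 6, 25)], t, ncomp=1)
            v = TOY_SIG2 * f * f
            pooled += np.sum(np.log(2 * np.pi * v) + (y - f) ** 2 / v)
        assert tiny == pytest.approx(pooled, abs=1e-3)

    def test_deterministic(self, study20, truth):
        assert ofv(study20.dataset, truth) == ofv(study20.dataset, truth)

    def test_non_psd_omega_rejected(self, study20, truth):
        import dataclasses
        bad = np.array([[0.1, 0.2, 0.0], [0.2, 0.1, 0.0], [0.0, 0.0, 0.1]])
        with pytest.raises(ValueError):
            om = OmegaMatrix(bad, ("cl", "v1", "v2"))
            ofv(study20.dataset, dataclasses.replace(truth, omega=om))


class TestFit:
    def test_all_fixed_is_noop(self, study20, truth):
        res = fit(
            study20.dataset,
            truth,
            fixed=["cl_tv", "v1_tv", "q2_tv", "v2_tv", "q3_tv", "v3_tv",
                   "inducer_coef", "omega", "sigma"],
        )
        assert res.converged
        assert res.ofv == pytest.approx(ofv(study20.dataset, truth), abs=1e-4)

    def test_fit_does_not_increase_ofv(self, fit20, study20, truth):
        assert fit20.ofv <= ofv(study20.dataset, truth) + 1e-6

    def test_refit_from_estimates_is_stationary(self, fit20, study20):
        res2 = fit(study20.dataset, fit20.model)
        assert abs(res2.ofv - fit20.ofv) < 0.01

    def test_underidentified_dataset_rejected(self):
        full = _toy_dataset(3).df
        ds = PKDataset(
            full.groupby("ID", group_keys=False).head(2)  # dose + 1 obs each
        )
        assert ds.n_obs == 2
        with pytest.raises(ValueError, match="identify"):
            fit(ds, _toy_model())  # 4 free parameters, 2 observations

    def test_heuristic_init_reaches_same_optimum(self, rich50, truth):
        """A data-informed cold start lands at the truth-started optimum."""
        res_cold = fit(rich50.dataset, initial_model(rich50.dataset),
                       estimate_inducer=True)
        res_warm = fit(rich50.dataset, truth)
        assert res_cold.converged
        assert abs(res_cold.ofv - res_warm.ofv) < 1.0
        nat_c = res_cold._packer.natural_params(res_cold.model)
        nat_w = res_warm._packer.natural_params(res_warm.model)
        assert nat_c["cl_tv"] == pytest.approx(nat_w["cl_tv"], rel=0.02)

    def test_cl_shrinkage_small_on_rich_data(self, fit20):
        assert abs(fit20.shrinkage["cl"]) < 10.0


class TestParameterRecovery:
    def test_median_bias_of_fixed_effects(self, recovery_fits, truth):
        """Median relative bias over 20 replicate studies.

        Well-identified fixed effects within 10%; the sparse deep
        compartment (Q3, V3) within 30%.
        """
        true_vals = {
            "cl_tv": 1.31, "v1_tv": 9.84, "q2_tv": 197.0, "v2_tv": 39.1,
            "inducer_coef": 1.63, "q3_tv": 0.6, "v3_tv": 9.01,
        }
        ests = pd.DataFrame([nat for nat, _ in recovery_fits])
        for name, tv in true_vals.items():
            bias = np.median(ests[name] / tv - 1.0)
            tol = 0.30 if name in ("q3_tv", "v3_tv") else 0.10
            assert abs(bias) < tol, f"{name}: median bias {bias:.3f}"

    def test_most_fits_converge(self, recovery_fits):
        conv = sum(res.converged for _, res in recovery_fits)
        assert conv >= 16  # >= 80% of replicates


class TestStandardErrors:
    def test_information_doubles_with_duplicated_data(self):
        """Duplicating every subject shrinks SEs by ~1/sqrt(2)."""
        base = _toy_dataset(5)
        frames = [base.df]
        for k in range(1, 4):  # 8 subjects total for a stable fit
            frames.append(_toy_dataset(5 + k).df.assign(ID=lambda d, k=k: d.ID + 10 * k))
        ds1 = PKDataset(pd.concat(frames, ignore_index=True))
        res1 = fit(ds1, _toy_model())
        se1, _ = standard_errors(ds1, res1)
        assert se1 is not None
        dup = pd.concat([ds1.df, ds1.df.assign(ID=ds1.df["ID"] + 1000)],
                        ignore_index=True)
        ds2 = PKDataset(dup)
        res2 = fit(ds2, res1.model)
        se2, _ = standard_errors(ds2, res2)
        assert se2 is not None
        ratios = [se2[k] / se1[k] for k in ("cl_tv", "v1_tv") if se1[k] > 0]
        assert np.median(ratios) == pytest.approx(1 / np.sqrt(2), rel=0.2)

    def test_rse_scale_matches_reported_precision(self, rich50, truth):
        """RSE of typical CL at n=50 is in the same range as the study's
        reported ~9.5% at n=20 (within a factor ~2, allowing for n)."""
        res = fit(rich50.dataset, truth)
        se, rse = standard_errors(rich50.dataset, res)
        assert se is not None
        assert 9.51 / 4 < rse["cl_tv"] < 9.51 * 2
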