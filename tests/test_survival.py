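import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from tumoronly.survival import (
    _cox_loglik,
    apply_exclusions,
    build_groups,
    cohort_summary,
    lasso_cox,
    load_clinical,
    refit_cox,
)


def clinical_frame(n=50, seed=0, died=0, neo=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "cancer_type": rng.choice(["CC", "RC"], size=n),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n),
            "os_time": rng.exponential(60, size=n) + 0.1,
            "os_event": rng.integers(0, 2, size=n),
            "pfs_time": rng.exponential(40, size=n) + 0.1,
            "pfs_event": rng.integers(0, 2, size=n),
            "died_within_month": False,
            "neoadjuvant": False,
        }
    )
    df.loc[: died - 1, "died_within_month"] = True
    df.loc[died : died + neo - 1, "neoadjuvant"] = True
    return df


def simulate_survival(seed, n=400, prev=0.10, hr=3.0, n_null=0,
                      baseline=np.log(2) / 60, censor_max=120.0):
    """Carrier indicators plus exponential PH survival times."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"planted": (rng.random(n) < prev).astype(int)})
    for j in range(n_null):
        X[f"null{j}"] = (rng.random(n) < prev).astype(int)
    h = baseline * np.where(X["planted"] == 1, hr, 1.0)
    T = rng.exponential(1 / h)
    C = rng.uniform(0, censor_max, n)
    return X, np.minimum(T, C), (T <= C).astype(int)


class TestClinicalLoader:
    def test_round_trip_and_validation(self, tmp_path):
        df = clinical_frame()
        path = tmp_path / "clin.tsv"
        df.to_csv(path, sep="\t", index=False)
        loaded = load_clinical(path)
        assert len(loaded) == len(df)

    def test_rejects_unknown_stage(self):
        df = clinical_frame()
        df.loc[0, "stage"] = "V"
        with pytest.raises(ValueError, match="stage"):
            load_clinical(df)

    def test_rejects_nonpositive_times(self):
        df = clinical_frame()
        df.loc[0, "os_time"] = 0.0
        with pytest.raises(ValueError, match="os_time"):
            load_clinical(df)


class TestExclusions:
    def test_planted_flags_all_removed(self):
        df = clinical_frame(n=100, died=24, neo=4)
        kept, removed = apply_exclusions(df)
        assert removed.sum() == 28
        assert len(kept) == 72
        assert not kept["died_within_month"].any()
        assert not kept["neoadjuvant"].any()

    def test_no_flags_is_identity(self):
        df = clinical_frame(n=30)
        kept, removed = apply_exclusions(df)
        assert removed.sum() == 0
        assert len(kept) == 30


class TestGroups:
    def test_eight_groups_with_correct_membership(self):
        df = clinical_frame(n=200, seed=3)
        groups = build_groups(df)
        assert len(groups) == 8
        assert not (groups["os_pooled_I-III"].data["stage"] == "IV").any()
        assert set(groups["pfs_cc_I-IV"].data["cancer_type"]) == {"CC"}

    def test_cc_rc_partition_pooled(self):
        df = clinical_frame(n=200, seed=4)
        g = build_groups(df)
        cc = set(g["pfs_cc_I-III"].data["patient_id"])
        rc = set(g["pfs_rc_I-III"].data["patient_id"])
        pooled = set(g["pfs_pooled_I-III"].data["patient_id"])
        assert cc | rc == pooled and not cc & rc

    def test_sizes_match_brute_force(self):
        df = clinical_frame(n=300, seed=5)
        g = build_groups(df)
        expected = len(
            df[(df["stage"] != "IV") & (df["cancer_type"] == "RC")]
        )
        assert len(g["pfs_rc_I-III"].data) == expected


class TestCoxLoglik:
    def test_matches_lifelines_at_fitted_beta(self):
        X, t, e = simulate_survival(1, n=80)
        df = pd.DataFrame({"time": t, "event": e, "x": X["planted"]})
        cph = CoxPHFitter().fit(df, "time", "event")
        ours = _cox_loglik(
            X[["planted"]].to_numpy(float),
            np.array([cph.params_["x"]]), t, e,
        )
        assert ours == pytest.approx(cph.log_likelihood_, rel=1e-6)


class TestLassoCox:
    def test_duplicated_covariate_not_doubly_selected(self):
        X, t, e = simulate_survival(2, n=300, prev=0.15)
        X["copy"] = X["planted"]
        res = lasso_cox(X, t, e, seed=2)
        assert len(set(res.selected) & {"planted", "copy"}) <= 1

    def test_all_zero_covariate_changes_nothing(self):
        X, t, e = simulate_survival(3, n=300, prev=0.15)
        base = lasso_cox(X, t, e, seed=3)
        X2 = X.copy()
        X2["zeros"] = 0
        with pytest.warns(UserWarning, match="constant"):
            aug = lasso_cox(X2, t, e, seed=3)
        assert set(aug.selected) == set(base.selected)
        assert "zeros" in aug.dropped_constant

    def test_no_events_rejected(self):
        X, t, _ = simulate_survival(4, n=50)
        with pytest.raises(ValueError, match="events"):
            lasso_cox(X, t, np.zeros(50, dtype=int))

    def test_selected_support_stable_across_elastic_net_mixing(self):
        """Well-separated planted effects select identically for any mixing
        weight; only coefficient sizes change."""
        rng = np.random.default_rng(0)
        n = 400
        X = pd.DataFrame(
            {
                "hot1": (rng.random(n) < 0.15).astype(int),
                "hot2": (rng.random(n) < 0.20).astype(int),
            }
        )
        h = np.log(2) / 60 * 3.0 ** X["hot1"] * 2.5 ** X["hot2"]
        T = rng.exponential(1 / h)
        C = rng.uniform(0, 120, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        supports = []
        coefs = []
        for alpha in (0.2, 0.5, 1.0):
            res = lasso_cox(X, t, e, alpha=alpha, seed=0)
            supports.append(frozenset(res.selected))
            coefs.append(res.coefficients["hot1"])
        assert supports[0] == supports[1] == supports[2] == {"hot1", "hot2"}
        # coefficient magnitudes, by contrast, vary with the mixing weight
        assert len({round(c, 6) for c in coefs}) > 1


class TestRefitCox:
    def test_hr_matches_partial_likelihood_grid_argmax(self):
        """Profile grid maximization of the Breslow partial likelihood on a
        small cohort brackets the refit estimate."""
        X, t, e = simulate_survival(6, n=50, prev=0.3, hr=2.5)
        out = refit_cox(["planted"], X, t, e)
        hr = out["hazard_ratio"].iloc[0]
        grid = np.linspace(-2.5, 2.5, 801)
        Xv = X[["planted"]].to_numpy(float)
        lls = [_cox_loglik(Xv, np.array([b]), t, e) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert np.log(hr) == pytest.approx(best, abs=0.01)

    def test_null_covariate_hr_converges_to_one(self):
        X, t, e = simulate_survival(7, n=2000, prev=0.3, hr=1.0)
        out = refit_cox(["planted"], X, t, e)
        assert abs(out["hazard_ratio"].iloc[0] - 1.0) < 0.15

    def test_degenerate_covariate_reported_not_fitted(self):
        X, t, e = simulate_survival(8, n=40)
        X["empty"] = 0
        out = refit_cox(["empty"], X, t, e)
        assert out["degenerate"].iloc[0]
        assert np.isnan(out["hazard_ratio"].iloc[0])

    def test_logrank_and_wald_agree_on_strong_effect(self):
        X, t, e = simulate_survival(9, n=400, prev=0.2, hr=3.0)
        out = refit_cox(["planted"], X, t, e)
        assert out["logrank_p"].iloc[0] < 0.01
        assert out["wald_p"].iloc[0] < 0.01


class TestCohortSummary:
    def test_crosstab_consistency(self):
        df = clinical_frame(n=120, seed=10)
        s = cohort_summary(load_clinical(df))
        assert s["stage_by_type"].to_numpy().sum() == 120
        assert s["n_pfs"] == df["pfs_time"].notna().sum()
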