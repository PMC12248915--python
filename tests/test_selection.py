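import numpy as np
import pandas as pd
import pytest

from hpmfm import (
    SelectionConfig,
    adjusted_c_index,
    build_mps,
    cluster_and_select,
    correlogram,
    cox_fit,
    loo_stability,
    mps_score,
    rank_and_retain,
)


def _clinical(rng, n, times=None, events=None):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "age": rng.normal(69, 10, n).round(1),
            "psa": rng.lognormal(np.log(13.9), 1.0, n).round(2),
            "ldh": rng.lognormal(np.log(208), 0.3, n).round(1),
            "alp": rng.lognormal(np.log(76), 0.4, n).round(1),
            "pfs_months": times if times is not None else rng.exponential(10, n),
            "pfs_event": events if events is not None else np.ones(n, int),
            "os_months": (times * 2 if times is not None else rng.exponential(20, n)),
            "os_event": np.ones(n, int),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(321)


class TestAdjustedC:
    def test_weighted_combination_of_endpoint_cs(self, rng):
        n = 40
        clin = _clinical(rng, n)
        x = rng.normal(size=n)
        cfg = SelectionConfig()
        c_pfs = cox_fit(
            pd.DataFrame({"f": x}),
            clin["pfs_months"].to_numpy(), clin["pfs_event"].to_numpy(),
        ).c_index
        c_os = cox_fit(
            pd.DataFrame({"f": x}),
            clin["os_months"].to_numpy(), clin["os_event"].to_numpy(),
        ).c_index
        assert adjusted_c_index(x, clin, cfg) == pytest.approx(
            0.8 * c_pfs + 0.2 * c_os
        )

    def test_degenerate_weighting_reduces_to_pfs(self, rng):
        clin = _clinical(rng, 30)
        x = rng.normal(size=30)
        cfg = SelectionConfig(w_pfs=1.0, w_os=0.0)
        c_pfs = cox_fit(
            pd.DataFrame({"f": x}),
            clin["pfs_months"].to_numpy(), clin["pfs_event"].to_numpy(),
        ).c_index
        assert adjusted_c_index(x, clin, cfg) == pytest.approx(c_pfs)

    def test_constant_feature_is_nan(self, rng):
        clin = _clinical(rng, 20)
        assert np.isnan(adjusted_c_index(np.full(20, 3.0), clin))

    def test_example_arithmetic(self):
        """0.8 x 0.813 + 0.2 x 0.879 = 0.8262 by the weighting rule."""
        assert 0.8 * 0.813 + 0.2 * 0.879 == pytest.approx(0.8262)


class TestRankAndRetain:
    def test_ceil_retention_count(self, rng):
        n = 30
        clin = _clinical(rng, n)
        feats = pd.DataFrame(
            rng.normal(size=(n, 7)),
            columns=[f"f{i}" for i in range(7)],
            index=clin["patient_id"],
        )
        cfg = SelectionConfig()
        res = rank_and_retain(feats, clin, cfg)
        # 7 features + 3 serology = 10 columns -> ceil(0.2 * 10) = 2
        assert len(res.retained) == 2
        assert res.matrix.shape[1] == 10

    def test_strong_driver_ranks_first(self, rng):
        """A feature proportional to the true log-hazard tops the ranking."""
        n = 100
        driver = rng.normal(size=n)
        t = 12.0 * (-np.log(rng.uniform(size=n)) / np.exp(1.2 * driver)) ** (1 / 1.2)
        clin = _clinical(rng, n, times=t)
        feats = pd.DataFrame(
            {"driver": driver, **{f"noise{i}": rng.normal(size=n) for i in range(8)}},
            index=clin["patient_id"],
        )
        res = rank_and_retain(feats, clin)
        assert res.retained[0] == "driver"

    def test_column_order_does_not_change_result(self, rng):
        n = 30
        clin = _clinical(rng, n)
        feats = pd.DataFrame(
            rng.normal(size=(n, 8)),
            columns=[f"f{i}" for i in range(8)],
            index=clin["patient_id"],
        )
        a = rank_and_retain(feats, clin)
        b = rank_and_retain(feats[list(reversed(feats.columns))], clin)
        assert a.retained == b.retained


class TestClusterAndSelect:
    def _blocks(self, rng, n=60):
        """Four latent factors, several near-copies of each."""
        cols = {}
        blocks = {}
        for b in range(4):
            z = rng.normal(size=n)
            for k in range(3):
                name = f"b{b}_f{k}"
                cols[name] = z + rng.normal(0, 0.05, n)
                blocks[name] = b
        return pd.DataFrame(cols), blocks

    def test_distance_rule(self, rng):
        x = rng.normal(size=50)
        mat = pd.DataFrame({"a": x, "b": x * 2.0, "c": -0.9 * x + rng.normal(0, 0.4, 50)})
        scores = pd.Series({"a": 0.9, "b": 0.8, "c": 0.7})
        res = cluster_and_select(mat, scores, SelectionConfig(n_clusters=2))
        r = res.correlogram
        assert r.loc["a", "b"] == pytest.approx(1.0)  # d = 0 for perfect correlation
        assert res.assignments["a"] == res.assignments["b"]

    def test_recovers_planted_blocks(self, rng):
        mat, blocks = self._blocks(rng)
        scores = pd.Series(
            {c: 0.7 + 0.01 * int(c[-1]) + 0.001 * int(c[1]) for c in mat.columns}
        )
        res = cluster_and_select(mat, scores, SelectionConfig(n_clusters=4))
        found = {}
        for c, k in res.assignments.items():
            found.setdefault(k, set()).add(blocks[c])
        assert all(len(v) == 1 for v in found.values())  # clusters pure
        for rep in res.representatives:
            peers = [c for c in mat.columns if blocks[c] == blocks[rep]]
            assert scores[rep] == max(scores[p] for p in peers)

    def test_too_few_features_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="n_clusters"):
            cluster_and_select(mat, pd.Series({"a": 1.0, "b": 0.9}), SelectionConfig())


class TestMps:
    def test_linear_score_zero_input(self):
        coefs = {"a": 0.5, "b": -2.0, "age": 0.1}
        assert mps_score(coefs, {"a": 0.0, "b": 0.0, "age": 0.0}) == 0.0

    def test_published_style_coefficient_arithmetic(self):
        """Fixed coefficient vector applied to a reference patient."""
        coefs = {
            "kPL_median": 0.269,
            "elongation": -3.069,
            "kPL_p90": 0.165,
            "psa": 0.0063,
            "age": -0.0874,
        }
        vals = {"kPL_median": 17.0, "elongation": 0.8, "kPL_p90": 30.0,
                "psa": 13.9, "age": 69.0}
        assert mps_score(coefs, vals) == pytest.approx(1.1248, abs=1e-4)

    def test_build_mps_fits_and_dichotomizes(self, rng):
        n = 40
        driver = rng.normal(size=n)
        t = 12.0 * (-np.log(rng.uniform(size=n)) / np.exp(driver)) ** (1 / 1.2)
        clin = _clinical(rng, n, times=t)
        feats = pd.DataFrame(
            {"driver": driver, "other": rng.normal(size=n)},
            index=clin["patient_id"],
        )
        model = build_mps(feats, clin, ["driver", "other"])
        assert set(model.coefficients) == {"driver", "other", "age"}
        assert model.coefficients["driver"] > 0
        assert model.threshold == pytest.approx(float(model.scores.median()))
        assert model.km_pfs["low"].n + model.km_pfs["high"].n == n
        assert model.c_index["pfs"] > 0.6

    def test_covariate_shift_leaves_patient_ranking(self, rng):
        n = 30
        clin = _clinical(rng, n)
        feats = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n)},
            index=clin["patient_id"],
        )
        m1 = build_mps(feats, clin, ["a", "b"])
        m2 = build_mps(feats.assign(a=feats["a"] + 100.0), clin, ["a", "b"])
        r1 = m1.scores.rank()
        r2 = m2.scores.rank()
        assert np.allclose(r1, r2)
        low1 = set(m1.scores[m1.scores <= m1.threshold].index)
        low2 = set(m2.scores[m2.scores <= m2.threshold].index)
        assert low1 == low2

    def test_collinear_representatives_ridge_stabilized(self, rng):
        n = 30
        clin = _clinical(rng, n)
        x = rng.normal(size=n)
        feats = pd.DataFrame({"a": x, "b": 2.0 * x}, index=clin["patient_id"])
        model = build_mps(feats, clin, ["a", "b"])
        assert model.ridge_stabilized
        assert np.isfinite(list(model.coefficients.values())).all()


class TestLooStability:
    def test_identical_patients_are_perfectly_stable(self):
        n = 16
        clin = pd.DataFrame(
            {
                "patient_id": [f"P{i:03d}" for i in range(n)],
                "age": 69.0, "psa": 10.0, "ldh": 200.0, "alp": 76.0,
                "pfs_months": 10.0, "pfs_event": 1,
                "os_months": 20.0, "os_event": 1,
            }
        )
        feats = pd.DataFrame(
            {"a": 1.0, "b": 2.0}, index=pd.Index(clin["patient_id"], name="patient_id")
        )
        res = loo_stability(feats, clin, ["a", "b"])
        assert res.n_refits == n
        assert all(v == 0.0 for v in res.normalized_sd.values())

    def test_sixteen_patients_sixteen_refits(self, rng):
        n = 16
        driver = rng.normal(size=n)
        t = 12.0 * (-np.log(rng.uniform(size=n)) / np.exp(driver)) ** (1 / 1.2)
        clin = _clinical(rng, n, times=t)
        feats = pd.DataFrame(
            {"driver": driver, "other": rng.normal(size=n)},
            index=clin["patient_id"],
        )
        res = loo_stability(feats, clin, ["driver", "other"])
        assert res.n_refits == 16
        assert res.coefficients.shape == (16, 3)
        sds = np.array(list(res.normalized_sd.values()))
        assert np.isfinite(sds).all() and (sds >= 0).all()

    def test_too_small_cohort_rejected(self, rng):
        clin = _clinical(rng, 2)
        feats = pd.DataFrame({"a": [1.0, 2.0]}, index=clin["patient_id"])
        with pytest.raises(ValueError, match="at least 3"):
            loo_stability(feats, clin, ["a"])


class TestCorrelogram:
    def test_perfect_and_anti_correlation_with_outcome(self, rng):
        n = 25
        clin = _clinical(rng, n)
        feats = pd.DataFrame(
            {
                "same_as_os": clin["os_months"].to_numpy(),
                "neg_os": -clin["os_months"].to_numpy(),
            },
            index=clin["patient_id"],
        )
        tab = correlogram(feats, clin)
        assert tab.loc["same_as_os", "OS"] == pytest.approx(1.0)
        assert tab.loc["neg_os", "OS"] == pytest.approx(-1.0)

    def test_independent_feature_weakly_correlated(self, rng):
        n = 200
        clin = _clinical(rng, n)
        feats = pd.DataFrame(
            {"noise": rng.normal(size=n)}, index=clin["patient_id"]
        )
        tab = correlogram(feats, clin)
        assert abs(tab.loc["noise", "OS"]) < 0.2
        assert abs(tab.loc["noise", "PFS"]) < 0.2
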