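"""Sample-level enrichment analysis: scaling, resampling null, calls."""

import numpy as np
import pandas as pd
import pytest

import crossheart as ch
from crossheart.normalize import FoldChangeMatrix
from tests.test_multivariate import fc_from_rows


class TestScaleCenter:
    def test_symmetric_column_unchanged_by_centering(self):
        df = pd.DataFrame({"c": [-4.0, 0.0, 4.0]})
        out = ch.scale_center(df)
        assert out.values["c"].tolist() == pytest.approx([-10.0, 0.0, 10.0])

    def test_asymmetric_column_hand_values(self):
        df = pd.DataFrame({"c": [0.0, 1.0, 4.0]})
        out = ch.scale_center(df)
        # scaled (-10, -5, 10), mean -5/3 subtracted
        assert out.values["c"].tolist() == pytest.approx(
            [-25 / 3, -10 / 3, 35 / 3]
        )
        assert out.column_meta.loc["c", "subtracted_mean"] == pytest.approx(-5 / 3)

    def test_constant_column_maps_to_zeros(self):
        df = pd.DataFrame({"c": [2.0, 2.0, 2.0]})
        out = ch.scale_center(df)
        assert (out.values["c"] == 0).all()
        assert bool(out.column_meta.loc["c", "degenerate"])

    def test_column_means_centered(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out = ch.scale_center(df)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
        spread = out.values + out.column_meta["subtracted_mean"]
        assert spread.to_numpy().min() >= -10 - 1e-9
        assert spread.to_numpy().max() <= 10 + 1e-9

    def test_maxabs_mode_preserves_zero(self):
        df = pd.DataFrame({"c": [-5.0, 0.0, 10.0]})
        out = ch.scale_center(df, mode="maxabs")
        scaled = out.values["c"] + out.column_meta.loc["c", "subtracted_mean"]
        assert scaled.tolist() == pytest.approx([-5.0, 0.0, 10.0])


def random_modules(ids, n_modules, size, rng, prefix="rand"):
    return ch.ModuleCollection({
        f"{prefix}_{i}": set(rng.choice(ids, size=size, replace=False))
        for i in range(n_modules)
    })


class TestSleaZ:
    def test_constant_column_degenerate_zero(self):
        df = pd.DataFrame(
            np.ones((30, 1)), columns=["c"],
            index=[f"g{i}" for i in range(30)],
        )
        mc = ch.ModuleCollection({"m": {f"g{i}" for i in range(10)}})
        res = ch.slea_z(df, mc, n_rand=100, seed=0)
        assert res.z.loc["m", "c"] == 0.0
        assert bool(res.degenerate.loc["m", "c"])

    def test_null_modules_rarely_cross_threshold(self):
        rng = np.random.default_rng(10)
        ids = [f"g{i}" for i in range(2000)]
        df = pd.DataFrame(
            rng.normal(size=(2000, 1)), index=ids, columns=["c"]
        )
        mc = random_modules(np.array(ids), 1000, 50, rng)
        res = ch.slea_z(df, mc, n_rand=2000, seed=1)
        assert (res.z["c"].abs() < 4).mean() >= 0.999

    def test_planted_extreme_module_huge_z(self):
        ids = [f"g{i}" for i in range(2000)]
        vals = np.zeros(2000)
        vals[:50] = 100.0
        df = pd.DataFrame({"c": vals}, index=ids)
        mc = ch.ModuleCollection({"hot": set(ids[:50])})
        res = ch.slea_z(df, mc, n_rand=2000, seed=2)
        assert res.z.loc["hot", "c"] > 20

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(200)]
        df = pd.DataFrame(rng.normal(size=(200, 3)), index=ids,
                          columns=list("abc"))
        mc = random_modules(np.array(ids), 5, 20, rng)
        r1 = ch.slea_z(df, mc, n_rand=500, seed=9)
        r2 = ch.slea_z(df, mc, n_rand=500, seed=9)
        pd.testing.assert_frame_equal(r1.z, r2.z)
        pd.testing.assert_frame_equal(r1.null_sd, r2.null_sd)

    def test_invariant_to_column_shift_and_scale(self):
        rng = np.random.default_rng(4)
        ids = [f"g{i}" for i in range(300)]
        df = pd.DataFrame(rng.normal(size=(300, 2)), index=ids,
                          columns=["u", "v"])
        mc = random_modules(np.array(ids), 4, 25, rng)
        base = ch.slea_z(df, mc, n_rand=1000, seed=5)
        shifted = ch.slea_z(df + 7.0, mc, n_rand=1000, seed=5)
        scaled = ch.slea_z(df * 3.0, mc, n_rand=1000, seed=5)
        assert np.allclose(base.z, shifted.z, atol=1e-9)
        assert np.allclose(base.z, scaled.z, atol=1e-9)

    def test_raising_member_values_raises_z(self):
        rng = np.random.default_rng(6)
        ids = [f"g{i}" for i in range(500)]
        df = pd.DataFrame({"c": rng.normal(size=500)}, index=ids)
        members = set(ids[:30])
        mc = ch.ModuleCollection({"m": members})
        before = ch.slea_z(df, mc, n_rand=2000, seed=7).z.loc["m", "c"]
        boosted = df.copy()
        boosted.loc[list(members), "c"] += 1.0
        after = ch.slea_z(boosted, mc, n_rand=2000, seed=7).z.loc["m", "c"]
        assert after > before

    def test_too_small_modules_skipped_and_all_small_rejected(self):
        ids = [f"g{i}" for i in range(50)]
        df = pd.DataFrame({"c": np.arange(50.0)}, index=ids)
        mc = ch.ModuleCollection({"small": set(ids[:2]), "ok": set(ids[:10])})
        res = ch.slea_z(df, mc, n_rand=100, seed=0)
        assert list(res.z.index) == ["ok"]
        with pytest.raises(ValueError, match="enough members"):
            ch.slea_z(df, ch.ModuleCollection({"small": set(ids[:2])}),
                      n_rand=100, seed=0)

    def test_module_covering_all_rows_rejected(self):
        ids = [f"g{i}" for i in range(20)]
        df = pd.DataFrame({"c": np.arange(20.0)}, index=ids)
        mc = ch.ModuleCollection({"all": set(ids)})
        with pytest.raises(ValueError, match="no null"):
            ch.slea_z(df, mc, n_rand=100, seed=0)

    def test_members_resolve_through_pair_ids(self):
        ids = [f"gA{i}|gB{i}" for i in range(30)]
        df = pd.DataFrame({"c": np.arange(30.0)}, index=ids)
        mc = ch.ModuleCollection({"m": {f"gA{i}" for i in range(8)}})
        res = ch.slea_z(df, mc, n_rand=200, seed=0)
        assert "m" in res.z.index


class TestCallSignificant:
    def make_result(self, z):
        zdf = pd.DataFrame({"c": [z]}, index=["m"])
        flags = pd.DataFrame({"c": [False]}, index=["m"])
        return ch.SLEAResult(
            z=zdf, null_mean=zdf * 0, null_sd=zdf * 0 + 1,
            degenerate=flags, n_rand=100, seed=0,
        )

    def test_threshold_is_strict(self):
        assert len(ch.call_significant(self.make_result(4.1))) == 1
        assert len(ch.call_significant(self.make_result(4.0))) == 0

    def test_negative_direction(self):
        table = ch.call_significant(self.make_result(-7.0))
        assert table.iloc[0]["direction"] == "-"


def result_from_z(zdict, contrasts):
    z = pd.DataFrame(zdict).T
    z.columns = [ch.contrast_label(*c) for c in contrasts]
    flags = z * 0 == 1
    return ch.SLEAResult(z=z, null_mean=z * 0, null_sd=z * 0 + 1,
                         degenerate=flags, n_rand=100, seed=0,
                         contrasts=list(contrasts))


class TestDifferentialResponse:
    contrasts = [("A", "cryoinjured", 6.0), ("B", "cryoinjured", 6.0)]

    def test_identical_profiles_score_zero(self):
        res = result_from_z({"m": [2.0, 2.0]}, self.contrasts)
        table = ch.differential_response(res, matched_times=[6.0])
        assert table.iloc[0]["score"] == pytest.approx(0.0)

    def test_single_species_response_scores_difference(self):
        res = result_from_z({"m": [5.0, 0.0], "n": [1.0, 1.0]}, self.contrasts)
        table = ch.differential_response(res, matched_times=[6.0])
        assert table.iloc[0]["module"] == "m"
        assert table.iloc[0]["score"] == pytest.approx(5.0)

    def test_missing_matched_time_rejected(self):
        res = result_from_z({"m": [5.0, 0.0]}, self.contrasts)
        with pytest.raises(ValueError, match="matched time"):
            ch.differential_response(res, matched_times=[48.0])

    def test_ties_broken_by_module_name(self):
        res = result_from_z({"b": [3.0, 0.0], "a": [3.0, 0.0]}, self.contrasts)
        table = ch.differential_response(res, matched_times=[6.0])
        assert list(table["module"]) == ["a", "b"]


class TestUpstreamInputPrep:
    def test_strict_threshold(self):
        fc = fc_from_rows([[1.2, 0.0], [1.0, -1.0], [0.5, -1.3]])
        out = ch.upstream_input_prep(fc, 1.0)
        assert sorted(out.index) == ["g0", "g2"]

    def test_zero_threshold_keeps_any_nonzero(self):
        fc = fc_from_rows([[0.0, 0.0], [0.1, 0.0]])
        out = ch.upstream_input_prep(fc, 0.0)
        assert list(out.index) == ["g1"]
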