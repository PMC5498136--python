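"""Gene-set formats, annotation propagation, exact hypergeometric tails
and BH adjustment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import crossheart as ch


def write_gmt(tmp_path, lines):
    path = tmp_path / "sets.gmt"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestReadGMT:
    def test_two_modules(self, tmp_path):
        path = write_gmt(tmp_path, [
            "setA\tdesc\tg1\tg2\tg3",
            "setB\t\tg1\tg4\tg5\tg6\tg7",
        ])
        mc = ch.read_gmt(path)
        assert len(mc) == 2
        assert mc.sizes()["setA"] == 3 and mc.sizes()["setB"] == 5

    def test_duplicate_member_counted_once(self, tmp_path):
        path = write_gmt(tmp_path, ["setA\tdesc\tg1\tg1\tg2"])
        assert ch.read_gmt(path).sizes()["setA"] == 2

    def test_duplicate_module_name_rejected(self, tmp_path):
        path = write_gmt(tmp_path, ["setA\t\tg1", "setA\t\tg2"])
        with pytest.raises(ValueError, match="setA"):
            ch.read_gmt(path)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = write_gmt(tmp_path, ["setA\t\tg1", "broken_line"])
        with pytest.raises(ValueError, match=":2"):
            ch.read_gmt(path)


class TestPropagateAnnotations:
    def test_child_members_reach_parent(self):
        mc = ch.ModuleCollection({"child": {"g1"}, "parent": {"g9"}})
        out = ch.propagate_annotations(mc, {"child": {"parent"}})
        assert out.modules["parent"] == {"g1", "g9"}

    def test_diamond_dag_counts_once(self):
        mc = ch.ModuleCollection(
            {"leaf": {"g1"}, "mid1": {"a"}, "mid2": {"b"}, "root": {"r"}}
        )
        parents = {"leaf": {"mid1", "mid2"}, "mid1": {"root"}, "mid2": {"root"}}
        out = ch.propagate_annotations(mc, parents)
        assert out.modules["root"] == {"g1", "a", "b", "r"}

    def test_three_level_chain_union(self):
        mc = ch.ModuleCollection({"a": {"x"}, "b": {"y"}, "c": {"z"}})
        out = ch.propagate_annotations(mc, {"a": {"b"}, "b": {"c"}})
        assert out.modules["c"] == {"x", "y", "z"}

    def test_cycle_rejected_naming_edge(self):
        mc = ch.ModuleCollection({"a": {"x"}, "b": {"y"}})
        with pytest.raises(ValueError, match="cycle"):
            ch.propagate_annotations(mc, {"a": {"b"}, "b": {"a"}})


def brute_force_tails(N, K, n, k):
    """Exact tails by enumerating every size-n selection of the universe."""
    annotated = set(range(K))
    total = over = under = 0
    for sel in itertools.combinations(range(N), n):
        total += 1
        ov = len(annotated & set(sel))
        over += ov >= k
        under += ov <= k
    return over / total, under / total


class TestHypergeomTest:
    def test_worked_example_overrepresentation(self):
        p_over, _ = ch.hypergeom_test(10, 4, 5, 4)
        assert p_over == pytest.approx(6 / 252, abs=1e-12)

    def test_worked_example_underrepresentation(self):
        _, p_under = ch.hypergeom_test(10, 5, 5, 0)
        assert p_under == pytest.approx(1 / 252, abs=1e-12)

    def test_minimum_overlap_boundary(self):
        # K and n cover N, forcing k_min = n+K-N; there p_over = 1
        p_over, p_under = ch.hypergeom_test(10, 8, 6, 4)
        assert p_over == pytest.approx(1.0, abs=1e-12)
        assert p_under == pytest.approx(
            brute_force_tails(10, 8, 6, 4)[1], abs=1e-12
        )

    def test_matches_enumeration_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            N = int(rng.integers(1, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k_min, k_max = max(0, n + K - N), min(K, n)
            k = int(rng.integers(k_min, k_max + 1))
            expected = brute_force_tails(N, K, n, k)
            got = ch.hypergeom_test(N, K, n, k)
            assert got[0] == pytest.approx(expected[0], abs=1e-12)
            assert got[1] == pytest.approx(expected[1], abs=1e-12)

    def test_tail_complement_identity(self):
        from scipy.stats import hypergeom

        for (N, K, n, k) in [(20, 5, 8, 2), (50, 25, 10, 5), (7, 3, 3, 1)]:
            p_over, p_under = ch.hypergeom_test(N, K, n, k)
            pmf = hypergeom(N, K, n).pmf(k)
            assert p_over + p_under - pmf == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ch.hypergeom_test(10, 11, 5, 2)
        with pytest.raises(ValueError):
            ch.hypergeom_test(10, 4, 5, 5)  # k above min(K, n)


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ((0.01, 0.02, 0.03, 0.5), (0.04, 0.04, 0.04, 0.5)),
        ((0.5,), (0.5,)),
        ((0.2, 0.2, 0.2), (0.2, 0.2, 0.2)),
        ((0.04, 0.01, 0.03, 0.005), (0.04, 0.02, 0.04, 0.02)),
        ((1.0, 0.5, 0.25, 0.125, 0.0625),
         (1.0, 0.625, 0.41666666666666663, 0.3125, 0.3125)),
    ])
    def test_step_up_hand_examples(self, p, expected):
        assert ch.bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(size=30))
        q = ch.bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ch.bh_adjust([0.5, 1.5])


class TestEnrich:
    def setup_method(self):
        self.universe = {f"g{i}" for i in range(40)}
        self.modules = ch.ModuleCollection({
            "planted": {f"g{i}" for i in range(10)},
            "other": {f"g{i}" for i in range(10, 30)},
        })

    def test_selected_equals_universe_gives_trivial_p_over(self):
        table = ch.enrich(self.universe, self.universe, self.modules)
        assert (table["overlap"] == table["module_size"]).all()
        assert np.allclose(table["p_over"], 1.0)

    def test_empty_selection_gives_zero_overlap(self):
        table = ch.enrich(set(), self.universe, self.modules)
        assert (table["overlap"] == 0).all()
        assert ((table["p_under"] >= 0) & (table["p_under"] <= 1)).all()

    def test_depleted_selection_p_under_smallest_for_large_module(self):
        # 5 genes selected, none annotated: depletion is least likely by
        # chance for the larger module
        selected = {f"g{i}" for i in range(30, 35)}
        table = ch.enrich(selected, self.universe, self.modules).set_index(
            "module"
        )
        assert table.loc["other", "p_under"] < table.loc["planted", "p_under"]

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            ch.enrich({"alien"}, self.universe, self.modules)

    def test_planted_module_attains_smallest_q_over(self):
        selected = {f"g{i}" for i in range(10)}  # exactly the planted set
        table = ch.enrich(selected, self.universe, self.modules)
        assert table.iloc[0]["module"] == "planted"
        assert table.iloc[0]["q_over"] == table["q_over"].min()

    def test_small_modules_skipped(self):
        modules = ch.ModuleCollection({"tiny": {"g0", "g1"},
                                       "ok": {f"g{i}" for i in range(6)}})
        table = ch.enrich({"g0"}, self.universe, modules)
        assert list(table["module"]) == ["ok"]
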