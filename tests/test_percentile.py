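import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guidescreen.counts import CountMatrix
from guidescreen.percentile import (
    GroupStats,
    PercentileError,
    ZMatrix,
    call_percentile_hits,
    compute_group_stats,
    compute_zscores,
    gene_recurrence,
    nearest_rank_threshold,
    percentile_sets,
    recurrence,
)


def cm_from(values, groups, genes=None):
    df = pd.DataFrame(values, dtype=float)
    genes = pd.Series(genes or {g: "gene" for g in df.index})
    return CountMatrix(df, genes, groups, normalized=True)


# -- independent brute-force oracle (pure python, no shared code path) -------

def brute_force_zscores(values: pd.DataFrame, group_of: dict, control: str):
    """Direct re-derivation of mu, sigma, k, sem and z from the definitions."""
    samples_by_group = {}
    for s in values.columns:
        samples_by_group.setdefault(group_of[s], []).append(s)
    z = {}
    for g in values.index:
        ctrl_vals = [values.at[g, s] for s in samples_by_group[control]]
        mu_ctrl = sum(ctrl_vals) / len(ctrl_vals)
        for grp, samps in samples_by_group.items():
            if grp == control:
                continue
            vals = [values.at[g, s] for s in samps]
            sd = statistics.stdev(vals)
            k = sum(1 for v in vals if v > 0)
            sem = sd / math.sqrt(k) if k > 0 else float("nan")
            for s in samps:
                if k == 0 or sem == 0 or math.isnan(sem):
                    z[(g, s)] = float("nan")
                else:
                    z[(g, s)] = (values.at[g, s] - mu_ctrl) / sem
    return z


class TestGroupStats:
    def test_two_value_hand_example(self):
        cm = cm_from({"a": {"g": 80}, "b": {"g": 120}}, {"a": "G", "b": "G"})
        stats = compute_group_stats(cm, {"G": ["a", "b"]})
        assert stats.mean.at["g", "G"] == 100
        assert stats.sd.at["g", "G"] == pytest.approx(28.2842712474619)
        assert stats.k.at["g", "G"] == 2
        assert stats.sem.at["g", "G"] == pytest.approx(20.0)

    def test_zeros_included_in_moments_but_not_group_count(self):
        vals = {f"s{i}": {"g": v} for i, v in enumerate([0, 0, 0, 10, 10])}
        cm = cm_from(vals, {f"s{i}": "G" for i in range(5)})
        stats = compute_group_stats(cm, {"G": list(vals)})
        assert stats.k.at["g", "G"] == 2
        assert stats.mean.at["g", "G"] == pytest.approx(4.0)
        assert stats.sd.at["g", "G"] == pytest.approx(statistics.stdev([0, 0, 0, 10, 10]))
        assert stats.sem.at["g", "G"] == pytest.approx(
            statistics.stdev([0, 0, 0, 10, 10]) / math.sqrt(2)
        )

    def test_present_only_moments_flag(self):
        vals = {f"s{i}": {"g": v} for i, v in enumerate([0, 0, 0, 10, 20])}
        cm = cm_from(vals, {f"s{i}": "G" for i in range(5)})
        stats = compute_group_stats(cm, {"G": list(vals)}, moments_over_present_only=True)
        assert stats.mean.at["g", "G"] == pytest.approx(15.0)
        assert stats.k.at["g", "G"] == 2

    def test_degenerate_constant_group(self):
        cm = cm_from({"a": {"g": 5}, "b": {"g": 5}}, {"a": "G", "b": "G"})
        stats = compute_group_stats(cm, {"G": ["a", "b"]})
        assert stats.sd.at["g", "G"] == 0
        assert stats.sem.at["g", "G"] == 0

    def test_small_group_rejected(self):
        cm = cm_from({"a": {"g": 5}}, {"a": "G"})
        with pytest.raises(PercentileError, match="< 2 samples"):
            compute_group_stats(cm, {"G": ["a"]})


class TestZScores:
    def _stats(self, ctrl_mean, sem, guide="g", group="G"):
        df = pd.DataFrame({"ctrl": {guide: ctrl_mean}, group: {guide: np.nan}})
        return GroupStats(
            mean=df,
            sd=df * np.nan,
            k=df * 0 + 1,
            sem=pd.DataFrame({"ctrl": {guide: np.nan}, group: {guide: sem}}),
            group_sizes={"ctrl": 2, group: 2},
        )

    def test_hand_example(self):
        # n = 130, mu_ctrl = 100, sigma = 20 over k = 16 present -> sem 5, z 6
        cm = cm_from({"s": {"g": 130}}, {"s": "G"})
        stats = self._stats(100.0, 20.0 / math.sqrt(16))
        zm = compute_zscores(cm, stats, control="ctrl", lung_groups=["G"])
        assert zm.z.at["g", "s"] == pytest.approx(6.0)

    def test_centring(self):
        cm = cm_from({"s": {"g": 100}}, {"s": "G"})
        zm = compute_zscores(cm, self._stats(100.0, 5.0), "ctrl", ["G"])
        assert zm.z.at["g", "s"] == 0.0

    def test_zero_sem_masked_never_inf(self):
        cm = cm_from({"s": {"g": 100}}, {"s": "G"})
        zm = compute_zscores(cm, self._stats(50.0, 0.0), "ctrl", ["G"])
        assert np.isnan(zm.z.at["g", "s"])

    def test_missing_control_group_rejected(self):
        cm = cm_from({"s": {"g": 1}}, {"s": "G"})
        with pytest.raises(PercentileError, match="control"):
            compute_zscores(cm, self._stats(1.0, 1.0), "nope", ["G"])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        groups = {}
        cols = {}
        for i in range(2):
            cols[f"c{i}"] = rng.integers(0, 50, 12)
            groups[f"c{i}"] = "ctrl"
        for grp, n in (("A", 3), ("B", 3)):
            for i in range(n):
                cols[f"{grp}{i}"] = rng.integers(0, 50, 12)
                groups[f"{grp}{i}"] = grp
        df = pd.DataFrame(cols, index=[f"g{j}" for j in range(12)], dtype=float)
        cm = CountMatrix(df, pd.Series("x", index=df.index), groups, normalized=True)
        stats = compute_group_stats(cm, {g: [s for s in cols if groups[s] == g] for g in ("ctrl", "A", "B")})
        zm = compute_zscores(cm, stats, "ctrl")
        oracle = brute_force_zscores(df, groups, "ctrl")
        for (g, s), expected in oracle.items():
            got = zm.z.at[g, s]
            if math.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestPercentileSets:
    def test_nearest_rank_hand_example(self):
        z = pd.DataFrame({"s": np.arange(1.0, 101.0)}, index=[f"g{i}" for i in range(1, 101)])
        zm = ZMatrix(z, {"s": "G"})
        sets = percentile_sets(zm, 98.0)
        assert sets["s"] == {"g98", "g99", "g100"}

    def test_all_tied_everyone_in_set(self):
        z = pd.DataFrame({"s": [5.0] * 10}, index=[f"g{i}" for i in range(10)])
        sets = percentile_sets(ZMatrix(z, {"s": "G"}), 98.0)
        assert len(sets["s"]) == 10

    def test_single_defined_guide(self):
        z = pd.DataFrame({"s": [3.0, np.nan]}, index=["g1", "g2"])
        sets = percentile_sets(ZMatrix(z, {"s": "G"}), 98.0)
        assert sets["s"] == {"g1"}

    def test_no_defined_values_empty_set(self):
        z = pd.DataFrame({"s": [np.nan, np.nan]}, index=["g1", "g2"])
        sets = percentile_sets(ZMatrix(z, {"s": "G"}), 98.0)
        assert sets["s"] == set()

    def test_bad_pct_rejected(self):
        with pytest.raises(PercentileError):
            nearest_rank_threshold(np.array([1.0]), 100.0)

    @given(m=st.integers(1, 400), pct=st.floats(1.0, 99.0))
    @settings(max_examples=80, deadline=None)
    def test_set_size_nearest_rank_property(self, m, pct):
        # distinct values: |set| = m - ceil(pct/100 * m) + 1
        z = pd.DataFrame({"s": np.arange(m, dtype=float)}, index=[f"g{i}" for i in range(m)])
        sets = percentile_sets(ZMatrix(z, {"s": "G"}), pct)
        assert len(sets["s"]) == m - math.ceil(pct / 100 * m) + 1


class TestRecurrence:
    def test_disjoint_singletons_no_hits(self):
        sets = {"s1": {"g1"}, "s2": {"g2"}}
        table = recurrence(sets, min_samples=2)
        assert table.empty

    def test_counts_and_sorting(self):
        sets = {"s1": {"g1", "g2"}, "s2": {"g1"}, "s3": {"g1", "g2"}, "s4": {"g2"}}
        z = pd.DataFrame(
            {"s1": [1.0, 9.0], "s2": [2.0, np.nan], "s3": [3.0, 1.0], "s4": [np.nan, 2.0]},
            index=["g1", "g2"],
        )
        table = recurrence(sets, ZMatrix(z, {}), min_samples=2)
        assert table["n_samples"].tolist() == [3, 3]
        # tie on count broken by max_z desc: g2 (9.0) before g1 (3.0)
        assert table["guide_id"].tolist() == ["g2", "g1"]
        assert table.iloc[0]["member_samples"] == "s1;s3;s4"

    def test_permutation_invariance(self):
        sets = {"s1": {"g1"}, "s2": {"g1", "g2"}, "s3": {"g2"}}
        a = recurrence(dict(sorted(sets.items())), min_samples=1)
        b = recurrence(dict(sorted(sets.items(), reverse=True)), min_samples=1)
        pd.testing.assert_frame_equal(a, b)

    def test_gene_aggregation(self):
        table = pd.DataFrame(
            dict(guide_id=["a_g1", "a_g2", "b_g1"], gene=["a", "a", "b"],
                 n_samples=[4, 2, 3], max_z=[5.0, 2.0, 3.0],
                 member_samples=["s1;s2;s3;s4", "s1;s2", "s1;s2;s3"])
        )
        genes = gene_recurrence(table)
        assert genes.iloc[0]["gene"] == "a"
        assert genes.iloc[0]["best_guide_recurrence"] == 4
        assert genes.iloc[0]["n_guides_in_sets"] == 2


class TestEndToEnd:
    def test_planted_hits_recovered_small_screen(self, small_screen):
        from guidescreen.counts import drop_absent_guides, filter_by_control_minimum, total_normalize

        raw = small_screen.counts
        controls = raw.samples_in_group("cells_500x")
        filtered, _ = filter_by_control_minimum(raw, controls, min_reads=30)
        normed = total_normalize(filtered)
        normed, _ = drop_absent_guides(normed)
        res = call_percentile_hits(normed, hit_group="lung_19d", min_samples=2)
        hit_genes = set(res["hit_table"]["gene"])
        assert {"gene01", "gene02"} <= hit_genes
        top2 = res["gene_table"].head(2)["gene"].tolist()
        assert set(top2) == {"gene01", "gene02"}
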