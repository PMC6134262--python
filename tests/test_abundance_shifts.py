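import numpy as np
import pytest

from psmkit import (
    DesignSpec,
    GroundTruth,
    ValidationError,
    bootstrap_contrast,
    make_design,
    pick_effect_sets,
    shift_report,
    simulate_tables,
    venn_regions,
)

from conftest import small_table


def table_with_means(ref_mean, cond_means, n_per=4):
    """One-feature table whose per-condition means are exact."""
    conds = ["ref"] * n_per + sum(([c] * n_per for c in cond_means), [])
    vals = [ref_mean] * n_per + sum(([m] * n_per for m in cond_means.values()), [])
    return small_table(np.array(vals, float)[:, None], conditions=conds)


class TestShiftReport:
    def test_threshold_arithmetic(self):
        t = table_with_means(100.0, {"up": 180.0, "down": 24.0, "mid": 150.0})
        rep = shift_report(t, "ref")
        fid = t.feature_ids[0]
        assert rep.relative_change.loc[fid, "up"] == pytest.approx(80.0)
        assert rep.relative_change.loc[fid, "down"] == pytest.approx(-76.0)
        assert rep.relative_change.loc[fid, "mid"] == pytest.approx(50.0)
        assert fid in rep.up_sets["up"]
        assert fid in rep.down_sets["down"]
        assert fid not in rep.up_sets["mid"] and fid not in rep.down_sets["mid"]

    def test_threshold_inclusive_at_exactly_75(self):
        t = table_with_means(100.0, {"hi": 175.0, "lo": 25.0})
        rep = shift_report(t, "ref")
        fid = t.feature_ids[0]
        assert fid in rep.up_sets["hi"] and fid in rep.down_sets["lo"]

    def test_reference_equal_condition_all_zero(self):
        rng = np.random.default_rng(0)
        t = small_table(rng.lognormal(3, 1, (6, 5)), conditions=["a"] * 3 + ["b"] * 3)
        rep = shift_report(t, "a")
        # comparing a condition against itself is vacuous: only 'b' reported
        assert list(rep.relative_change.columns) == ["b"]
        rep_b = shift_report(t, "b")
        assert list(rep_b.relative_change.columns) == ["a"]

    def test_undetected_in_reference_routed_separately(self):
        X = np.array([[0.0, 10.0], [0.0, 10.0], [5.0, 40.0], [5.0, 40.0]])
        t = small_table(X, conditions=["ref", "ref", "c", "c"])
        rep = shift_report(t, "ref")
        assert rep.undetected == {t.feature_ids[0]}
        assert t.feature_ids[0] not in rep.relative_change.index
        assert rep.relative_change.loc[t.feature_ids[1], "c"] == pytest.approx(300.0)

    def test_unknown_reference_rejected(self):
        t = table_with_means(1.0, {"c": 2.0})
        with pytest.raises(ValidationError, match="reference"):
            shift_report(t, "nope")

    def test_generator_effect_features_recovered(self):
        design = make_design(
            DesignSpec(factors=(("temp", ("ambient", "warm")),), replicates_per_cell=10, blocks=2))
        effect, _ = pick_effect_sets(50, 300, ["warm"], n_effect=40, delta=2.0)
        truth = GroundTruth(seed=51, n_features_total=300, shared_fraction=0.0,
                            effect_features=effect, noise_cv=0.02, block_sd=0.0,
                            dropout_rate=0.0)
        pos, _, real = simulate_tables(design, truth)
        rep = shift_report(pos, "ambient")
        reg = real.registry.set_index("metabolite_id")
        truth_pos_ids = {f"{reg.loc[m, 'pos_id']}" for m in real.effect_realized["warm"]
                         if reg.loc[m, "pos_id"]}
        # delta = 2 is +100% >= +75%: every affected feature must classify up
        assert truth_pos_ids <= rep.up_sets["warm"]
        # independent recount of one affected feature's group means
        fid = sorted(truth_pos_ids)[0]
        col = pos.feature_ids.index(fid)
        warm = pos.conditions == "warm"
        expect = 100.0 * (pos.intensities[warm, col].mean()
                          - pos.intensities[~warm, col].mean()) / pos.intensities[~warm, col].mean()
        assert rep.relative_change.loc[fid, "warm"] == pytest.approx(expect)


class TestVennRegions:
    def test_three_sets_brute_force(self):
        rng = np.random.default_rng(1)
        universe = [f"f{i}" for i in range(60)]
        sets = {c: set(rng.choice(universe, size=rng.integers(5, 30), replace=False))
                for c in ("x", "y", "z")}
        regions = venn_regions(sets)
        assert len(regions) == 7
        # brute-force: classify every element of the union by its signature
        expected = {}
        for el in set.union(*sets.values()):
            sig = "&".join(sorted(c for c in sets if el in sets[c]))
            expected[sig] = expected.get(sig, 0) + 1
        for sig, count in regions.items():
            assert count == expected.get(sig, 0)
        assert sum(regions.values()) == len(set.union(*sets.values()))

    def test_report_venn_counts_sum_to_union(self):
        rng = np.random.default_rng(2)
        conds = ["ref", "a", "b", "c"]
        X = rng.lognormal(4, 1.2, size=(12, 40))
        t = small_table(X, conditions=sum(([c] * 3 for c in conds), []))
        rep = shift_report(t, "ref")
        assert sum(rep.venn_up.values()) == len(set.union(set(), *rep.up_sets.values()))
        assert sum(rep.venn_down.values()) == len(set.union(set(), *rep.down_sets.values()))
        for c in ("a", "b", "c"):
            assert not (rep.up_sets[c] & rep.down_sets[c])


class TestBootstrapContrast:
    def test_zero_variance_degenerate_ci(self):
        t = small_table(np.array([[10.0]] * 4 + [[15.0]] * 4),
                        conditions=["ref"] * 4 + ["c"] * 4)
        res = bootstrap_contrast(t, t.feature_ids[0], "c", "ref", n_boot=200, seed=0)
        assert res.relative_change == pytest.approx(50.0)
        assert res.ci_low == pytest.approx(50.0) and res.ci_high == pytest.approx(50.0)
        assert res.significant

    def test_condition_completely_absent(self):
        t = small_table(np.array([[10.0]] * 4 + [[0.0]] * 4),
                        conditions=["ref"] * 4 + ["c"] * 4)
        res = bootstrap_contrast(t, t.feature_ids[0], "c", "ref", n_boot=200, seed=0)
        assert res.absent_flag
        assert res.relative_change == -100.0
        assert res.ci_low == res.ci_high == -100.0

    def test_undetected_reference_rejected(self):
        t = small_table(np.array([[0.0]] * 4 + [[5.0]] * 4),
                        conditions=["ref"] * 4 + ["c"] * 4)
        with pytest.raises(ValidationError, match="undefined"):
            bootstrap_contrast(t, t.feature_ids[0], "c", "ref")

    def test_ci_brackets_estimate_and_is_reproducible(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.lognormal(3, 0.3, 8), rng.lognormal(3.8, 0.3, 8)])
        t = small_table(vals[:, None], conditions=["ref"] * 8 + ["c"] * 8)
        r1 = bootstrap_contrast(t, t.feature_ids[0], "c", "ref", n_boot=2000, seed=7)
        r2 = bootstrap_contrast(t, t.feature_ids[0], "c", "ref", n_boot=2000, seed=7)
        assert r1.ci_low <= r1.relative_change <= r1.ci_high
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_ci_width_shrinks_with_group_size(self):
        rng = np.random.default_rng(9)
        widths = []
        for n in (4, 16, 64):
            vals = np.concatenate([rng.lognormal(3, 0.4, n), rng.lognormal(4, 0.4, n)])
            t = small_table(vals[:, None], conditions=["ref"] * n + ["c"] * n)
            r = bootstrap_contrast(t, t.feature_ids[0], "c", "ref", n_boot=1000, seed=n)
            widths.append(r.ci_high - r.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_matches_scipy_percentile_bootstrap(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        ref = np.exp(rng.normal(8, 0.25, 8))
        cond = np.exp(rng.normal(9, 0.25, 8))
        vals = np.concatenate([ref, cond])
        t = small_table(vals[:, None], conditions=["ref"] * 8 + ["c"] * 8)
        r = bootstrap_contrast(t, t.feature_ids[0], "c", "ref", n_boot=20000, seed=1)

        def rel_change(c, rf):
            return 100.0 * (np.mean(c) - np.mean(rf)) / np.mean(rf)

        sci = stats.bootstrap((cond, ref), rel_change, n_resamples=20000,
                              method="percentile", confidence_level=0.95,
                              random_state=2)
        width = r.ci_high - r.ci_low
        assert r.ci_low == pytest.approx(sci.confidence_interval.low, abs=0.03 * width)
        assert r.ci_high == pytest.approx(sci.confidence_interval.high, abs=0.03 * width)

    def test_unknown_feature_rejected(self):
        t = small_table(np.ones((4, 1)), conditions=["ref", "ref", "c", "c"])
        with pytest.raises(ValidationError, match="not in table"):
            bootstrap_contrast(t, "ghost", "c", "ref")
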