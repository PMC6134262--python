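import filecmp

import numpy as np
import pytest

from psmkit import (
    B4WARMED_DESIGN,
    OBSERVATIONAL_DESIGN,
    DesignSpec,
    GroundTruth,
    ValidationError,
    make_design,
    pick_effect_sets,
    simulate_tables,
)
from psmkit.synthetic_data import write_simulation


class TestMakeDesign:
    def test_warming_experiment_layout(self):
        # 2 overstory x 3 warming x 2 precipitation, 6 replicates -> 72 plots
        samples = make_design(B4WARMED_DESIGN)
        assert len(samples) == 72
        conds = {s.condition for s in samples}
        assert len(conds) == 12
        blocks = {s.block for s in samples}
        assert len(blocks) == 3
        # round-robin within cells: every cell spread over all blocks
        for c in conds:
            cell_blocks = [s.block for s in samples if s.condition == c]
            assert sorted(set(cell_blocks)) == sorted(blocks)

    def test_observational_layout(self):
        # 2 overstory x 2 temperature, 3 replicates -> 12 plots
        samples = make_design(OBSERVATIONAL_DESIGN)
        assert len(samples) == 12
        assert len({s.condition for s in samples}) == 4

    def test_degenerate_single_plot(self):
        spec = DesignSpec(factors=(("f", ("only",)),), replicates_per_cell=1, blocks=1)
        assert len(make_design(spec)) == 1

    def test_zero_levels_rejected(self):
        with pytest.raises(ValidationError, match="zero levels"):
            DesignSpec(factors=(("f", ()),))

    def test_every_sample_has_one_block(self):
        samples = make_design(B4WARMED_DESIGN)
        assert all(s.block for s in samples)
        assert len({s.sample_id for s in samples}) == len(samples)


class TestSimulateTables:
    def _design(self, reps=4):
        return make_design(
            DesignSpec(factors=(("temp", ("ambient", "warm")),),
                       replicates_per_cell=reps, blocks=2))

    def test_zero_shared_fraction_no_cross_matches(self):
        truth = GroundTruth(seed=1, n_features_total=100, shared_fraction=0.0)
        pos, neg, real = simulate_tables(self._design(), truth)
        assert real.pairs == []
        # no negative mass lies within tolerance of any adjusted positive mass
        adj = np.array([f.mass for f in pos.features]) - truth.polarity_offset
        negm = np.array([f.mass for f in neg.features])
        assert np.abs(adj[:, None] - negm[None, :]).min() > 0.005

    def test_full_overlap_exact_offset(self):
        truth = GroundTruth(seed=2, n_features_total=60, shared_fraction=1.0,
                            mass_jitter=0.0, rt_jitter=0.0)
        pos, neg, real = simulate_tables(self._design(), truth)
        assert len(real.pairs) == 60 and pos.n_features == neg.n_features == 60
        reg = real.registry
        shared = reg[reg.shared]
        pos_mass = {f.feature_id: f.mass for f in pos.features}
        neg_mass = {f.feature_id: f.mass for f in neg.features}
        for _, row in shared.iterrows():
            assert pos_mass[row.pos_id] - neg_mass[row.neg_id] == pytest.approx(
                truth.polarity_offset, abs=1e-12)

    def test_effect_mean_ratio_recovers_delta(self):
        # delta = 3 on chosen features: group mean ratio ~ 3 over replicates
        design = make_design(
            DesignSpec(factors=(("temp", ("ambient", "warm")),),
                       replicates_per_cell=12, blocks=3))
        n_eff = 40
        ratios = []
        for rep in range(30):
            effect, _ = pick_effect_sets(1000 + rep, 200, ["warm"], n_eff, delta=3.0)
            truth = GroundTruth(seed=2000 + rep, n_features_total=200, shared_fraction=0.0,
                                effect_features=effect, dropout_rate=0.0)
            pos, _, real = simulate_tables(design, truth)
            reg = real.registry.set_index("metabolite_id")
            cols = [pos.feature_ids.index(reg.loc[m, "pos_id"])
                    for m in real.effect_realized["warm"] if reg.loc[m, "pos_id"]]
            warm = pos.conditions == "warm"
            m_w = pos.intensities[np.ix_(warm, cols)].mean(axis=0)
            m_a = pos.intensities[np.ix_(~warm, cols)].mean(axis=0)
            ratios.append(np.mean(m_w / m_a))
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.05)

    def test_turnover_presence_differences_match_toggles(self):
        ids = [f"M{i+1:05d}" for i in range(100)]
        turnover = {"warm": {ids[0]: "loss", ids[1]: "gain"}}
        truth = GroundTruth(seed=5, n_features_total=100, shared_fraction=1.0,
                            turnover_features=turnover, dropout_rate=0.0)
        pos, _, real = simulate_tables(self._design(), truth)
        reg = real.registry.set_index("metabolite_id")
        warm = pos.conditions == "warm"
        col_loss = pos.feature_ids.index(reg.loc[ids[0], "pos_id"])
        col_gain = pos.feature_ids.index(reg.loc[ids[1], "pos_id"])
        assert (pos.intensities[warm, col_loss] == 0).all()
        assert (pos.intensities[~warm, col_loss] > 0).all()
        assert (pos.intensities[warm, col_gain] > 0).all()
        assert (pos.intensities[~warm, col_gain] == 0).all()

    def test_presence_counts_bookkeeping(self):
        truth = GroundTruth(seed=6, n_features_total=120, shared_fraction=0.4)
        pos, neg, real = simulate_tables(self._design(), truth)
        for table, pol in ((pos, "positive"), (neg, "negative")):
            counts = (table.intensities > 0).sum(axis=1)
            for i, s in enumerate(table.samples):
                assert real.presence_counts[pol][s.sample_id] == counts[i]

    def test_effect_turnover_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            GroundTruth(seed=1, effect_features={"w": {"M00001": 2.0}},
                        turnover_features={"w": {"M00001": "loss"}})

    def test_identical_seed_byte_identical_files(self, tmp_path):
        design = self._design(reps=3)
        outs = []
        for sub in ("a", "b"):
            truth = GroundTruth(seed=9, n_features_total=80, shared_fraction=0.5)
            pos, neg, real = simulate_tables(design, truth)
            paths = write_simulation(pos, neg, real, tmp_path / sub)
            outs.append(paths)
        for key in outs[0]:
            assert filecmp.cmp(outs[0][key], outs[1][key], shallow=False), key
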