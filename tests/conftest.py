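import numpy as np
import pytest

from psmkit import (
    DesignSpec,
    FeatureRecord,
    FeatureTable,
    GroundTruth,
    SampleRecord,
    make_design,
    simulate_tables,
)


def small_table(intensities, conditions=None, blocks=None, rts=None):
    """Hand-built FeatureTable from a samples x features array."""
    X = np.asarray(intensities, dtype=float)
    n_s, n_f = X.shape
    conditions = conditions or ["c1"] * n_s
    blocks = blocks or ["b1"] * n_s
    rts = rts if rts is not None else np.linspace(2.0, 18.0, n_f)
    features = [
        FeatureRecord(feature_id=f"F{j+1:03d}", mass=200.0 + j, rt=float(rts[j]),
                      polarity="positive", provenance="pos_only")
        for j in range(n_f)
    ]
    samples = [
        SampleRecord(sample_id=f"S{i+1:03d}", species="sp", condition=conditions[i],
                     block=blocks[i], year="Y1")
        for i in range(n_s)
    ]
    return FeatureTable(features=features, samples=samples, intensities=X)


@pytest.fixture
def tiny_table():
    return small_table(
        [[0.0, 5.2, 0.0, 1.1],
         [1.0, 0.0, 3.0, 2.0],
         [1.0, 2.0, 3.0, 0.0]],
        conditions=["a", "a", "b"],
        blocks=["b1", "b1", "b2"],
    )


@pytest.fixture(scope="session")
def sim_pair():
    """A simulated dual-polarity pair at smoke scale with known truth."""
    design = make_design(
        DesignSpec(factors=(("temp", ("ambient", "warm")),), replicates_per_cell=6, blocks=3))
    truth = GroundTruth(seed=11, n_features_total=500, shared_fraction=0.3)
    return simulate_tables(design, truth)
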