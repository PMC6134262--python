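"""Simulation studies validating the pipeline's statistical machinery.

Each routine runs the full relevant code path on generator output with
known ground truth and measures an operating characteristic: type-I error
and power of the strata-restricted perMANOVA, coverage of the bootstrap
confidence interval for relative-abundance change, and parameter recovery
of the richness mixed model.  They are used by the test suite and the
reproduction script; problem sizes are arguments so callers choose the
replication budget.
"""

from __future__ import annotations

import numpy as np

from .abundance_shifts import bootstrap_contrast
from .diversity import canberra_matrix
from .feature_io import FeatureRecord, FeatureTable, SampleRecord
from .mixed_models import fit_lme
from .permstats import permanova
from .polarity_fusion import MatchConfig, match_features, merge_tables
from .synthetic_data import DesignSpec, GroundTruth, make_design, pick_effect_sets, simulate_tables


def _two_group_design(n_per_group: int = 10, blocks: int = 5):
    return make_design(DesignSpec(
        factors=(("condition", ("ref", "alt")),),
        replicates_per_cell=n_per_group, blocks=blocks))


def _simulate_fused(design, truth):
    pos, neg, real = simulate_tables(design, truth)
    match = match_features(pos, neg, MatchConfig())
    return merge_tables(pos, neg, match), real


def permanova_rejection_rate(
    n_sims: int,
    seed: int,
    delta: float | None = None,
    effect_fraction: float = 0.05,
    n_features: int = 500,
    n_per_group: int = 10,
    blocks: int = 5,
    n_perm: int = 999,
    alpha: float = 0.05,
) -> float:
    """Fraction of simulations in which the Canberra perMANOVA rejects.

    ``delta=None`` simulates the null (no effects; block variance present;
    permutations restricted within blocks): the rate estimates type-I
    error.  With ``delta`` set, multiplicative effects of that size are
    placed on ``effect_fraction`` of the features in the non-reference
    condition and the rate estimates power.
    """
    design = _two_group_design(n_per_group, blocks)
    n_effect = int(round(effect_fraction * n_features))
    rejections = 0
    for i in range(n_sims):
        sim_seed = seed + 1000 * i
        if delta is None:
            effect = {}
        else:
            effect, _ = pick_effect_sets(sim_seed + 1, n_features, ["alt"],
                                         n_effect=n_effect, delta=delta)
        truth = GroundTruth(seed=sim_seed, n_features_total=n_features,
                            shared_fraction=0.3, effect_features=effect)
        fused, _ = _simulate_fused(design, truth)
        D = canberra_matrix(fused)
        res = permanova(D, fused.conditions, strata=fused.blocks,
                        n_perm=n_perm, seed=sim_seed + 2, method="monte-carlo")
        if res.p <= alpha:
            rejections += 1
    return rejections / n_sims


def _one_feature_table(ref_vals: np.ndarray, cond_vals: np.ndarray) -> FeatureTable:
    vals = np.concatenate([ref_vals, cond_vals])[:, None]
    samples = [SampleRecord(f"S{i+1:03d}", "sp",
                            "ref" if i < len(ref_vals) else "alt", "b1")
               for i in range(len(vals))]
    return FeatureTable(
        features=[FeatureRecord("F001", 300.0, 10.0, "positive", "pos_only")],
        samples=samples, intensities=vals)


def bootstrap_coverage(
    n_outer: int,
    seed: int,
    true_ratio: float = 3.5,
    n_per_group: int = 8,
    n_boot: int = 2000,
    sigma: float | None = None,
    level: float = 0.95,
) -> float:
    """Coverage of the percentile bootstrap CI for relative change.

    Each outer replicate draws log-normal intensities for a reference and
    an affected group whose population means differ by ``true_ratio``
    (relative change 100*(true_ratio - 1) percent) and checks whether the
    CI covers the true change.  ``sigma`` defaults to the generator's
    multiplicative noise (CV 0.25 on the log scale).
    """
    if sigma is None:
        sigma = float(np.sqrt(np.log1p(0.25 ** 2)))  # generator noise_cv default
    true_change = 100.0 * (true_ratio - 1.0)
    mu = 8.0
    rng = np.random.default_rng(seed)
    covered = 0
    for i in range(n_outer):
        ref = np.exp(rng.normal(mu, sigma, n_per_group))
        cond = np.exp(rng.normal(mu + np.log(true_ratio), sigma, n_per_group))
        t = _one_feature_table(ref, cond)
        res = bootstrap_contrast(t, "F001", "alt", "ref", n_boot=n_boot,
                                 seed=int(rng.integers(2**31 - 1)), level=level)
        if res.ci_low <= true_change <= res.ci_high:
            covered += 1
    return covered / n_outer


def lme_recovery_rate(
    n_sims: int,
    seed: int,
    true_delta: float = 50.0,
    block_sd: float = 5.0,
    resid_sd: float = 10.0,
    n_per_level: int = 12,
    n_blocks: int = 6,
) -> float:
    """Fraction of simulated richness fits whose estimate lands within
    2 standard errors of the true condition shift."""
    rng = np.random.default_rng(seed)
    cond = np.repeat(["ref", "trt"], n_per_level)
    block = np.tile([f"b{i}" for i in range(n_blocks)], 2 * n_per_level // n_blocks)
    ok = 0
    for _ in range(n_sims):
        u = dict(zip([f"b{i}" for i in range(n_blocks)],
                     rng.normal(0, block_sd, n_blocks)))
        y = (200.0 + true_delta * (cond == "trt")
             + np.array([u[b] for b in block])
             + rng.normal(0, resid_sd, len(cond)))
        res = fit_lme(y, cond, block, "ref")
        fe = res.fixed_effects["trt"]
        if fe.se > 0 and abs(fe.estimate - true_delta) <= 2.0 * fe.se:
            ok += 1
    return ok / n_sims
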