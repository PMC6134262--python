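# psmkit

Analysis of **dual-polarity untargeted LC-MS feature tables** of plant
secondary metabolite (PSM) profiles under combinations of abiotic factors
(warming, light, drought), for chemical ecologists and metabolomics
analysts who receive peak tables from upstream peak detection and need the
downstream statistics: polarity fusion, phytochemical diversity,
blocked-design multivariate tests, ordination, and reference-condition
abundance shifts.

## What it computes

An LC-MS run with polarity switching yields two partially overlapping
feature sets: a metabolite ionizing in both modes appears as [M+H]⁺ in the
positive table and [M−H]⁻ in the negative table, with masses differing by
roughly two proton masses (2.014552 Da) at the same retention time. The
pipeline:

1. **Trims** features to a retention-time window (default 1–21 min,
   inclusive) and **fuses** polarities: positive-mode masses are shifted by
   a fixed offset and features pairing within mass/RT tolerances are merged
   one-to-one, keeping the intensity vector of the mode with greater mean
   intensity. A replication preset (`paper_mode`) uses a published 2.1046 Da
   offset instead of the physical two-proton value.
2. **Diversity**: per-sample phytochemical richness (presence counts) and
   two dissimilarities — Canberra on intensities,
   `d(x,y) = (1/NZ) Σ |xᵢ−yᵢ|/(xᵢ+yᵢ)` over the NZ non-double-zero
   features, and Jaccard on presence/absence,
   `d(A,B) = 1 − |A∩B|/|A∪B|` (phytochemical turnover).
3. **perMANOVA** with restricted permutations: the distance matrix's total
   sum of squares `SS_T = (1/N) Σ_{i<j} d²ᵢⱼ` is split into within/between
   components, `F = (SS_A/(a−1))/(SS_W/(N−a))`, `r² = SS_A/SS_T`, with the
   null distribution from label permutations restricted to shuffle only
   within blocks/sites (strata), so the test honours the blocked sampling
   design. Exact enumeration for small n; `p = (#{F* ≥ F}+1)/(n_perm+1)`
   otherwise. **PERMDISP** (distances to group centers in principal
   coordinates, with the negative-eigenvalue correction) and **mean
   dissimilarity matrices** separate location from dispersion effects.
4. **NMDS** (k = 2, Kruskal stress-1, isotonic regression + majorization,
   multiple restarts) with 95% standard-error group ellipses
   `(x−c)ᵀ(Cov/n)⁻¹(x−c) ≤ χ²₂(0.95)`.
5. **Abundance shifts**: per-feature relative change
   `100·(mean_cond − mean_ref)/mean_ref` against a designated reference
   condition; features shifting by ≥ ±75% form up/down sets with Venn-style
   region counts; percentile bootstrap CIs for single compounds.
6. **Mixed models**: richness ~ condition with a random intercept per
   block/site (REML), contrasts vs the reference level.

A **synthetic-data generator** emulates the whole data-generating process
(blocked factorial designs, log-normal intensities, block random effects,
shared-polarity features at the two-proton offset, condition effects,
presence/absence turnover, dropout) with full ground truth, so every stage
is validated against known answers — no external data needed.

## Worked example

```python
import numpy as np
from psmkit import (DesignSpec, GroundTruth, MatchConfig, canberra_matrix,
                    make_design, match_features, merge_tables, permanova,
                    pick_effect_sets, simulate_tables, richness, fit_lme)

design = make_design(DesignSpec(factors=(("temp", ("ambient", "warm")),),
                                replicates_per_cell=8, blocks=4))
effect, _ = pick_effect_sets(7, 800, ["warm"], n_effect=60, delta=3.0)
truth = GroundTruth(seed=7, n_features_total=800, shared_fraction=0.3,
                    effect_features=effect)
pos, neg, real = simulate_tables(design, truth)
print(f"positive table: {pos.shape}, negative table: {neg.shape}")
match = match_features(pos, neg, MatchConfig())
fused = merge_tables(pos, neg, match)
print(f"matched pairs: {len(match.pairs)}, fused features: {fused.n_features}")
D = canberra_matrix(fused)
res = permanova(D, fused.conditions, strata=fused.blocks, n_perm=999, seed=1)
print(f"perMANOVA: F = {res.F:.3f}, r2 = {res.r2:.3f}, p = {res.p:.3f}")
rich = richness(fused)
lme = fit_lme(rich.to_numpy(), fused.conditions, fused.blocks, reference="ambient")
fe = lme.fixed_effects["warm"]
print(f"richness LME: delta = {fe.estimate:.2f} (SE {fe.se:.2f}, p = {fe.p:.3f})")
```

prints

```
positive table: (16, 520), negative table: (16, 520)
matched pairs: 240, fused features: 800
perMANOVA: F = 2.178, r2 = 0.135, p = 0.002
richness LME: delta = 0.38 (SE 3.19, p = 0.909)
```

Reading: of 800 latent metabolites, 240 ionize in both modes and are fused
back to exactly 800 features (520 + 520 − 240). The 60 features given a
3-fold warming effect shift the multivariate centroid — the
strata-restricted perMANOVA rejects (p = 0.002) with 13.5% of the
distance variance explained — while richness is unchanged (no
presence/absence effects were simulated; the mixed-model contrast is a
null 0.38 ± 3.19 features).

The same analysis runs from the shell: `psmkit simulate`, `psmkit merge`,
`psmkit diversity`, `psmkit permanova`, `psmkit permdisp`, `psmkit nmds`,
`psmkit shifts`, `psmkit contrast`, `psmkit lme`, or end-to-end from one
YAML config with `psmkit run --config cfg.yaml --outdir out/` (writes a
versioned `report.json` with every seed and parameter echoed, plus
Table-style TSV summaries; identical config + seeds gives a byte-identical
report).

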