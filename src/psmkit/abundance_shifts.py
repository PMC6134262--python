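"""Reference-condition abundance contrasts.

Every non-reference condition is compared to a designated reference
condition (the level assumed least perturbing).  For each feature the
relative change is

    100 * (mean_condition - mean_reference) / mean_reference   [percent]

with condition means taken as arithmetic means of raw intensities over that
condition's samples, zeros included.  Features undetected in the reference
(mean 0) cannot be expressed as a percent change and are reported
separately.  Features shifting by at least +/-75% (inclusive, configurable)
form per-condition "up" and "down" sets, whose intersections across
conditions are tabulated Venn-style.

For individual compounds of interest, :func:`bootstrap_contrast` attaches a
percentile bootstrap confidence interval to the relative change by
resampling samples with replacement independently within the condition and
reference groups.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_io import FeatureTable, ValidationError


@dataclass
class ShiftReport:
    reference: str
    threshold_pct: float
    relative_change: pd.DataFrame   # features x non-reference conditions, percent
    up_sets: dict                   # condition -> set of feature_ids (>= +threshold)
    down_sets: dict                 # condition -> set of feature_ids (<= -threshold)
    undetected: set                 # mean_ref == 0
    venn_up: dict                   # region signature "condA&condB" -> exclusive count
    venn_down: dict
    normalized: bool = False        # per-sample total-intensity normalization applied

    def counts_table(self) -> pd.DataFrame:
        conds = list(self.relative_change.columns)
        return pd.DataFrame({
            "condition": conds,
            "n_up": [len(self.up_sets[c]) for c in conds],
            "n_down": [len(self.down_sets[c]) for c in conds],
        })


@dataclass
class CompoundContrast:
    feature_id: str
    condition: str
    reference: str
    relative_change: float          # percent
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    significant: bool               # CI excludes 0
    absent_flag: bool               # feature undetected in all condition samples
    n_dropped_replicates: int = 0   # bootstrap replicates with resampled mean_ref == 0


def venn_regions(sets: dict) -> dict:
    """Exclusive region counts of a family of sets.

    Region signature is the ``&``-joined sorted tuple of member set names;
    counts are of elements belonging to exactly those sets.  Regions with
    count 0 are included so the full 2^m - 1 layout is explicit.
    """
    names = sorted(sets)
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo)) if combo else set()
            outside = set.union(set(), *(sets[c] for c in names if c not in combo))
            regions["&".join(combo)] = len(inside - outside)
    return regions


def _condition_means(table: FeatureTable, normalize: bool) -> pd.DataFrame:
    X = table.intensities
    if normalize:
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        X = X / totals
    df = pd.DataFrame(X, index=table.sample_ids, columns=table.feature_ids)
    return df.groupby(table.conditions).mean()   # conditions x features


def shift_report(
    table: FeatureTable,
    reference: str,
    threshold_pct: float = 75.0,
    normalize: bool = False,
) -> ShiftReport:
    """Classify per-feature relative abundance changes against a reference.

    Features whose reference-condition mean is 0 go to ``undetected`` and
    are excluded from the percent-change sets.  Classification is inclusive:
    change >= +threshold joins the up set, <= -threshold the down set.
    """
    conds = set(table.conditions)
    if reference not in conds:
        raise ValidationError(f"reference condition {reference!r} not present in table")
    means = _condition_means(table, normalize)
    ref_mean = means.loc[reference]
    others = [c for c in means.index if c != reference]

    detected = ref_mean > 0
    undetected = set(ref_mean.index[~detected])
    rel = pd.DataFrame(index=means.columns[detected], columns=others, dtype=float)
    for c in others:
        rel[c] = 100.0 * (means.loc[c, detected] - ref_mean[detected]) / ref_mean[detected]

    up_sets = {c: set(rel.index[rel[c] >= threshold_pct]) for c in others}
    down_sets = {c: set(rel.index[rel[c] <= -threshold_pct]) for c in others}
    return ShiftReport(
        reference=reference,
        threshold_pct=threshold_pct,
        relative_change=rel,
        up_sets=up_sets,
        down_sets=down_sets,
        undetected=undetected,
        venn_up=venn_regions(up_sets),
        venn_down=venn_regions(down_sets),
        normalized=normalize,
    )


def bootstrap_contrast(
    table: FeatureTable,
    feature: str,
    condition: str,
    reference: str,
    n_boot: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
) -> CompoundContrast:
    """Percentile bootstrap CI for one feature's relative change.

    Samples are resampled with replacement independently within the
    condition and reference groups; replicates whose resampled reference
    mean is 0 are dropped and counted.  A condition group that is entirely
    zero mirrors a compound completely absent under that condition:
    ``absent_flag`` is set and the change is -100% with a degenerate CI.
    """
    try:
        col = table.feature_ids.index(feature)
    except ValueError:
        raise ValidationError(f"feature {feature!r} not in table") from None
    conds = table.conditions
    x_cond = table.intensities[conds == condition, col]
    x_ref = table.intensities[conds == reference, col]
    if len(x_cond) < 2 or len(x_ref) < 2:
        raise ValidationError("both groups need at least 2 samples for the bootstrap")
    if x_ref.mean() == 0:
        raise ValidationError(
            f"feature {feature!r} undetected in reference {reference!r}; "
            "relative change undefined")

    rel_obs = 100.0 * (x_cond.mean() - x_ref.mean()) / x_ref.mean()

    if (x_cond == 0).all():
        return CompoundContrast(
            feature_id=feature, condition=condition, reference=reference,
            relative_change=-100.0, ci_low=-100.0, ci_high=-100.0,
            n_boot=0, seed=seed, significant=True, absent_flag=True,
        )

    rng = np.random.default_rng(seed)
    idx_c = rng.integers(0, len(x_cond), size=(n_boot, len(x_cond)))
    idx_r = rng.integers(0, len(x_ref), size=(n_boot, len(x_ref)))
    mean_c = x_cond[idx_c].mean(axis=1)
    mean_r = x_ref[idx_r].mean(axis=1)
    keep = mean_r > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} bootstrap replicates with zero reference mean")
    reps = 100.0 * (mean_c[keep] - mean_r[keep]) / mean_r[keep]
    alpha = 1.0 - level
    ci_low, ci_high = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return CompoundContrast(
        feature_id=feature, condition=condition, reference=reference,
        relative_change=float(rel_obs), ci_low=float(ci_low), ci_high=float(ci_high),
        n_boot=n_boot, seed=seed,
        significant=bool(ci_low > 0 or ci_high < 0),
        absent_flag=False, n_dropped_replicates=n_dropped,
    )
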