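"""Synthetic dual-polarity feature tables with known ground truth.

Real untargeted LC-MS runs with polarity switching yield two partially
overlapping feature sets: a metabolite ionizing in both modes appears as an
[M+H]+ peak in the positive table and an [M-H]- peak in the negative table,
the two masses differing by roughly two proton masses and sharing a
retention time.  The generator emulates exactly the statistical structure
the downstream analyses assume, with every choice recorded so tests can
compare results against truth:

* a designed sample layout (blocked factorial or small observational design),
* a latent metabolite registry; a ``shared_fraction`` of metabolites is
  detectable in both polarities with negative-mode mass = positive-mode
  mass - ``polarity_offset`` and identical RT up to jitter,
* log-normal baseline intensities with multiplicative per-block random
  effects (additive on the log scale, shared by all samples of a block) and
  multiplicative sample noise of a given coefficient of variation,
* condition-specific multiplicative effects (centroid shifts) on chosen
  metabolites and presence/absence toggles (turnover) on others,
* baseline dropout: a present feature reads 0 with a small probability.

Identical seeds give identical tables, and the written files are
byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_io import FeatureRecord, FeatureTable, SampleRecord, ValidationError, write_feature_table

#: physical [M+H]+ vs [M-H]- mass difference, in Daltons (two protons)
TWO_PROTON_MASS = 2.014552


@dataclass(frozen=True)
class DesignSpec:
    """Layout of a blocked factorial (or simple observational) design.

    ``factors`` is an ordered list of ``(name, levels)``; every combination
    of levels (a "cell") receives ``replicates_per_cell`` plots, assigned to
    ``blocks`` strata round-robin within each cell.  ``plants_per_plot``
    controls how many samples are drawn per plot (1 = one sample per plot).
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    replicates_per_cell: int = 6
    blocks: int = 3
    plants_per_plot: int = 1

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValidationError("design needs at least one factor")
        for name, levels in self.factors:
            if len(levels) == 0:
                raise ValidationError(f"factor {name!r} has zero levels")
        if self.replicates_per_cell < 1:
            raise ValidationError("replicates_per_cell must be >= 1")
        if self.blocks < 1:
            raise ValidationError("blocks must be >= 1")
        if self.plants_per_plot < 1:
            raise ValidationError("plants_per_plot must be >= 1")

    @property
    def n_cells(self) -> int:
        n = 1
        for _, levels in self.factors:
            n *= len(levels)
        return n

    @property
    def n_plots(self) -> int:
        return self.n_cells * self.replicates_per_cell

    @staticmethod
    def from_dict(d: Mapping) -> "DesignSpec":
        factors = tuple((str(name), tuple(str(l) for l in levels)) for name, levels in d["factors"])
        return DesignSpec(
            factors=factors,
            replicates_per_cell=int(d.get("replicates_per_cell", 6)),
            blocks=int(d.get("blocks", 3)),
            plants_per_plot=int(d.get("plants_per_plot", 1)),
        )


#: the warming-experiment template: 2 overstory x 3 warming x 2 precipitation,
#: six replicates (two per block) -> 72 plots in 3 blocks
B4WARMED_DESIGN = DesignSpec(
    factors=(
        ("overstory", ("open", "closed")),
        ("warming", ("ambient", "warm1.7", "warm3.4")),
        ("precipitation", ("ambient", "reduced")),
    ),
    replicates_per_cell=6,
    blocks=3,
)

#: the observational template: 2 overstory x 2 temperature, three plot
#: replicates -> 12 plots, each plot its own site/stratum
OBSERVATIONAL_DESIGN = DesignSpec(
    factors=(
        ("overstory", ("open", "closed")),
        ("temperature", ("warm", "cool")),
    ),
    replicates_per_cell=3,
    blocks=12,
)


def make_design(spec: DesignSpec, species: str = "speciesA", year: str = "Y1") -> list[SampleRecord]:
    """Expand a :class:`DesignSpec` into one :class:`SampleRecord` per plot x plant.

    ``condition`` is the factor levels of the cell joined with ``+`` (e.g.
    ``"open+warm3.4+reduced"``); plots are assigned to blocks round-robin
    within each factor cell so every cell is spread across blocks.
    """
    import itertools

    samples: list[SampleRecord] = []
    plot_no = 0
    for cell in itertools.product(*(levels for _, levels in spec.factors)):
        condition = "+".join(cell)
        for rep in range(spec.replicates_per_cell):
            plot_no += 1
            block = f"B{rep % spec.blocks + 1}"
            for plant in range(spec.plants_per_plot):
                sid = f"P{plot_no:03d}" if spec.plants_per_plot == 1 else f"P{plot_no:03d}-{plant + 1}"
                samples.append(SampleRecord(
                    sample_id=sid, species=species, condition=condition,
                    block=block, year=year,
                ))
    assert plot_no == spec.n_plots
    return samples


@dataclass
class GroundTruth:
    """Generator parameters plus (after simulation) the realized truth.

    Configuration fields
    --------------------
    seed : RNG seed; identical seeds give byte-identical outputs.
    n_features_total : number of latent metabolites before polarity split.
    shared_fraction : proportion detectable in both ionization modes.
    polarity_offset : Daltons subtracted from the positive-mode mass to get
        the negative-mode mass of a shared metabolite.
    effect_features : condition -> {metabolite_id: delta}; intensities of
        those metabolites are multiplied by delta (fold change) in samples
        of that condition.
    turnover_features : condition -> {metabolite_id: "loss"|"gain"}; a
        "loss" metabolite is forced absent in that condition, a "gain"
        metabolite is present only in that condition.
    baseline_mu, baseline_sigma : log-normal parameters of per-metabolite
        baseline intensity, exp(N(mu, sigma^2)).
    noise_cv : coefficient of variation of multiplicative sample noise.
    block_sd : SD of the per-(block, metabolite) random effect on log intensity.
    dropout_rate : probability a present feature still reads 0.

    Realized fields (populated by :func:`simulate_tables`)
    ------------------------------------------------------
    registry : DataFrame with one row per latent metabolite
        (metabolite_id, pos_id, neg_id, mass, rt, shared).
    pairs : list of (pos_id, neg_id) for shared metabolites — the ground
        truth the cross-polarity matcher must recover.
    effect_realized / turnover_realized : condition -> set of metabolite ids
        actually simulated with the effect.
    presence_counts : polarity -> {sample_id: number of features with
        intensity > 0} for richness bookkeeping.
    """

    seed: int = 0
    n_features_total: int = 1900
    shared_fraction: float = 0.3
    polarity_offset: float = TWO_PROTON_MASS
    effect_features: dict = field(default_factory=dict)
    turnover_features: dict = field(default_factory=dict)
    baseline_mu: float = 13.0
    baseline_sigma: float = 1.5
    noise_cv: float = 0.25
    block_sd: float = 0.20
    dropout_rate: float = 0.05
    mass_range: tuple[float, float] = (150.0, 800.0)
    rt_range: tuple[float, float] = (1.0, 21.0)
    min_mass_spacing: float = 0.05
    mass_jitter: float = 0.001
    rt_jitter: float = 0.02
    response_sigma: float = 0.5

    # realized (filled by simulate_tables)
    registry: pd.DataFrame | None = None
    pairs: list | None = None
    effect_realized: dict | None = None
    turnover_realized: dict | None = None
    presence_counts: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValidationError("shared_fraction must lie in [0, 1]")
        for cond, eff in self.effect_features.items():
            for fid, delta in eff.items():
                if not delta > 0:
                    raise ValidationError(f"effect delta for {fid!r} in {cond!r} must be > 0")
            toggled = set(self.turnover_features.get(cond, {}))
            overlap = set(eff) & toggled
            if overlap:
                raise ValidationError(
                    f"effect and turnover sets overlap in condition {cond!r}: {sorted(overlap)}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.noise_cv < 0 or self.block_sd < 0:
            raise ValidationError("noise_cv and block_sd must be >= 0")

    @staticmethod
    def from_dict(d: Mapping) -> "GroundTruth":
        kwargs = dict(d)
        for key in ("mass_range", "rt_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("effect_features",):
            if key in kwargs:
                kwargs[key] = {c: {str(f): float(v) for f, v in m.items()} for c, m in kwargs[key].items()}
        if "turnover_features" in kwargs:
            kwargs["turnover_features"] = {
                c: {str(f): str(v) for f, v in m.items()} for c, m in kwargs["turnover_features"].items()}
        return GroundTruth(**kwargs)


def pick_effect_sets(
    truth_seed: int,
    n_features_total: int,
    conditions: Sequence[str],
    n_effect: int,
    delta: float,
    n_turnover: int = 0,
) -> tuple[dict, dict]:
    """Convenience builder: draw disjoint effect and turnover metabolite sets.

    Returns ``(effect_features, turnover_features)`` dictionaries ready for
    :class:`GroundTruth`, using the metabolite naming scheme of
    :func:`simulate_tables`.  Turnover sets alternate loss/gain toggles.
    """
    rng = np.random.default_rng(truth_seed)
    ids = [f"M{i + 1:05d}" for i in range(n_features_total)]
    effect: dict = {}
    turnover: dict = {}
    for cond in conditions:
        chosen = rng.choice(ids, size=n_effect + n_turnover, replace=False)
        effect[cond] = {fid: delta for fid in chosen[:n_effect]}
        if n_turnover:
            turnover[cond] = {
                fid: ("loss" if i % 2 == 0 else "gain")
                for i, fid in enumerate(chosen[n_effect:])
            }
    return effect, turnover


def _spaced_masses(rng: np.random.Generator, n: int, lo: float, hi: float, spacing: float) -> np.ndarray:
    """Draw n masses in [lo, hi] with pairwise spacing >= ``spacing``.

    Uniform order statistics on the slack interval plus a deterministic
    comb; guarantees exact one-to-one matchability when the matcher's mass
    tolerance is below spacing/2.
    """
    slack = (hi - lo) - (n - 1) * spacing
    if slack <= 0:
        raise ValidationError(
            f"cannot place {n} masses in [{lo}, {hi}] with spacing {spacing}")
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + spacing * np.arange(n)


def simulate_tables(
    design: Sequence[SampleRecord],
    truth: GroundTruth,
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Simulate positive- and negative-mode feature tables for a design.

    Returns ``(pos_table, neg_table, realized)`` where ``realized`` is a copy
    of ``truth`` whose realized fields (registry, pairs, effect/turnover
    memberships, per-sample presence counts) record what was actually
    simulated.
    """
    design = list(design)
    if not design:
        raise ValidationError("design must contain at least one sample")
    rng = np.random.default_rng(truth.seed)
    n_total = truth.n_features_total

    # --- metabolite registry -------------------------------------------
    met_ids = [f"M{i + 1:05d}" for i in range(n_total)]
    masses = _spaced_masses(rng, n_total, *truth.mass_range, truth.min_mass_spacing)
    rts = rng.uniform(*truth.rt_range, size=n_total)

    n_shared = int(round(truth.shared_fraction * n_total))
    perm = rng.permutation(n_total)
    shared_idx = np.sort(perm[:n_shared])
    rest = np.sort(perm[n_shared:])
    pos_only_idx = rest[: len(rest) // 2 + len(rest) % 2]
    neg_only_idx = rest[len(rest) // 2 + len(rest) % 2:]

    in_pos = np.zeros(n_total, dtype=bool)
    in_pos[shared_idx] = True
    in_pos[pos_only_idx] = True
    in_neg = np.zeros(n_total, dtype=bool)
    in_neg[shared_idx] = True
    in_neg[neg_only_idx] = True

    pos_ids = np.array([f"P{i + 1:05d}" if in_pos[i] else "" for i in range(n_total)])
    neg_ids = np.array([f"N{i + 1:05d}" if in_neg[i] else "" for i in range(n_total)])

    # --- latent intensity matrix (samples x metabolites) ----------------
    n_samples = len(design)
    conditions = np.array([s.condition for s in design])
    blocks = np.array([s.block for s in design])
    block_levels, block_codes = np.unique(blocks, return_inverse=True)

    baseline = np.exp(rng.normal(truth.baseline_mu, truth.baseline_sigma, size=n_total))
    block_eff = np.exp(rng.normal(0.0, truth.block_sd, size=(len(block_levels), n_total)))
    sigma_n = np.sqrt(np.log1p(truth.noise_cv ** 2))
    noise = np.exp(rng.normal(-0.5 * sigma_n ** 2, sigma_n, size=(n_samples, n_total)))

    latent = baseline[None, :] * block_eff[block_codes, :] * noise

    id_to_col = {m: i for i, m in enumerate(met_ids)}
    effect_realized: dict[str, set] = {}
    for cond, eff in truth.effect_features.items():
        cols = [id_to_col[f] for f in eff if f in id_to_col]
        deltas = np.array([eff[met_ids[c]] for c in cols])
        mask = conditions == cond
        if mask.any() and cols:
            latent[np.ix_(mask, cols)] *= deltas[None, :]
            effect_realized[cond] = {met_ids[c] for c in cols}

    turnover_realized: dict[str, dict] = {}
    for cond, togg in truth.turnover_features.items():
        mask = conditions == cond
        realized = {}
        for fid, kind in togg.items():
            if fid not in id_to_col:
                continue
            c = id_to_col[fid]
            if kind == "loss":
                latent[mask, c] = 0.0
            elif kind == "gain":
                latent[~mask, c] = 0.0
            else:
                raise ValidationError(f"turnover kind must be 'loss' or 'gain', got {kind!r}")
            realized[fid] = kind
        if realized:
            turnover_realized[cond] = realized

    # --- polarity-specific responses and dropout ------------------------
    resp_pos = np.exp(rng.normal(0.0, truth.response_sigma, size=n_total))
    resp_neg = np.exp(rng.normal(0.0, truth.response_sigma, size=n_total))
    drop_pos = rng.random((n_samples, n_total)) < truth.dropout_rate
    drop_neg = rng.random((n_samples, n_total)) < truth.dropout_rate

    inten_pos_full = latent * resp_pos[None, :]
    inten_pos_full[drop_pos] = 0.0
    inten_neg_full = latent * resp_neg[None, :]
    inten_neg_full[drop_neg] = 0.0

    mass_jit = rng.uniform(-truth.mass_jitter, truth.mass_jitter, size=n_total)
    rt_jit = rng.uniform(-truth.rt_jitter, truth.rt_jitter, size=n_total)

    pos_cols = np.flatnonzero(in_pos)
    neg_cols = np.flatnonzero(in_neg)

    pos_features = [
        FeatureRecord(feature_id=pos_ids[i], mass=float(masses[i]), rt=float(rts[i]),
                      polarity="positive", provenance="pos_only")
        for i in pos_cols
    ]
    neg_features = [
        FeatureRecord(
            feature_id=neg_ids[i],
            mass=float(masses[i] - truth.polarity_offset + (mass_jit[i] if in_pos[i] else 0.0)),
            rt=float(max(rts[i] + (rt_jit[i] if in_pos[i] else 0.0), 1e-6)),
            polarity="negative", provenance="neg_only")
        for i in neg_cols
    ]

    pos_table = FeatureTable(features=pos_features, samples=design,
                             intensities=inten_pos_full[:, pos_cols])
    neg_table = FeatureTable(features=neg_features, samples=design,
                             intensities=inten_neg_full[:, neg_cols])

    registry = pd.DataFrame({
        "metabolite_id": met_ids,
        "pos_id": pos_ids,
        "neg_id": neg_ids,
        "mass": masses,
        "rt": rts,
        "shared": in_pos & in_neg,
    })
    pairs = [(pos_ids[i], neg_ids[i]) for i in shared_idx]
    presence_counts = {
        "positive": {s.sample_id: int(np.count_nonzero(inten_pos_full[r, pos_cols]))
                     for r, s in enumerate(design)},
        "negative": {s.sample_id: int(np.count_nonzero(inten_neg_full[r, neg_cols]))
                     for r, s in enumerate(design)},
    }

    realized = replace(
        truth,
        registry=registry,
        pairs=pairs,
        effect_realized=effect_realized,
        turnover_realized={c: set(m) for c, m in turnover_realized.items()},
        presence_counts=presence_counts,
    )
    return pos_table, neg_table, realized


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the realized ground truth (JSON, sorted keys, diffable)."""
    payload = {
        "seed": truth.seed,
        "n_features_total": truth.n_features_total,
        "shared_fraction": truth.shared_fraction,
        "polarity_offset": truth.polarity_offset,
        "baseline_mu": truth.baseline_mu,
        "baseline_sigma": truth.baseline_sigma,
        "noise_cv": truth.noise_cv,
        "block_sd": truth.block_sd,
        "dropout_rate": truth.dropout_rate,
        "effect_features": {c: dict(sorted(m.items())) for c, m in sorted(truth.effect_features.items())},
        "turnover_features": {c: dict(sorted(m.items())) for c, m in sorted(truth.turnover_features.items())},
        "pairs": [list(p) for p in (truth.pairs or [])],
        "effect_realized": {c: sorted(s) for c, s in sorted((truth.effect_realized or {}).items())},
        "turnover_realized": {c: sorted(s) for c, s in sorted((truth.turnover_realized or {}).items())},
        "presence_counts": truth.presence_counts,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_simulation(
    pos: FeatureTable,
    neg: FeatureTable,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write both polarity tables (three-file contract each) plus truth JSON."""
    outdir = Path(outdir)
    paths = {}
    for tag, table in (("pos", pos), ("neg", neg)):
        paths[f"{tag}_intensity"] = outdir / f"{tag}_intensity.csv"
        paths[f"{tag}_features"] = outdir / f"{tag}_features.csv"
        paths[f"{tag}_samples"] = outdir / f"{tag}_samples.csv"
        write_feature_table(table, paths[f"{tag}_intensity"], paths[f"{tag}_features"], paths[f"{tag}_samples"])
    paths["truth"] = outdir / "ground_truth.json"
    write_truth_json(truth, paths["truth"])
    return paths
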