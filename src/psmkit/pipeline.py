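"""End-to-end orchestration: simulate/load -> trim -> fuse -> analyze.

One YAML config drives the whole analysis; :func:`run_pipeline` executes
the stage sequence

    simulate (or load) -> RT trim (per polarity) -> polarity fusion
    -> Canberra perMANOVA / PERMDISP / mean dissimilarity (profiles)
    -> Jaccard perMANOVA / PERMDISP (turnover)
    -> NMDS (k = 2) with group SE ellipses
    -> richness linear mixed model
    -> reference-condition shift report

and writes a machine-readable JSON report (schema versioned, every seed
and parameter echoed, counts in/out of every filter) plus a one-row-per-
condition TSV summary.  Identical config and seeds give a byte-identical
report: the report contains no timestamps and is serialized with sorted
keys.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .abundance_shifts import shift_report
from .diversity import binarize, canberra_matrix, jaccard_matrix, richness
from .feature_io import FeatureTable, ValidationError, read_feature_table, trim_rt_window
from .mixed_models import fit_lme
from .ordination import group_ellipses, nmds
from .permstats import meandist, permanova, permdisp
from .polarity_fusion import MatchConfig, match_features, merge_tables
from .synthetic_data import DesignSpec, GroundTruth, make_design, simulate_tables, write_simulation

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "reference": None,              # required: reference condition label
    "rt_window": [1.0, 21.0],
    "match": {"mass_offset": None, "mass_tol": 0.005, "rt_tol": 0.10, "paper_mode": False},
    "presence_threshold": 0.0,
    "n_perm": 9999,
    "permdisp": {"center_type": "spatial_median", "n_perm": 999},
    "nmds": {"k": 2, "n_restarts": 20, "max_iter": 300, "tol": 1e-7},
    "shifts": {"threshold_pct": 75.0, "normalize": False},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    return cfg


def _merged_config(cfg: Mapping) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj)
        if isinstance(obj, (set, frozenset)):
            items = sorted(str(x) for x in items)
        return [_jsonable(x) for x in items]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def _acquire_tables(cfg: dict, outdir: Path) -> tuple[FeatureTable, FeatureTable, dict]:
    """Simulate from the config's simulation block or load from file paths."""
    if "simulation" in cfg:
        sim = cfg["simulation"]
        design_spec = DesignSpec.from_dict(sim["design"])
        truth_cfg = dict(sim.get("truth", {}))
        truth_cfg.setdefault("seed", cfg["seed"])
        truth = GroundTruth.from_dict(truth_cfg)
        design = make_design(design_spec,
                             species=sim.get("species", "speciesA"),
                             year=sim.get("year", "Y1"))
        pos, neg, realized = simulate_tables(design, truth)
        write_simulation(pos, neg, realized, outdir / "simulated")
        prov = {
            "source": "simulation",
            "n_plots": design_spec.n_plots,
            "n_samples": len(design),
            "n_features_total": truth.n_features_total,
            "truth_seed": truth.seed,
        }
        return pos, neg, prov
    if "inputs" in cfg:
        paths = cfg["inputs"]
        pos = read_feature_table(paths["pos_intensity"], paths["pos_features"], paths["pos_samples"])
        neg = read_feature_table(paths["neg_intensity"], paths["neg_features"], paths["neg_samples"])
        return pos, neg, {"source": "files", **{k: str(v) for k, v in paths.items()}}
    raise ValidationError("config needs either a 'simulation' or an 'inputs' block")


def run_pipeline(cfg: Mapping, outdir: str | Path) -> dict:
    """Run the full analysis described by ``cfg``; returns the report dict.

    Writes ``report.json`` and ``summary.tsv`` under ``outdir`` plus all
    intermediate stage outputs with deterministic filenames.
    """
    cfg = _merged_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "psmkit_version": __version__,
        "config": _jsonable(cfg),
        "stages": {},
    }

    stage = "acquire"
    try:
        pos, neg, prov = _acquire_tables(cfg, outdir)
        report["stages"]["acquire"] = prov

        stage = "trim"
        rt_lo, rt_hi = cfg["rt_window"]
        pos_t = trim_rt_window(pos, rt_lo, rt_hi)
        neg_t = trim_rt_window(neg, rt_lo, rt_hi)
        report["stages"]["trim"] = {
            "rt_window": [rt_lo, rt_hi],
            "pos_in": pos.n_features, "pos_out": pos_t.n_features,
            "neg_in": neg.n_features, "neg_out": neg_t.n_features,
        }

        stage = "fusion"
        mc = cfg["match"]
        match_kwargs = {k: mc[k] for k in ("mass_tol", "rt_tol", "paper_mode") if mc.get(k) is not None}
        if mc.get("mass_offset") is not None:
            match_kwargs["mass_offset"] = mc["mass_offset"]
        match_cfg = MatchConfig(**match_kwargs)
        match = match_features(pos_t, neg_t, match_cfg)
        fused = merge_tables(pos_t, neg_t, match)
        report["stages"]["fusion"] = {
            "mass_offset": match_cfg.mass_offset,
            "mass_tol": match_cfg.mass_tol,
            "rt_tol": match_cfg.rt_tol,
            "paper_mode": match_cfg.paper_mode,
            "n_pairs": len(match.pairs),
            "n_unmatched_pos": len(match.unmatched_positive),
            "n_unmatched_neg": len(match.unmatched_negative),
            "n_features_fused": fused.n_features,
        }
        from .feature_io import write_feature_table
        write_feature_table(fused, outdir / "fused_intensity.csv",
                            outdir / "fused_features.csv", outdir / "fused_samples.csv")

        groups = fused.conditions
        strata = fused.blocks
        thresh = float(cfg["presence_threshold"])
        n_perm = int(cfg["n_perm"])

        stage = "profiles"
        D_can = canberra_matrix(fused)
        perm_can = permanova(D_can, groups, strata=strata, n_perm=n_perm,
                             seed=seed + 1, method="monte-carlo")
        disp_can = permdisp(D_can, groups, center_type=cfg["permdisp"]["center_type"],
                            n_perm=int(cfg["permdisp"]["n_perm"]), seed=seed + 2)
        md_can = meandist(D_can, groups)
        report["stages"]["profiles"] = {
            "metric": "canberra",
            "permanova": {"F": perm_can.F, "r2": perm_can.r2, "p": perm_can.p,
                          "n_perm": perm_can.n_perm, "method": perm_can.method},
            "permdisp": {"F": disp_can.F, "p": disp_can.p,
                         "center_type": disp_can.center_type},
            "meandist": {"groups": md_can.groups, "m": md_can.m,
                         "centroid_separation": md_can.centroid_separation},
        }
        D_can.to_frame().to_csv(outdir / "canberra.csv", float_format="%.12g")

        stage = "turnover"
        B = binarize(fused, thresh)
        D_jac = jaccard_matrix(B, fused.sample_ids)
        perm_jac = permanova(D_jac, groups, strata=strata, n_perm=n_perm,
                             seed=seed + 3, method="monte-carlo")
        disp_jac = permdisp(D_jac, groups, center_type=cfg["permdisp"]["center_type"],
                            n_perm=int(cfg["permdisp"]["n_perm"]), seed=seed + 4)
        report["stages"]["turnover"] = {
            "metric": "jaccard",
            "presence_threshold": thresh,
            "permanova": {"F": perm_jac.F, "r2": perm_jac.r2, "p": perm_jac.p,
                          "n_perm": perm_jac.n_perm, "method": perm_jac.method},
            "permdisp": {"F": disp_jac.F, "p": disp_jac.p},
        }
        D_jac.to_frame().to_csv(outdir / "jaccard.csv", float_format="%.12g")

        stage = "nmds"
        nm = cfg["nmds"]
        ord_res = nmds(D_can, k=int(nm["k"]), n_restarts=int(nm["n_restarts"]),
                       max_iter=int(nm["max_iter"]), tol=float(nm["tol"]), seed=seed + 5)
        ellipses = group_ellipses(ord_res, groups)
        report["stages"]["nmds"] = {
            "k": int(nm["k"]),
            "stress": ord_res.stress,
            "converged": ord_res.converged,
            "best_restart": ord_res.best_restart,
            "n_restarts": ord_res.n_restarts,
            "ellipses": [
                {"group": e.group, "center": e.center, "covariance": e.covariance,
                 "radius_scale": e.radius_scale, "level": e.level, "n": e.n,
                 "degenerate": e.degenerate}
                for e in ellipses
            ],
        }
        scores = ord_res.scores
        with open(outdir / "nmds_scores.tsv", "w") as fh:
            fh.write("sample_id\t" + "\t".join(f"NMDS{i+1}" for i in range(scores.shape[1])) + "\n")
            for sid, row in zip(ord_res.sample_ids, scores):
                fh.write(sid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")

        stage = "richness_lme"
        reference = cfg.get("reference")
        if reference is None:
            raise ValidationError("config must name the reference condition")
        rich = richness(fused, thresh)
        lme = fit_lme(rich.to_numpy(), groups, strata, reference=reference,
                      response_name="richness")
        report["stages"]["richness_lme"] = {
            "reference": reference,
            "mean_richness": float(rich.mean()),
            "effects": {
                lvl: {"estimate": fe.estimate, "se": fe.se, "p": fe.p}
                for lvl, fe in lme.fixed_effects.items()
            },
            "random_intercept_sd": lme.random_intercept_sd,
            "residual_sd": lme.residual_sd,
            "boundary": lme.boundary,
        }

        stage = "shifts"
        sh = cfg["shifts"]
        rep = shift_report(fused, reference, threshold_pct=float(sh["threshold_pct"]),
                           normalize=bool(sh["normalize"]))
        report["stages"]["shifts"] = {
            "reference": reference,
            "threshold_pct": rep.threshold_pct,
            "n_undetected_in_reference": len(rep.undetected),
            "counts": {c: {"up": len(rep.up_sets[c]), "down": len(rep.down_sets[c])}
                       for c in rep.relative_change.columns},
            "venn_up": rep.venn_up,
            "venn_down": rep.venn_down,
        }
        rep.counts_table().to_csv(outdir / "shift_counts.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 — stage attribution, then re-raise
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    # summary TSV: one row per condition, Table-style layout
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("condition\tn\tfeatures\tcanberra_F\tcanberra_r2\tcanberra_p\t"
                 "dispersion_F\tdispersion_p\tjaccard_F\tjaccard_r2\tjaccard_p\t"
                 "delta_richness\trichness_p\tn_up\tn_down\n")
        for cond in dict.fromkeys(groups.tolist()):
            n_c = int((groups == cond).sum())
            fe = lme.fixed_effects.get(cond)
            is_ref = cond == reference
            fh.write("\t".join([
                cond, str(n_c), str(fused.n_features),
                f"{perm_can.F:.6g}", f"{perm_can.r2:.6g}", f"{perm_can.p:.6g}",
                f"{disp_can.F:.6g}", f"{disp_can.p:.6g}",
                f"{perm_jac.F:.6g}", f"{perm_jac.r2:.6g}", f"{perm_jac.p:.6g}",
                "0" if is_ref else (f"{fe.estimate:.6g}" if fe else "NA"),
                "NA" if is_ref or fe is None else f"{fe.p:.6g}",
                "0" if is_ref else str(len(rep.up_sets.get(cond, set()))),
                "0" if is_ref else str(len(rep.down_sets.get(cond, set()))),
            ]) + "\n")

    payload = _jsonable(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
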