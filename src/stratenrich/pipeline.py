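"""End-to-end orchestration: ingest → prune → genomic control → curves →
GLM → interactions → locus overlap → cross-trait summary.

``run_all`` takes a single configuration mapping (or YAML path), runs every
stage for every trait × annotation set, writes TSV/JSON artifacts plus a
manifest (config hash, seeds, stage log) and returns the in-memory results.
Any stage failure aborts with the stage name; artifacts written so far are
kept and the manifest marks the run incomplete.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc_stats import add_chisq, apply_gc, gc_lambda
from .control_matching import match_controls
from .enrichment_curves import estimate_pi1, fold_enrichment, mann_whitney, qq_points
from .glm_enrich import DesignSpec, fit_on_replicates, interaction_scan
from .io_formats import (
    AnnotationSet,
    assign_bed_annotations,
    assign_proximal_distal,
    eqtl_annotation_sets,
    read_bed,
    read_eqtl_table,
    read_gwas,
    read_ld_pairs,
    read_loci,
    read_variant_table,
    restrict_to_template,
)
from .ld_ops import build_conflict_graph, random_prune, total_ld_score
from .locus_overlap import locus_overlap_analysis, significant_loci
from .synthetic_data import (
    SimConfig,
    make_fixture,
    simulate_expression_p,
    simulate_gwas,
    simulate_variants,
)

logger = logging.getLogger(__name__)

DEFAULT_ANALYSIS = {
    "seed": 0,
    "n_sets": 10,
    "r2_max": 0.2,
    "window_bp": 1_000_000,
    "tss_threshold": 25_000,
    "fold_bin_width": 0.1,
    "min_denominator": 10,
    "control_ratio": 1.2,
    "interactions": True,
    "overlap": {"r2_min": 0.8, "p_threshold": 5e-8, "K": None, "N": None},
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a YAML path")
    out = dict(config)
    analysis = dict(DEFAULT_ANALYSIS)
    overlap = dict(DEFAULT_ANALYSIS["overlap"])
    user = out.get("analysis", {})
    overlap.update(user.get("overlap", {}))
    analysis.update(user)
    analysis["overlap"] = overlap
    out["analysis"] = analysis
    if ("simulate" in out) == ("inputs" in out):
        raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_inputs(config: dict):
    """Stage 'ingest': simulate in memory or read the external files."""
    if "simulate" in config:
        sim = dict(config["simulate"])
        scale = sim.pop("scale", None)
        if scale is not None:
            fx = make_fixture(
                scale,
                out_dir=sim.pop("out_dir", None) or Path("scratch") / f"fixture_{scale}",
                seed=sim.pop("seed", 0),
            )
            mem = fx["in_memory"]
            return mem["variants"], mem["ld_pairs"], mem["sets"], mem["stats"], mem["expression_p"], None
        sc = SimConfig(**sim)
        variants, ld_pairs, sets = simulate_variants(sc)
        stats = {t: simulate_gwas(variants, sc, t, sets) for t in sc.traits}
        expr = simulate_expression_p(variants, sc, sets)
        return variants, ld_pairs, sets, stats, expr, None

    paths = config["inputs"]
    variants = read_variant_table(paths["variants"])
    ld_pairs = read_ld_pairs(paths["ld_pairs"])
    sets = {}
    if paths.get("eqtl"):
        sets.update(eqtl_annotation_sets(read_eqtl_table(paths["eqtl"])))
    if paths.get("bed"):
        sets.update(assign_bed_annotations(variants, read_bed(paths["bed"])))
    stats = {}
    for trait, path in paths.get("gwas", {}).items():
        stats[trait] = read_gwas(path, trait=trait)
    if not stats:
        raise ValueError("no GWAS inputs configured")
    expr = {}
    if paths.get("expression_p"):
        tab = pd.read_csv(paths["expression_p"], sep="\t", dtype={"SNP": str})
        expr = dict(zip(tab["SNP"], tab["P_EXPR"]))
    if paths.get("template"):
        template = [l.strip() for l in Path(paths["template"]).read_text().splitlines() if l.strip()]
        variants, _, sets = restrict_to_template(variants, None, template, sets)
        universe = frozenset(variants["variant_id"])
        stats = {t: s.loc[s["variant_id"].isin(universe)].reset_index(drop=True) for t, s in stats.items()}
    loci = read_loci(paths["loci"]) if paths.get("loci") else None
    return variants, ld_pairs, sets, stats, expr, loci


def _eqtl_union(sets) -> AnnotationSet:
    ids = frozenset()
    for lab, s in sets.items():
        if lab.startswith("eqtl:") and lab != "eqtl:all":
            ids |= s.variant_ids
    return AnnotationSet("eqtl:all", ids, provenance="union over tissues")


def run_all(config, out_dir) -> dict:
    """Run the full stratified-enrichment pipeline under one configuration."""
    config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = config["analysis"]
    manifest = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": analysis["seed"],
        "stages": [],
        "complete": False,
    }

    def _write_manifest():
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    def stage(name):
        manifest["stages"].append(name)
        _write_manifest()
        logger.info("stage: %s", name)

    results: dict = {"config": config}
    try:
        stage("ingest")
        variants, ld_pairs, sets, stats_by_trait, expression_p, loci = _load_inputs(config)
        if not sets or not any(l.startswith("eqtl:") for l in sets):
            raise ValueError("no eQTL annotation sets configured")
        logger.info("ingest: %d variants, %d LD pairs, %d traits",
                    len(variants), len(ld_pairs), len(stats_by_trait))

        stage("annotate")
        if variants["total_ld"].isna().any():
            variants = variants.copy()
            variants["total_ld"] = total_ld_score(variants, ld_pairs, analysis["window_bp"]).to_numpy()
        variants, tss_sets, tss_threshold = assign_proximal_distal(variants, analysis["tss_threshold"])
        sets = dict(sets)
        sets.update(tss_sets)
        sets["eqtl:all"] = _eqtl_union(sets)
        eqtl_labels = sorted(l for l in sets if l.startswith("eqtl:") and l != "eqtl:all")
        roadmap_labels = sorted(l for l in sets if l.startswith("roadmap:"))
        sets["eqtl:proximal"] = AnnotationSet(
            "eqtl:proximal", sets["eqtl:all"].variant_ids & sets["proximal"].variant_ids, "eQTL ∩ proximal"
        )
        sets["eqtl:distal"] = AnnotationSet(
            "eqtl:distal", sets["eqtl:all"].variant_ids & sets["distal"].variant_ids, "eQTL ∩ distal"
        )

        stage("match_controls")
        for lab in eqtl_labels + ["eqtl:all"]:
            clab = "control:" + lab.removeprefix("eqtl:")
            res = match_controls(
                sets[lab], variants, expression_p,
                ratio=analysis["control_ratio"], seed=analysis["seed"], label=clab,
            )
            sets[clab] = res.controls

        stage("prune")
        graph = build_conflict_graph(variants, ld_pairs, analysis["r2_max"], analysis["window_bp"])
        replicates = random_prune(
            variants, ld_pairs,
            r2_max=analysis["r2_max"], window_bp=analysis["window_bp"],
            n_sets=analysis["n_sets"], seed=analysis["seed"], graph=graph,
        )
        results["replicates"] = replicates

        stage("genomic_control")
        corrected = {}
        results["gc"] = {}
        for trait, stats in stats_by_trait.items():
            stats = add_chisq(stats)
            gc = gc_lambda(stats, variants, replicates)
            corrected[trait] = apply_gc(stats, gc)
            results["gc"][trait] = gc
            gc.to_json(out_dir / f"gc_{trait}.json")
            logger.info("genomic control %s: lambda = %.4f", trait, gc.lambda_gc)

        stage("curves")
        set_pairs = [(lab, "control:" + lab.removeprefix("eqtl:")) for lab in eqtl_labels + ["eqtl:all"]]
        curves_rows, results["curves"] = [], {}
        for trait, stats in corrected.items():
            z2 = stats.set_index("variant_id")["z2"]
            pmap = stats.set_index("variant_id")["p"]
            for eqtl_lab, ctrl_lab in set_pairs:
                e_ids = sorted(sets[eqtl_lab].variant_ids & frozenset(pmap.index))
                c_ids = sorted(sets[ctrl_lab].variant_ids & frozenset(pmap.index))
                if not e_ids or not c_ids:
                    continue
                pe, pc = pmap.loc[e_ids].to_numpy(), pmap.loc[c_ids].to_numpy()
                curve = fold_enrichment(pe, pc, analysis["fold_bin_width"], analysis["min_denominator"])
                _, p_mw = mann_whitney(z2.loc[e_ids].to_numpy(), z2.loc[c_ids].to_numpy())
                pi1_e = estimate_pi1(pe).pi1
                pi1_c = estimate_pi1(pc).pi1
                qq = qq_points(pe)
                results["curves"][(trait, eqtl_lab)] = {
                    "fold": curve, "p_mw": p_mw, "pi1_eqtl": pi1_e, "pi1_control": pi1_c, "qq": qq,
                }
                curves_rows.append(
                    {"trait": trait, "set": eqtl_lab, "pi1_eqtl": pi1_e, "pi1_control": pi1_c, "p_mw": p_mw}
                )
                pd.DataFrame(
                    {
                        "threshold": curve.thresholds,
                        "fold_enrichment": curve.ratio,
                        "n_set": curve.n_numerator,
                        "n_baseline": curve.n_denominator,
                    }
                ).to_csv(out_dir / f"fold_{trait}_{eqtl_lab.replace(':', '_')}.tsv", sep="\t", index=False)
        pd.DataFrame(curves_rows).to_csv(out_dir / "curves_summary.tsv", sep="\t", index=False)

        stage("glm")
        results["glm"] = {}
        glm_rows = []
        for trait, stats in corrected.items():
            for eqtl_lab, ctrl_lab in set_pairs + [("eqtl:proximal", "eqtl:distal")]:
                terms = [eqtl_lab, ctrl_lab, *roadmap_labels, "total_ld"]
                terms = [t for t in terms if t == "total_ld" or len(sets[t]) > 0]
                spec = DesignSpec(terms=tuple(terms), scope="full")
                fit = fit_on_replicates(variants, stats, replicates, spec, sets)
                results["glm"][(trait, eqtl_lab)] = fit
                for _, row in fit.table.iterrows():
                    if row["term"] in (eqtl_lab, ctrl_lab):
                        glm_rows.append({"trait": trait, "model": eqtl_lab, **row.to_dict()})
        glm_table = pd.DataFrame(glm_rows)
        glm_table.to_csv(out_dir / "glm_enrichment.tsv", sep="\t", index=False)
        results["glm_table"] = glm_table

        if analysis["interactions"] and roadmap_labels:
            stage("interactions")
            results["interactions"] = {}
            for trait, stats in corrected.items():
                base = DesignSpec(
                    terms=("eqtl:all", "control:all", *roadmap_labels, "total_ld"), scope="full"
                )
                fit = interaction_scan(
                    variants, stats, replicates, base, sets,
                    eqtl_term="eqtl:all", partner_terms=(*roadmap_labels, "total_ld"),
                )
                results["interactions"][trait] = fit
                fit.table.to_csv(out_dir / f"interactions_{trait}.tsv", sep="\t", index=False)

        stage("locus_overlap")
        first_trait = next(iter(corrected))
        if loci is None:
            loci = significant_loci(corrected[first_trait], variants,
                                    p_threshold=analysis["overlap"]["p_threshold"])
        results["loci"] = loci
        if len(loci):
            K = analysis["overlap"]["K"] or len(sets["eqtl:all"])
            N = analysis["overlap"]["N"] or len(variants)
            overlap = locus_overlap_analysis(
                loci, sets["eqtl:all"], variants, ld_pairs, K=K, N=N,
                r2_min=analysis["overlap"]["r2_min"],
            )
            results["overlap"] = overlap
            (out_dir / "overlap.json").write_text(json.dumps({
                "n_loci": overlap.n_loci, "k_overlapping": overlap.k_overlapping,
                "baseline_fraction": overlap.baseline_fraction,
                "overlap_fraction": overlap.overlap_fraction,
                "enrichment_ratio": overlap.enrichment_ratio,
                "reciprocal_ratio": overlap.reciprocal_ratio,
                "odds_ratio": overlap.odds_ratio, "fisher_p": overlap.fisher_p,
            }, indent=1))
            if overlap.detail is not None:
                overlap.detail.to_csv(out_dir / "overlap_detail.tsv", sep="\t", index=False)

        stage("summary")
        summary = summary_table(results)
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        results["summary"] = summary
        results["variants"], results["sets"], results["stats"] = variants, sets, corrected
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["failed_stage"] = failed
        _write_manifest()
        raise StageError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    manifest["complete"] = True
    manifest["prune_seeds"] = results["replicates"].seeds
    _write_manifest()
    return results


def summary_table(results: dict) -> pd.DataFrame:
    """Cross-trait summary: one row per trait × set with π1, Mann-Whitney
    −log10 p, the meta GLM coefficient and its p (the coordinates and sizes
    of the cross-trait enrichment scatter)."""
    rows = []
    for (trait, lab), cur in results.get("curves", {}).items():
        row = {
            "trait": trait,
            "set": lab,
            "pi1": cur["pi1_eqtl"],
            "pi1_control": cur["pi1_control"],
            "neg_log10_p_mw": float(-np.log10(max(cur["p_mw"], 1e-300))),
        }
        fit = results.get("glm", {}).get((trait, lab))
        if fit is not None:
            term = fit.term(lab)
            row["beta_bar"] = float(term["beta_bar"])
            row["glm_p"] = float(term["p"])
        rows.append(row)
    return pd.DataFrame(rows)
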