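"""Synthetic variant maps, annotations and GWAS summary statistics.

The generator emulates the statistical structure the enrichment pipeline
assumes, at a desk scale where every stage is consequential:

* **Block LD** — variants sit in blocks of ``block_size`` spanning
  ``block_span_bp``; within a block each variant carries a loading
  ρ_i ~ Beta(a, b) on a shared haplotype factor, giving pairwise
  r²(i, j) = ρ_i·ρ_j (positive semi-definite by construction) and zero LD
  across blocks.  The emitted pairwise LD list is exact, so LD-score and
  pruning oracles can be checked against it.
* **Annotations** — per-tissue eQTL sets of a configurable fraction share a
  common core so that the pairwise overlap between tissues is exactly the
  configured sharing fraction (~10% in real cross-tissue eQTL panels);
  chromatin-state categories and a genic flag are assigned independently;
  TSS distances are log-uniform between 1 kb and 500 kb so the 25 kb
  proximal/distal split is non-degenerate.
* **Association statistics** — z-scores are drawn jointly within a block
  (corr(z_i, z_j) = √(ρ_i·ρ_j)) with per-variant variance
  σ²_i = λ·(1 + Σ_k β_k·x_ik + β_LD·(totLD_i − 1)) for the non-null
  fraction of each annotation class and σ²_i = λ otherwise.  Effects are
  injected on the E[χ²] scale, so the linear-in-χ² enrichment model is
  correctly specified and a fitted coefficient estimates the configured
  β_k directly.

All randomness flows from ``SimConfig.seed`` through a documented
``numpy.random.SeedSequence`` splitting scheme: stream 0 builds the variant
map, stream (1, i) the GWAS for trait i, stream 2 expression-association
p-values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import ld_ops
from .io_formats import AnnotationSet, write_ld_pairs, write_variant_table

DEFAULT_ROADMAP_FRACTIONS = {
    "active_promoter": 0.03,
    "weak_promoter": 0.03,
    "strong_enhancer": 0.04,
    "weak_enhancer": 0.05,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    ``beta`` maps annotation classes to enrichment coefficients on the
    E[χ²] scale; keys are ``"eqtl"`` (union of tissue eQTL sets), a concrete
    label such as ``"roadmap:active_promoter"``, or an intersection
    ``"eqtl*roadmap:active_promoter"``.  ``nonnull_fraction`` gives the
    per-class fraction of members that carry the effect (1 = the whole
    class is inflated).
    """

    n_variants: int = 100_000
    block_size: int = 20
    block_span_bp: int = 60_000
    block_gap_bp: int = 40_000
    n_chroms: int = 10
    rho_beta: tuple = (2.0, 2.0)
    maf_range: tuple = (0.01, 0.5)
    tissues: tuple = ("adipose", "epidermal", "lcl", "blood")
    eqtl_fraction: float = 0.02
    tissue_sharing: float = 0.10
    roadmap_fractions: Mapping = field(default_factory=lambda: dict(DEFAULT_ROADMAP_FRACTIONS))
    genic_fraction: float = 0.5
    beta: Mapping = field(default_factory=lambda: {"eqtl": 0.20})
    trait_beta: Mapping = field(default_factory=dict)  # per-trait overrides of ``beta``
    beta_ld: float = 0.0
    nonnull_fraction: Mapping = field(default_factory=lambda: {"eqtl": 1.0})
    lambda_gc: float = 1.0
    traits: tuple = ("trait1",)
    seed: int = 0

    def __post_init__(self):
        fracs = [self.eqtl_fraction, self.tissue_sharing, self.genic_fraction]
        fracs += list(self.roadmap_fractions.values())
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(self.roadmap_fractions.values()) > 1:
            raise ValueError("chromatin-state category fractions sum above 1 (exclusive assignment)")
        if self.lambda_gc < 1:
            raise ValueError("genomic inflation lambda must be >= 1")
        if any(b < 0 for b in self.beta.values()):
            raise ValueError("enrichment coefficients must be >= 0")


def _rng(config: SimConfig, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


def simulate_variants(config: SimConfig):
    """Build the variant table, exact pairwise LD list and annotation sets.

    Returns ``(variants, ld_pairs, sets)`` where ``sets`` holds one
    ``eqtl:<tissue>`` set per tissue and one ``roadmap:<category>`` set per
    chromatin-state category.  ``total_ld`` on the variant table is the LD
    score computed from the emitted pair list.
    """
    rng = _rng(config, 0)
    n = config.n_variants
    m = config.block_size
    n_blocks = int(np.ceil(n / m))

    block_of = np.repeat(np.arange(n_blocks), m)[:n]
    within = np.concatenate([np.arange(min(m, n - b * m)) for b in range(n_blocks)])
    blocks_per_chrom = int(np.ceil(n_blocks / config.n_chroms))
    chrom_idx = block_of // blocks_per_chrom
    block_on_chrom = block_of % blocks_per_chrom
    spacing = max(config.block_span_bp // max(m, 1), 1)
    pos = 1 + block_on_chrom * (config.block_span_bp + config.block_gap_bp) + within * spacing
    chrom = np.array([f"chr{c + 1}" for c in chrom_idx])
    ids = np.array([f"rs{i + 1}" for i in range(n)])

    rho = rng.beta(config.rho_beta[0], config.rho_beta[1], size=n)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    genic = rng.random(n) < config.genic_fraction
    tss_distance = np.floor(10 ** rng.uniform(3.0, np.log10(5e5), size=n)).astype(int)

    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "maf": maf,
            "is_genic": genic,
            "tss_distance": tss_distance.astype(float),
            "total_ld": np.nan,
            "_block": block_of,
            "_rho": rho,
        }
    )

    # exact within-block pairwise r2 = rho_i * rho_j
    ia, ib = [], []
    for b in range(n_blocks):
        members = np.nonzero(block_of == b)[0]
        if members.size < 2:
            continue
        ti, tj = np.triu_indices(members.size, k=1)
        ia.append(members[ti])
        ib.append(members[tj])
    if ia:
        ia = np.concatenate(ia)
        ib = np.concatenate(ib)
        ld_pairs = pd.DataFrame(
            {
                "id_a": ids[ia],
                "pos_a": pos[ia].astype(np.int64),
                "id_b": ids[ib],
                "pos_b": pos[ib].astype(np.int64),
                "r2": rho[ia] * rho[ib],
            }
        )
    else:
        ld_pairs = pd.DataFrame(columns=["id_a", "pos_a", "id_b", "pos_b", "r2"])

    variants["total_ld"] = ld_ops.total_ld_score(variants, ld_pairs).to_numpy()

    sets = {}
    per_tissue = int(round(config.eqtl_fraction * n))
    if per_tissue > 0 and config.tissues:
        core_n = int(round(config.tissue_sharing * per_tissue))
        unique_n = per_tissue - core_n
        need = core_n + unique_n * len(config.tissues)
        drawn = rng.choice(n, size=min(need, n), replace=False)
        core = drawn[:core_n]
        rest = drawn[core_n:]
        for t_idx, tissue in enumerate(config.tissues):
            uniq = rest[t_idx * unique_n : (t_idx + 1) * unique_n]
            members = frozenset(ids[np.concatenate([core, uniq])])
            lab = f"eqtl:{tissue}"
            sets[lab] = AnnotationSet(lab, members, provenance="simulated eQTL designation")

    cats = list(config.roadmap_fractions)
    probs = np.array([config.roadmap_fractions[c] for c in cats] + [0.0])
    probs[-1] = 1.0 - probs[:-1].sum()
    assignment = rng.choice(len(cats) + 1, size=n, p=probs)
    for c_idx, cat in enumerate(cats):
        lab = f"roadmap:{cat}"
        sets[lab] = AnnotationSet(
            lab, frozenset(ids[assignment == c_idx]), provenance="simulated chromatin state"
        )
    return variants, ld_pairs, sets


def _class_members(key: str, sets: Mapping, variants: pd.DataFrame) -> frozenset:
    """Resolve a beta key: 'eqtl' union, a concrete label, or 'a*b' intersection."""
    if "*" in key:
        parts = key.split("*")
        members = _class_members(parts[0], sets, variants)
        for part in parts[1:]:
            members &= _class_members(part, sets, variants)
        return members
    if key == "eqtl":
        out = frozenset()
        for lab, s in sets.items():
            if lab.startswith("eqtl:"):
                out |= s.variant_ids
        return out
    if key in sets:
        return frozenset(getattr(sets[key], "variant_ids", sets[key]))
    raise KeyError(f"unknown annotation class {key!r} in effect configuration")


def simulate_gwas(
    variants: pd.DataFrame,
    config: SimConfig,
    trait: str | None = None,
    sets: Mapping | None = None,
) -> pd.DataFrame:
    """Draw block-correlated association z-scores and return a p-value table.

    Within a block, z_i = σ_i·(√ρ_i·u_b + √(1−ρ_i)·e_i) with a shared
    factor u_b per block, so corr(z_i, z_j) = √(ρ_i ρ_j) matches the
    emitted r² and E[z²_i] = σ²_i carries the configured enrichment.
    """
    sets = sets or {}
    trait = trait or config.traits[0]
    t_idx = list(config.traits).index(trait) if trait in config.traits else 0
    rng = _rng(config, 1, t_idx)

    n = len(variants)
    ids = variants["variant_id"].to_numpy()
    id_index = pd.Index(ids)
    sigma2 = np.ones(n)
    betas = config.trait_beta.get(trait, config.beta)
    for key, beta_k in betas.items():
        members = _class_members(key, sets, variants)
        x = id_index.isin(members)
        frac = config.nonnull_fraction.get(key, 1.0)
        nonnull = x & (rng.random(n) < frac)
        sigma2 = sigma2 + beta_k * nonnull
    if config.beta_ld != 0.0:
        sigma2 = sigma2 + config.beta_ld * (variants["total_ld"].to_numpy(dtype=float) - 1.0)
    sigma2 = config.lambda_gc * sigma2
    if np.any(sigma2 <= 0):
        raise ValueError("non-positive variance in the association model")

    rho = variants["_rho"].to_numpy() if "_rho" in variants.columns else np.zeros(n)
    block = variants["_block"].to_numpy() if "_block" in variants.columns else np.arange(n)
    u = rng.standard_normal(block.max() + 1)
    e = rng.standard_normal(n)
    z = np.sqrt(sigma2) * (np.sqrt(rho) * u[block] + np.sqrt(1.0 - rho) * e)
    from scipy import stats as sps

    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, 1e-300, 1.0)
    return pd.DataFrame({"variant_id": ids, "trait": trait, "p": p})


def simulate_expression_p(
    variants: pd.DataFrame, config: SimConfig, sets: Mapping, hot_fraction: float = 0.02
) -> dict:
    """Minimum expression-association p per variant, for control exclusion.

    eQTLs get genuinely small p-values; a ``hot_fraction`` of the remaining
    pool gets sub-threshold p so the exclusion rule has something to do.
    """
    rng = _rng(config, 2)
    ids = variants["variant_id"].to_numpy()
    eqtl = _class_members("eqtl", sets, variants) if sets else frozenset()
    p = rng.uniform(1e-3, 1.0, size=len(ids))
    hot = rng.random(len(ids)) < hot_fraction
    p[hot] = rng.uniform(1e-12, 1e-5, size=int(hot.sum()))
    is_eqtl = pd.Index(ids).isin(eqtl)
    p[is_eqtl] = rng.uniform(1e-16, 1e-8, size=int(is_eqtl.sum()))
    return dict(zip(ids, p))


def simulate_pvalue_mixture(
    n: int, pi1: float, seed: int = 0, alt_shift: float = 3.0, alt_scale: float = 3.0
) -> np.ndarray:
    """Uniform nulls mixed with strong alternatives at proportion ``pi1``.

    Alternative z magnitudes are ``alt_shift + |N(0, alt_scale²)|`` so every
    alternative p-value is at most ~2.7e-3 and the Storey tail is pure null.
    """
    if not 0 <= pi1 <= 1:
        raise ValueError("pi1 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_alt = int(round(pi1 * n))
    p = rng.uniform(0, 1, size=n)
    p[p == 0] = 1e-300
    if n_alt:
        from scipy import stats as sps

        z = alt_shift + np.abs(rng.normal(0, alt_scale, size=n_alt))
        p[:n_alt] = np.clip(2.0 * sps.norm.sf(z), 1e-300, 1.0)
    rng.shuffle(p)
    return p


TINY = SimConfig(n_variants=2_000, block_size=10, block_span_bp=30_000, traits=("trait1",))
DESK = SimConfig(
    n_variants=100_000,
    block_size=20,
    traits=("trait1", "trait2"),
    lambda_gc=1.1,
    beta={"eqtl": 0.20},
)


def make_fixture(scale: str = "tiny", out_dir=None, seed: int = 0) -> dict:
    """Write a complete input directory in the formats the readers expect.

    ``tiny`` (2,000 variants) is for unit tests; ``desk`` (100,000 variants,
    4 tissues, 2 traits) for end-to-end runs.  The manifest records the full
    configuration and seed; the same seed reproduces the files byte for
    byte.  Returns a dict of paths plus the in-memory objects.
    """
    base = {"tiny": TINY, "desk": DESK}.get(scale)
    if base is None:
        raise ValueError("scale must be 'tiny' or 'desk'")
    config = SimConfig(**{**asdict(base), "seed": seed})
    out_dir = Path(out_dir) if out_dir is not None else Path(f"fixture_{scale}")
    out_dir.mkdir(parents=True, exist_ok=True)

    variants, ld_pairs, sets = simulate_variants(config)
    paths = {"dir": out_dir}
    public = variants.drop(columns=["_block", "_rho"])
    write_variant_table(public, out_dir / "variants.tsv")
    write_ld_pairs(ld_pairs, out_dir / "ld_pairs.tsv")
    paths["variants"] = out_dir / "variants.tsv"
    paths["ld_pairs"] = out_dir / "ld_pairs.tsv"

    stats_by_trait = {}
    for trait in config.traits:
        stats = simulate_gwas(variants, config, trait, sets)
        merged = stats.merge(public[["variant_id", "chrom", "pos"]], on="variant_id")
        gwas = pd.DataFrame(
            {
                "SNP": merged["variant_id"],
                "CHR": merged["chrom"],
                "BP": merged["pos"],
                "P": merged["p"],
            }
        )
        path = out_dir / f"gwas_{trait}.tsv"
        gwas.to_csv(path, sep="\t", index=False)
        paths[f"gwas_{trait}"] = path
        stats_by_trait[trait] = stats

    # eQTL designation table: every simulated eQTL at FDR 0.01
    vt = variants.set_index("variant_id")
    rows = []
    for lab, s in sets.items():
        if not lab.startswith("eqtl:"):
            continue
        tissue = lab.removeprefix("eqtl:")
        for vid in sorted(s.variant_ids):
            rows.append(
                {
                    "SNP": vid,
                    "gene": f"gene_{vid}",
                    "tissue": tissue,
                    "tss_dist": int(vt.loc[vid, "tss_distance"]),
                    "fdr": 0.01,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "eqtl.tsv", sep="\t", index=False)
    paths["eqtl"] = out_dir / "eqtl.tsv"

    # chromatin-state BED: one 1-bp interval per annotated variant (0-based)
    bed_rows = []
    for lab, s in sets.items():
        if not lab.startswith("roadmap:"):
            continue
        cat = lab.removeprefix("roadmap:")
        for vid in sorted(s.variant_ids):
            p0 = int(vt.loc[vid, "pos"]) - 1
            bed_rows.append({"chrom": vt.loc[vid, "chrom"], "start": p0, "end": p0 + 1, "name": cat})
    pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name"]).to_csv(
        out_dir / "roadmap.bed", sep="\t", index=False, header=False
    )
    paths["bed"] = out_dir / "roadmap.bed"

    expr = simulate_expression_p(variants, config, sets)
    pd.DataFrame({"SNP": list(expr), "P_EXPR": list(expr.values())}).to_csv(
        out_dir / "expression_p.tsv", sep="\t", index=False
    )
    paths["expression_p"] = out_dir / "expression_p.tsv"

    manifest = {"scale": scale, "seed": seed, "config": _jsonable(asdict(config))}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    paths["manifest"] = out_dir / "manifest.json"
    paths["config"] = config
    paths["in_memory"] = {
        "variants": variants,
        "ld_pairs": ld_pairs,
        "sets": sets,
        "stats": stats_by_trait,
        "expression_p": expr,
    }
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
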