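"""Readers, writers and annotation-set algebra.

The central in-memory containers are plain pandas DataFrames:

* the **variant table** — one row per variant with columns
  ``variant_id, chrom, pos, maf, is_genic, tss_distance, total_ld``
  (``pos`` is 1-based; ``tss_distance`` and ``total_ld`` may be NaN);
* the **association table** — one row per (variant, trait) with columns
  ``variant_id, trait, p`` (and ``z2`` once derived, see
  :mod:`stratenrich.assoc_stats`).

Variant memberships in annotation categories (tissue eQTL sets, matched
controls, chromatin-state categories, proximal/distal) are carried by
:class:`AnnotationSet` objects rather than by wide indicator columns, so that
set algebra (consensus intersection, exclusion of multi-tissue variants,
template re-projection) stays explicit and cheap.

Coordinate conventions: variant positions are 1-based; BED intervals are
0-based half-open.  The conversion lives in exactly one place
(:func:`bed_contains`).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "maf",
    "is_genic",
    "tss_distance",
    "total_ld",
]

#: Annotation labels must either be one of these bare labels or start with
#: one of the registered prefixes.  The registry exists to catch typos such
#: as ``eqlt:adipose`` before they silently produce empty strata.
LABEL_PREFIXES = ("eqtl:", "control:", "roadmap:")
BARE_LABELS = frozenset({"proximal", "distal", "genic", "intergenic"})


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def validate_label(label: str, registry: Iterable[str] | None = None) -> str:
    """Check *label* against the annotation registry; return it unchanged."""
    if registry is not None:
        if label not in set(registry):
            raise ValueError(f"unknown annotation label {label!r} (not in registry)")
        return label
    if label in BARE_LABELS or label.startswith(LABEL_PREFIXES):
        return label
    raise ValueError(
        f"unknown annotation label {label!r}; expected one of {sorted(BARE_LABELS)} "
        f"or a prefix in {LABEL_PREFIXES}"
    )


@dataclass(frozen=True)
class AnnotationSet:
    """A named set of variant ids with free-text provenance."""

    label: str
    variant_ids: frozenset
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "variant_ids", frozenset(self.variant_ids))

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.variant_ids


def combine_sets(a: AnnotationSet, b: AnnotationSet, mode: str) -> AnnotationSet:
    """Union / intersection / difference of two annotation sets.

    ``difference`` is ``a − b``.  Provenance strings are concatenated so the
    history of consensus sets (e.g. intersections of eQTL designations at a
    matched FDR) remains inspectable.
    """
    ops = {
        "union": frozenset.union,
        "intersection": frozenset.intersection,
        "difference": frozenset.difference,
    }
    if mode not in ops:
        raise ValueError(f"unknown combine mode {mode!r}; expected one of {sorted(ops)}")
    ids = ops[mode](a.variant_ids, b.variant_ids)
    return AnnotationSet(
        label=f"{a.label}|{mode}|{b.label}",
        variant_ids=ids,
        provenance=f"{mode}({a.label}[{a.provenance}], {b.label}[{b.provenance}])",
    )


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

DEFAULT_GWAS_COLUMNS = {"variant_id": "SNP", "chrom": "CHR", "pos": "BP", "p": "P", "n": "N"}


def read_gwas(
    path,
    column_map: Mapping[str, str] | None = None,
    trait: str | None = None,
    p_floor: float = 1e-300,
) -> pd.DataFrame:
    """Read whitespace/tab-delimited GWAS summary statistics.

    Rows with a missing id, unparseable p, p < 0 or p > 1 are dropped and
    counted; p = 0 is clamped to ``p_floor`` with a warning (exact zeros in
    large GWAS exports are underflowed top hits, not errors).  Drop and clamp
    counts are stored in ``df.attrs['n_dropped']`` / ``df.attrs['n_clamped']``.
    """
    colmap = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype={colmap["variant_id"]: str})
    if df.shape[0] == 0:
        raise FormatError(f"{path}: empty GWAS file")
    for key in ("variant_id", "p"):
        if colmap[key] not in df.columns:
            raise FormatError(f"{path}: missing mandated column {colmap[key]!r}")
    out = pd.DataFrame({"variant_id": df[colmap["variant_id"]]})
    for key in ("chrom", "pos", "n"):
        if colmap.get(key) in df.columns:
            out[key] = df[colmap[key]]
    p = pd.to_numeric(df[colmap["p"]], errors="coerce")
    bad = p.isna() | (p < 0) | (p > 1) | out["variant_id"].isna()
    n_dropped = int(bad.sum())
    out = out.loc[~bad].copy()
    p = p.loc[~bad]
    n_clamped = int((p == 0).sum())
    if n_clamped:
        warnings.warn(f"{path}: clamped {n_clamped} p = 0 entries to {p_floor}")
    out["p"] = p.clip(lower=p_floor)
    out["trait"] = trait if trait is not None else Path(str(path)).stem
    out = out.reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    out.attrs["n_clamped"] = n_clamped
    if n_dropped:
        logger.info("read_gwas(%s): dropped %d malformed rows", path, n_dropped)
    return out


# ---------------------------------------------------------------------------
# eQTL tables
# ---------------------------------------------------------------------------

def read_eqtl_table(path) -> pd.DataFrame:
    """Read an eQTL designation table (SNP, gene, tissue, tss_dist, fdr)."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "gene": str, "tissue": str})
    required = {"SNP", "gene", "tissue", "tss_dist", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing eQTL columns {sorted(missing)}")
    return df


def eqtl_annotation_sets(eqtl: pd.DataFrame, fdr_max: float = 0.01) -> dict:
    """One AnnotationSet per tissue from a designation table, at ``fdr_max``."""
    kept = eqtl.loc[eqtl["fdr"] <= fdr_max]
    sets = {}
    for tissue, sub in kept.groupby("tissue"):
        label = f"eqtl:{tissue}"
        sets[label] = AnnotationSet(
            label=label,
            variant_ids=frozenset(sub["SNP"]),
            provenance=f"designation FDR <= {fdr_max}",
        )
    return sets


# ---------------------------------------------------------------------------
# BED annotations
# ---------------------------------------------------------------------------

def bed_contains(start: int, end: int, pos: int) -> bool:
    """Is a 1-based variant position inside a 0-based half-open interval?"""
    return start <= pos - 1 < end


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED4 (chrom, start, end[, name]); start > end is an error."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = ""
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"]].iloc[0]
        raise FormatError(f"{path}: interval with start > end at {bad['chrom']}:{bad['start']}")
    return df


def assign_bed_annotations(
    variants: pd.DataFrame,
    bed: pd.DataFrame,
    prefix: str = "roadmap",
    label: str | None = None,
) -> dict:
    """Assign BED intervals to variants, one AnnotationSet per track name.

    A variant at 1-based position P belongs to [start, end) iff
    start <= P-1 < end.  Intervals on chromosomes absent from the variant
    table trigger a warning and are skipped.  If *label* is given the name
    column is ignored and a single set is produced.
    """
    known_chroms = set(variants["chrom"].unique())
    unknown = sorted(set(bed["chrom"].unique()) - known_chroms)
    if unknown:
        warnings.warn(f"BED: skipping intervals on unknown chromosomes {unknown}")
        bed = bed.loc[bed["chrom"].isin(known_chroms)]

    trees: dict[tuple, IntervalTree] = {}
    names = [label] * len(bed) if label is not None else list(bed["name"])
    for (chrom, start, end), name in zip(bed[["chrom", "start", "end"]].itertuples(index=False), names):
        if start == end:  # zero-length interval contains nothing
            continue
        trees.setdefault((chrom, name), IntervalTree()).addi(start, end)

    members: dict[str, set] = {}
    by_chrom = variants.groupby("chrom", sort=False)
    for (chrom, name), tree in trees.items():
        lab = name if label is not None else f"{prefix}:{name}"
        acc = members.setdefault(lab, set())
        if chrom not in by_chrom.groups:
            continue
        sub = by_chrom.get_group(chrom)
        for vid, pos in zip(sub["variant_id"], sub["pos"]):
            if tree.overlaps_point(pos - 1):
                acc.add(vid)
    return {
        lab: AnnotationSet(label=lab, variant_ids=frozenset(ids), provenance="BED track")
        for lab, ids in members.items()
    }


# ---------------------------------------------------------------------------
# Template restriction & TSS proximity
# ---------------------------------------------------------------------------

def restrict_to_template(
    variants: pd.DataFrame,
    stats: pd.DataFrame | None,
    template: Iterable[str],
    annotation_sets: Mapping[str, AnnotationSet] | None = None,
):
    """Restrict variants, stats and annotation sets to a high-quality template.

    Returns ``(variants, stats, annotation_sets)`` with every annotation set
    re-projected onto the template.  Idempotent.  Raises if no variant
    survives.
    """
    template = frozenset(template)
    if not template:
        raise ValueError("empty template")
    keep = variants["variant_id"].isin(template)
    out_variants = variants.loc[keep].reset_index(drop=True)
    if out_variants.shape[0] == 0:
        raise ValueError("template restriction left no variants")
    universe = frozenset(out_variants["variant_id"])
    out_stats = None
    if stats is not None:
        out_stats = stats.loc[stats["variant_id"].isin(universe)].reset_index(drop=True)
    out_sets = None
    if annotation_sets is not None:
        out_sets = {
            lab: AnnotationSet(lab, s.variant_ids & universe, s.provenance)
            for lab, s in annotation_sets.items()
        }
    return out_variants, out_stats, out_sets


def assign_proximal_distal(variants: pd.DataFrame, threshold=25_000):
    """Split variants with a TSS distance into proximal/distal at *threshold*.

    ``threshold='median'`` uses the median distance so the two categories are
    equally populated (sizes differ by at most one when distances are
    distinct).  Variants without a distance get neither label.  Returns
    ``(variants_with_tss_class_column, {'proximal': set, 'distal': set},
    threshold_used)``.
    """
    dist = variants["tss_distance"]
    known = dist.notna()
    if (dist.loc[known] < 0).any():
        raise ValueError("negative distance to TSS")
    if threshold == "median":
        threshold = float(dist.loc[known].median())
    out = variants.copy()
    out["tss_class"] = pd.array([pd.NA] * len(out), dtype="string")
    out.loc[known & (dist <= threshold), "tss_class"] = "proximal"
    out.loc[known & (dist > threshold), "tss_class"] = "distal"
    prov = f"distance-to-TSS threshold {threshold} bp"
    sets = {
        "proximal": AnnotationSet(
            "proximal", frozenset(out.loc[out["tss_class"] == "proximal", "variant_id"]), prov
        ),
        "distal": AnnotationSet(
            "distal", frozenset(out.loc[out["tss_class"] == "distal", "variant_id"]), prov
        ),
    }
    return out, sets, threshold


# ---------------------------------------------------------------------------
# LD pairs, loci lists, persistence
# ---------------------------------------------------------------------------

def read_ld_pairs(path) -> pd.DataFrame:
    """Read pairwise LD (SNP_A, BP_A, SNP_B, BP_B, R2) as a sparse list."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP_A": str, "SNP_B": str})
    required = {"SNP_A", "BP_A", "SNP_B", "BP_B", "R2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing LD columns {sorted(missing)}")
    out = df.rename(
        columns={"SNP_A": "id_a", "BP_A": "pos_a", "SNP_B": "id_b", "BP_B": "pos_b", "R2": "r2"}
    )
    if ((out["r2"] < 0) | (out["r2"] > 1)).any():
        raise FormatError(f"{path}: r2 outside [0, 1]")
    return out


def write_ld_pairs(ld_pairs: pd.DataFrame, path) -> None:
    out = ld_pairs.rename(
        columns={"id_a": "SNP_A", "pos_a": "BP_A", "id_b": "SNP_B", "pos_b": "BP_B", "r2": "R2"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_loci(path) -> pd.DataFrame:
    """Read a lead-variant list (SNP, CHR, BP) for genome-wide loci."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    missing = {"SNP", "CHR", "BP"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing loci columns {sorted(missing)}")
    return df.rename(columns={"SNP": "variant_id", "CHR": "chrom", "BP": "pos"})


def write_variant_table(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False, columns=[c for c in VARIANT_COLUMNS if c in variants.columns])


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing variant-table columns {sorted(missing)}")
    df["is_genic"] = df["is_genic"].astype(bool)
    return df


def write_annotation_set(aset: AnnotationSet, path) -> None:
    payload = {
        "label": aset.label,
        "provenance": aset.provenance,
        "variant_ids": sorted(aset.variant_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotation_set(path) -> AnnotationSet:
    payload = json.loads(Path(path).read_text())
    return AnnotationSet(
        label=payload["label"],
        variant_ids=frozenset(payload["variant_ids"]),
        provenance=payload.get("provenance", ""),
    )
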