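"""Annotation overlap with LD windows around genome-wide-significant loci.

For each lead variant of a significant locus, the r² ≥ 0.8 LD window is
formed and a locus counts as overlapping when at least one annotated
variant lies in the window's member set (default) or within its spanning
base-pair interval (``mode='interval'``).  The overlap fraction k/n is
contrasted with the genome-wide fraction K/N of independent loci
represented by the annotation; the printed enrichment ratio is the ratio of
proportions (K/N) ÷ (k/n), with the odds-ratio variant and the reciprocal
also emitted, and a two-sided Fisher exact p on the 2×2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ld_ops import ld_window


@dataclass
class OverlapResult:
    """Locus-overlap counts, enrichment ratios and exact-test p."""

    n_loci: int
    k_overlapping: int
    baseline_fraction: float  # K/N
    overlap_fraction: float  # k/n
    enrichment_ratio: float  # (K/N) / (k/n); NaN when k = 0
    reciprocal_ratio: float  # (k/n) / (K/N)
    odds_ratio: float
    fisher_p: float
    detail: pd.DataFrame | None = None


def overlap_loci(
    loci: pd.DataFrame,
    annotation,
    variants: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    r2_min: float = 0.8,
    mode: str = "members",
) -> pd.DataFrame:
    """Per-locus overlap detail: one row per (locus, annotated variant) hit.

    ``loci`` needs columns variant_id/chrom/pos for the lead variants; every
    lead must resolve in the variant table.  Returns a frame with columns
    lead_id, chrom, lead_pos, variant_id (annotated member).  A lead that is
    itself annotated counts as overlapping.
    """
    if mode not in ("members", "interval"):
        raise ValueError("mode must be 'members' or 'interval'")
    ann_ids = frozenset(getattr(annotation, "variant_ids", annotation))
    vt = variants.set_index("variant_id")
    rows = []
    for lead, chrom, pos in loci[["variant_id", "chrom", "pos"]].itertuples(index=False):
        win = ld_window(lead, variants, ld_pairs, r2_min=r2_min)  # raises if unresolvable
        if mode == "members":
            hits = sorted(win.members & ann_ids)
        else:
            in_ann = vt.loc[vt.index.isin(ann_ids)]
            on = in_ann.loc[
                (in_ann["chrom"] == win.chrom)
                & (in_ann["pos"] >= win.start)
                & (in_ann["pos"] <= win.end)
            ]
            hits = sorted(on.index)
        for h in hits:
            rows.append({"lead_id": lead, "chrom": chrom, "lead_pos": pos, "variant_id": h})
    return pd.DataFrame(rows, columns=["lead_id", "chrom", "lead_pos", "variant_id"])


def enrichment_ratio(k: int, n: int, K: int, N: int, detail: pd.DataFrame | None = None) -> OverlapResult:
    """Summary from overlap counts k/n and baseline representation K/N.

    The ratio of proportions is scale-invariant in (k, n) and (K, N); the
    Fisher p comes from the two-sided exact test on [[k, n−k], [K, N−K]].
    k = 0 leaves the ratio undefined (NaN) rather than failing.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < K <= N):
        raise ValueError("need 0 < K <= N")
    overlap_frac = k / n
    baseline_frac = K / N
    ratio = baseline_frac / overlap_frac if k > 0 else float("nan")
    reciprocal = overlap_frac / baseline_frac
    table = np.array([[k, n - k], [K, N - K]])
    odds, fisher_p = sps.fisher_exact(table, alternative="two-sided")
    # fisher_exact's odds ratio is for the table as given; report baseline/overlap odds
    odds_ratio = (
        (K / (N - K)) / (k / (n - k)) if (0 < k < n and K < N) else float("nan")
    )
    return OverlapResult(
        n_loci=int(n),
        k_overlapping=int(k),
        baseline_fraction=baseline_frac,
        overlap_fraction=overlap_frac,
        enrichment_ratio=ratio,
        reciprocal_ratio=reciprocal,
        odds_ratio=odds_ratio,
        fisher_p=float(fisher_p),
        detail=detail,
    )


def locus_overlap_analysis(
    loci: pd.DataFrame,
    annotation,
    variants: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    K: int,
    N: int,
    r2_min: float = 0.8,
    mode: str = "members",
) -> OverlapResult:
    """End-to-end locus-overlap test: window intersection then 2×2 summary."""
    detail = overlap_loci(loci, annotation, variants, ld_pairs, r2_min=r2_min, mode=mode)
    k = detail["lead_id"].nunique() if len(detail) else 0
    return enrichment_ratio(k=k, n=len(loci), K=K, N=N, detail=detail)


def significant_loci(
    stats: pd.DataFrame,
    variants: pd.DataFrame,
    p_threshold: float = 5e-8,
    min_separation_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Greedy LD-independent lead list: best p first, one lead per window.

    A helper for synthetic runs (real studies publish their locus lists):
    variants passing the significance threshold are scanned in order of
    increasing p and a variant becomes a lead unless a previously chosen
    lead lies within ``min_separation_bp`` on the same chromosome.
    """
    vt = variants.set_index("variant_id")
    hits = stats.loc[stats["p"] <= p_threshold].sort_values("p")
    leads = []
    for vid in hits["variant_id"]:
        if vid not in vt.index:
            continue
        chrom, pos = vt.loc[vid, "chrom"], int(vt.loc[vid, "pos"])
        if all(c != chrom or abs(pos - p0) > min_separation_bp for _, c, p0 in leads):
            leads.append((vid, chrom, pos))
    return pd.DataFrame(leads, columns=["variant_id", "chrom", "pos"])
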