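"""Total LD scores, random LD-based pruning replicates, and LD windows.

Pruning is the project's answer to the non-independence of annotated
variants: rather than analysing one arbitrary set of LD-independent
representatives, ten maximal near-independent subsets are drawn under fresh
random orderings and every downstream model is fitted on each.  A missing
pair in the sparse LD list is treated as r² = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PruneReplicates:
    """Near-independent variant-id subsets with the seeds that produced them."""

    sets: list  # list[frozenset[str]]
    seeds: list  # per-replicate integer seeds, recorded for exact replay
    r2_max: float
    window_bp: int
    disjoint: bool = False

    @property
    def n_sets(self) -> int:
        return len(self.sets)


def _pair_distances(ld_pairs: pd.DataFrame, variants: pd.DataFrame) -> np.ndarray:
    """Base-pair distance for each pair; inf when on different chromosomes."""
    chrom = variants.set_index("variant_id")["chrom"]
    pos = variants.set_index("variant_id")["pos"]
    ca = chrom.reindex(ld_pairs["id_a"]).to_numpy()
    cb = chrom.reindex(ld_pairs["id_b"]).to_numpy()
    pa = pos.reindex(ld_pairs["id_a"]).to_numpy(dtype=float)
    pb = pos.reindex(ld_pairs["id_b"]).to_numpy(dtype=float)
    dist = np.abs(pa - pb)
    dist[ca != cb] = np.inf
    return dist


def total_ld_score(
    variants: pd.DataFrame, ld_pairs: pd.DataFrame, window_bp: int = 1_000_000
) -> pd.Series:
    """Total LD score per variant: 1 + Σ r² over partners within the window.

    The self-count of 1 follows the conventional LD-score definition; a
    variant with no partners scores exactly 1.
    """
    score = pd.Series(1.0, index=pd.Index(variants["variant_id"], name="variant_id"))
    if len(ld_pairs) == 0:
        return score
    dist = _pair_distances(ld_pairs, variants)
    ok = dist <= window_bp
    pairs = ld_pairs.loc[ok]
    contrib_a = pairs.groupby("id_a")["r2"].sum()
    contrib_b = pairs.groupby("id_b")["r2"].sum()
    score = score.add(contrib_a.reindex(score.index, fill_value=0.0), fill_value=0.0)
    score = score.add(contrib_b.reindex(score.index, fill_value=0.0), fill_value=0.0)
    return score


def build_conflict_graph(
    variants: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    r2_max: float = 0.2,
    window_bp: int = 1_000_000,
):
    """Adjacency over variant indices for pairs with r² ≥ r2_max within window.

    Returns ``(ids, neighbors)`` where ``neighbors[i]`` is an int array of the
    conflicting partners of variant ``ids[i]``.  Reusable across replicates
    and simulations sharing a variant map.
    """
    ids = variants["variant_id"].to_numpy()
    index = pd.Series(np.arange(len(ids)), index=ids)
    n = len(ids)
    if len(ld_pairs) == 0:
        return ids, [np.empty(0, dtype=np.int64)] * n
    dist = _pair_distances(ld_pairs, variants)
    conflict = (ld_pairs["r2"].to_numpy() >= r2_max) & (dist <= window_bp)
    a = index.reindex(ld_pairs.loc[conflict, "id_a"]).to_numpy()
    b = index.reindex(ld_pairs.loc[conflict, "id_b"]).to_numpy()
    src = np.concatenate([a, b]).astype(np.int64)
    dst = np.concatenate([b, a]).astype(np.int64)
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    bounds = np.searchsorted(src, np.arange(n + 1))
    neighbors = [dst[bounds[i] : bounds[i + 1]] for i in range(n)]
    return ids, neighbors


def random_prune(
    variants: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    r2_max: float = 0.2,
    window_bp: int = 1_000_000,
    n_sets: int = 10,
    seed: int = 0,
    disjoint: bool = False,
    graph=None,
) -> PruneReplicates:
    """Draw ``n_sets`` maximal near-independent variant subsets at random.

    Each replicate draws a fresh permutation and greedily retains a variant
    iff no already-retained variant within ``window_bp`` has r² ≥ ``r2_max``
    with it; the result is a maximal independent set of the conflict graph
    under that ordering.  Sampling within a replicate is without replacement;
    replicates are independent draws and may overlap.  With
    ``disjoint=True`` each replicate additionally excludes variants retained
    by earlier replicates (the alternative reading of "no replacement";
    later replicates then shrink and may be empty on small universes).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    ids, neighbors = graph if graph is not None else build_conflict_graph(
        variants, ld_pairs, r2_max=r2_max, window_bp=window_bp
    )
    n = len(ids)
    master = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_sets)]
    sets = []
    used = np.zeros(n, dtype=bool)  # only consulted when disjoint
    for rep_seed in rep_seeds:
        rng = np.random.default_rng(rep_seed)
        order = rng.permutation(n)
        blocked = used.copy() if disjoint else np.zeros(n, dtype=bool)
        keep = np.zeros(n, dtype=bool)
        for v in order:
            if not blocked[v]:
                keep[v] = True
                nb = neighbors[v]
                if nb.size:
                    blocked[nb] = True
        if disjoint:
            used |= keep
        sets.append(frozenset(ids[keep]))
    return PruneReplicates(
        sets=sets, seeds=rep_seeds, r2_max=r2_max, window_bp=window_bp, disjoint=disjoint
    )


@dataclass
class LdWindow:
    """The r²-qualified neighborhood of a lead variant."""

    lead: str
    chrom: str
    start: int
    end: int
    members: frozenset


def ld_window(
    lead: str,
    variants: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    r2_min: float = 0.8,
) -> LdWindow:
    """Members = lead ∪ {variants with r² ≥ r2_min to the lead} (inclusive).

    The interval spans min..max position of members on the lead's chromosome;
    a lead with no qualifying partner yields a zero-length interval at its
    own position.
    """
    vt = variants.set_index("variant_id")
    if lead not in vt.index:
        raise ValueError(f"lead variant {lead!r} not in variant table")
    members = {lead}
    if len(ld_pairs):
        hit_a = ld_pairs.loc[(ld_pairs["id_a"] == lead) & (ld_pairs["r2"] >= r2_min), "id_b"]
        hit_b = ld_pairs.loc[(ld_pairs["id_b"] == lead) & (ld_pairs["r2"] >= r2_min), "id_a"]
        members |= set(hit_a) | set(hit_b)
    chrom = vt.loc[lead, "chrom"]
    on_chrom = [m for m in members if m in vt.index and vt.loc[m, "chrom"] == chrom]
    positions = [int(vt.loc[m, "pos"]) for m in on_chrom]
    return LdWindow(
        lead=lead,
        chrom=str(chrom),
        start=min(positions),
        end=max(positions),
        members=frozenset(members),
    )


def save_replicates(reps: PruneReplicates, out_dir) -> None:
    """One id-list file per replicate plus a manifest with seeds and params."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(reps.sets):
        (out_dir / f"replicate_{i:02d}.txt").write_text("\n".join(sorted(s)) + "\n")
    manifest = {
        "n_sets": reps.n_sets,
        "seeds": reps.seeds,
        "r2_max": reps.r2_max,
        "window_bp": reps.window_bp,
        "disjoint": reps.disjoint,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_replicates(in_dir) -> PruneReplicates:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    sets = []
    for i in range(manifest["n_sets"]):
        text = (in_dir / f"replicate_{i:02d}.txt").read_text().strip()
        sets.append(frozenset(text.split("\n")) if text else frozenset())
    return PruneReplicates(
        sets=sets,
        seeds=manifest["seeds"],
        r2_max=manifest["r2_max"],
        window_bp=manifest["window_bp"],
        disjoint=manifest.get("disjoint", False),
    )
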