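"""p ↔ χ² conversion and intergenic genomic control (median of medians).

A two-sided p-value maps to a 1-df chi-squared statistic through
z² = (Φ⁻¹(p/2))², i.e. the square of the normal quantile of the half
p-value.  Genomic control estimates the inflation factor λ as the median of
the per-replicate medians of intergenic χ², divided by the null χ²₁ median
m₀ ≈ 0.4549; all statistics are divided by λ (and p regenerated) before any
enrichment modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


def chi1_median() -> float:
    """Median m₀ of the 1-df chi-squared distribution (≈ 0.454936)."""
    return float(sps.chi2.ppf(0.5, df=1))


def chisq_from_p(p):
    """χ² (1 df) from a two-sided p-value in (0, 1]; strictly decreasing."""
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    out = sps.chi2.isf(arr, df=1)  # == (Phi^-1(p/2))**2
    return float(out) if np.isscalar(p) else out


def p_from_chisq(z2):
    """Two-sided p from a 1-df chi-squared statistic (inverse of chisq_from_p)."""
    arr = np.asarray(z2, dtype=float)
    if np.any(arr < 0):
        raise ValueError("chi-squared statistics must be >= 0")
    out = sps.chi2.sf(arr, df=1)
    return float(out) if np.isscalar(z2) else out


def add_chisq(stats: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the association table with a ``z2`` column."""
    out = stats.copy()
    out["z2"] = chisq_from_p(out["p"].to_numpy())
    return out


@dataclass
class GcFactor:
    """Genome-wide intergenic correction factor with its provenance."""

    lambda_gc: float
    per_replicate_medians: list
    n_intergenic_per_replicate: list
    m0: float = field(default_factory=chi1_median)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "lambda_gc": self.lambda_gc,
                    "per_replicate_medians": self.per_replicate_medians,
                    "n_intergenic_per_replicate": self.n_intergenic_per_replicate,
                    "m0": self.m0,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "GcFactor":
        d = json.loads(Path(path).read_text())
        return cls(
            lambda_gc=d["lambda_gc"],
            per_replicate_medians=d["per_replicate_medians"],
            n_intergenic_per_replicate=d["n_intergenic_per_replicate"],
            m0=d["m0"],
        )


def gc_lambda(stats: pd.DataFrame, variants: pd.DataFrame, replicates) -> GcFactor:
    """λ from the median-of-medians of intergenic χ² across pruning replicates.

    Per replicate, the median χ² over its intergenic members is taken; λ is
    the median of those per-replicate medians divided by the null median m₀.
    A replicate without any intergenic variant is an error (the correction
    would be undefined for it).
    """
    if "z2" not in stats.columns:
        stats = add_chisq(stats)
    z2 = stats.set_index("variant_id")["z2"]
    intergenic = frozenset(variants.loc[~variants["is_genic"].astype(bool), "variant_id"])
    medians, counts = [], []
    for i, rep in enumerate(replicates.sets):
        ids = [v for v in rep & intergenic if v in z2.index]
        if not ids:
            raise ValueError(f"replicate {i} contains no intergenic variants")
        vals = z2.loc[ids].to_numpy()
        medians.append(float(np.median(vals)))
        counts.append(len(vals))
    lam = float(np.median(medians) / chi1_median())
    return GcFactor(lambda_gc=lam, per_replicate_medians=medians, n_intergenic_per_replicate=counts)


def apply_gc(stats: pd.DataFrame, gc: GcFactor) -> pd.DataFrame:
    """Divide every χ² by λ and regenerate p-values from the corrected χ².

    Rank order of p-values is preserved; λ = 1 is an exact no-op on χ² (p is
    still regenerated from χ², which round-trips to numerical tolerance).
    """
    if gc.lambda_gc <= 0:
        raise ValueError("lambda_gc must be > 0")
    if "z2" not in stats.columns:
        stats = add_chisq(stats)
    out = stats.copy()
    out["z2"] = out["z2"].to_numpy() / gc.lambda_gc
    out["p"] = p_from_chisq(out["z2"].to_numpy())
    return out
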