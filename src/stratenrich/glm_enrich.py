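"""Chi-squared general linear models on pruning replicates, with meta-analysis.

The response is the (genomic-control-corrected) 1-df association χ²; the
design holds 0/1 annotation indicators (tissue eQTL sets, matched controls,
chromatin-state categories, proximal/distal), the continuous total LD score,
and optional pairwise interactions (eQTL × chromatin category, eQTL × total
LD).  Each pruning replicate is fitted by ordinary least squares (Gaussian
family, identity link — the χ² response is heteroskedastic; classical SEs
are reported by default, with an HC1 robust option) and the ten fits are
combined by fixed-effect inverse-variance meta-analysis.

The meta-analysis deliberately ignores the correlation between overlapping
replicates, so meta p-values are anti-conservative; see docs/methods.md.
The replicate mean β̄ is reported alongside the inverse-variance pooled
estimate, which can differ when per-replicate SEs differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

TOTAL_LD_TERM = "total_ld"
SCOPES = ("full", "eqtl_controls")


@dataclass(frozen=True)
class DesignSpec:
    """Which covariates and interactions enter the χ² linear model."""

    terms: tuple
    interactions: tuple = ()
    scope: str = "full"
    center_ld: bool = False

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in design")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ValueError(f"interaction ({a}, {b}) references undeclared main terms")


def interaction_name(a: str, b: str) -> str:
    return f"{a}:{b}"


def _membership(term: str, sets: Mapping, ids: pd.Index) -> np.ndarray:
    if term not in sets:
        raise KeyError(f"term {term!r} has no annotation set")
    members = sets[term]
    members = getattr(members, "variant_ids", members)
    return ids.isin(members).astype(float)


def build_design(
    variants: pd.DataFrame,
    stats: pd.DataFrame,
    replicate_ids,
    spec: DesignSpec,
    sets: Mapping,
):
    """Design matrix and χ² response for one pruning replicate.

    Rows are the replicate's variants present in both tables; with scope
    ``eqtl_controls`` only variants carrying any ``eqtl:`` or ``control:``
    label in *sets* are retained (matched controls are then the reference
    level).  Indicator terms come from annotation sets; ``total_ld`` is the
    continuous LD score, optionally centered.  A term constant within the
    replicate is an error naming the term.
    """
    rep = frozenset(replicate_ids)
    vt = variants.loc[variants["variant_id"].isin(rep)].set_index("variant_id")
    z2 = stats.set_index("variant_id")["z2"]
    ids = vt.index.intersection(z2.index)
    if spec.scope == "eqtl_controls":
        in_scope = frozenset()
        for lab, s in sets.items():
            if lab.startswith(("eqtl:", "control:")):
                in_scope |= frozenset(getattr(s, "variant_ids", s))
        ids = ids[ids.isin(in_scope)]
    if len(ids) == 0:
        raise ValueError("empty design: no replicate variants in scope")
    vt = vt.loc[ids]

    X = pd.DataFrame(index=ids)
    for term in spec.terms:
        if term == TOTAL_LD_TERM:
            col = vt["total_ld"].to_numpy(dtype=float)
            if spec.center_ld:
                col = col - col.mean()
            X[term] = col
        else:
            X[term] = _membership(term, sets, ids)
    for a, b in spec.interactions:
        X[interaction_name(a, b)] = X[a].to_numpy() * X[b].to_numpy()
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if constant:
        raise ValueError(f"degenerate (constant) design columns within replicate: {constant}")
    y = z2.loc[ids].to_numpy(dtype=float)
    return X, y


def fit_chisq_glm(X: pd.DataFrame, y, robust: bool = False) -> pd.DataFrame:
    """OLS fit of χ² on the design; per-term (β, SE, p) from t statistics."""
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more rows than design columns")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(f"rank-deficient design; collinear among terms {list(X.columns)}")
    res = sm.OLS(y, Xc).fit(cov_type="HC1" if robust else "nonrobust")
    out = pd.DataFrame(
        {
            "term": Xc.columns,
            "beta": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    out["n"] = int(X.shape[0])
    return out


@dataclass
class EnrichmentFit:
    """Per-term replicate coefficients plus meta-analyzed summaries.

    ``table`` columns: term, beta_bar (plain mean over replicates), beta_iv
    (inverse-variance pooled), se_meta, ci_low, ci_high (95% around
    beta_iv), p (meta), n_replicates.  ``replicate_betas``/``replicate_ses``
    are term × replicate frames; ``n_per_replicate`` lists design rows.
    """

    table: pd.DataFrame
    replicate_betas: pd.DataFrame
    replicate_ses: pd.DataFrame
    n_per_replicate: list = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        row = self.table.loc[self.table["term"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r} in fit")
        return row.iloc[0]


def meta_analyze(replicate_fits: Sequence[pd.DataFrame]) -> EnrichmentFit:
    """Fixed-effect inverse-variance combination of per-replicate (β, SE).

    β̄ is the arithmetic mean of replicate coefficients (the headline effect
    size); the meta SE, 95% CI and p come from the pooled inverse-variance
    estimate.  Every replicate must report every term.
    """
    if len(replicate_fits) == 0:
        raise ValueError("no replicate fits to combine")
    terms = list(replicate_fits[0]["term"])
    for i, fit in enumerate(replicate_fits):
        if list(fit["term"]) != terms:
            missing = set(terms) ^ set(fit["term"])
            raise ValueError(f"replicate {i} term mismatch: {sorted(missing)}")
    betas = pd.DataFrame(
        {i: fit.set_index("term")["beta"] for i, fit in enumerate(replicate_fits)}
    ).loc[terms]
    ses = pd.DataFrame(
        {i: fit.set_index("term")["se"] for i, fit in enumerate(replicate_fits)}
    ).loc[terms]
    w = 1.0 / ses.to_numpy() ** 2
    beta_iv = (w * betas.to_numpy()).sum(axis=1) / w.sum(axis=1)
    se_meta = np.sqrt(1.0 / w.sum(axis=1))
    z = beta_iv / se_meta
    p = 2.0 * sps.norm.sf(np.abs(z))
    crit = sps.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "term": terms,
            "beta_bar": betas.mean(axis=1).to_numpy(),
            "beta_iv": beta_iv,
            "se_meta": se_meta,
            "ci_low": beta_iv - crit * se_meta,
            "ci_high": beta_iv + crit * se_meta,
            "p": p,
            "n_replicates": len(replicate_fits),
        }
    )
    return EnrichmentFit(
        table=table,
        replicate_betas=betas,
        replicate_ses=ses,
        n_per_replicate=[int(fit["n"].iloc[0]) for fit in replicate_fits],
    )


def fit_on_replicates(
    variants: pd.DataFrame,
    stats: pd.DataFrame,
    replicates,
    spec: DesignSpec,
    sets: Mapping,
    robust: bool = False,
) -> EnrichmentFit:
    """Fit the model on every pruning replicate and meta-analyze."""
    fits = []
    for rep in replicates.sets:
        X, y = build_design(variants, stats, rep, spec, sets)
        fits.append(fit_chisq_glm(X, y, robust=robust))
    return meta_analyze(fits)


def interaction_scan(
    variants: pd.DataFrame,
    stats: pd.DataFrame,
    replicates,
    base_spec: DesignSpec,
    sets: Mapping,
    eqtl_term: str,
    partner_terms: Sequence[str],
    robust: bool = False,
) -> EnrichmentFit:
    """Add eQTL × partner interactions to the base model and refit.

    ``partner_terms`` are typically the chromatin-state categories plus
    ``total_ld``; main effects are retained, and any partner missing from
    the base terms is added.  With an empty partner list the output is the
    plain base fit.
    """
    terms = list(base_spec.terms)
    if eqtl_term not in terms:
        terms.append(eqtl_term)
    for t in partner_terms:
        if t not in terms:
            terms.append(t)
    interactions = tuple(base_spec.interactions) + tuple(
        (eqtl_term, t) for t in partner_terms
    )
    spec = replace(base_spec, terms=tuple(terms), interactions=interactions)
    return fit_on_replicates(variants, stats, replicates, spec, sets, robust=robust)
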