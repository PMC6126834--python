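"""Chi-squared GLM enrichment with LD-pruning replicas and meta-analysis.

Simulates a 0.2 E[chi2]-scale eQTL effect, draws ten random LD-pruned
near-independent variant sets, applies intergenic genomic control, fits the
chi-squared linear model (eQTL + control indicators + total LD) on each
replica and meta-analyzes.  The eQTL coefficient should recover ~0.20; the
matched-control coefficient should sit near 0.
"""

import stratenrich as se
from stratenrich.glm_enrich import DesignSpec, fit_on_replicates

cfg = se.SimConfig(n_variants=50_000, block_size=20, beta={"eqtl": 0.20},
                   lambda_gc=1.1, seed=42)
variants, ld_pairs, sets = se.simulate_variants(cfg)
stats = se.add_chisq(se.simulate_gwas(variants, cfg, sets=sets))

sets = dict(sets)
sets["eqtl:all"] = se.AnnotationSet(
    "eqtl:all",
    frozenset().union(*[s.variant_ids for l, s in sets.items() if l.startswith("eqtl:")]),
)
sets["control:all"] = se.match_controls(sets["eqtl:all"], variants, seed=0,
                                        label="control:all").controls

replicates = se.random_prune(variants, ld_pairs, n_sets=10, seed=42)
gc = se.gc_lambda(stats, variants, replicates)
print(f"genomic inflation: true lambda = {cfg.lambda_gc}, estimated = {gc.lambda_gc:.3f}")
corrected = se.apply_gc(stats, gc)

spec = DesignSpec(terms=("eqtl:all", "control:all", "total_ld"), scope="full")
fit = fit_on_replicates(variants, corrected, replicates, spec, sets)
print("\nterm         beta_bar   95% CI            meta p")
for term in ("eqtl:all", "control:all", "total_ld"):
    row = fit.term(term)
    print(f"{term:12s} {row['beta_bar']:8.3f}   [{row['ci_low']:6.3f}, {row['ci_high']:6.3f}]  {row['p']:.2e}")
print("\nbeta_bar is the mean coefficient over the ten pruning replicas;")
print("the eQTL term estimates the excess association chi-squared carried by")
print("eQTLs after adjusting for matched controls and LD-tagging power.")
print("Meta p-values ignore replica overlap and are anti-conservative.")
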