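"""Edge-wise ACTE heritability on a simulated twin + sibling cohort.

Simulates 117 MZ twin pairs (69 with a non-twin sibling) and 60 DZ pairs
(48 with a sibling), with 30 edge phenotypes generated at h2 = 0.6, fits
the ACTE/ACE/AE/CE/E model family to every edge, and reports the AIC-best
model and the recovered narrow-sense heritability.
"""

import numpy as np

import hubwire

spec = hubwire.TwinSimSpec(a2=0.6, c2=0.05, t2=0.0, e2=0.35, seed=42)
cohort = hubwire.simulate_twin_cohort(spec, n_edges=30)
results, proportions = hubwire.edgewise_heritability(cohort, seed=0)

print(f"cohort: {len(cohort.subjects)} subjects in "
      f"{cohort.subjects.family_id.nunique()} families")
print(f"\nbest-model proportions: "
      + ", ".join(f"{m}: {p:.2f}" for m, p in proportions.items() if p > 0))
print(f"mean best-model h2:  {results.h2.mean():.3f}  (generated at 0.60)")
print(f"mean full-ACTE h2:   {results.h2_acte.mean():.3f}")
print(f"mean outliers/edge:  {results.n_outliers.mean():.1f} "
      f"(Tukey fences at 1.5 IQR)")
print("\nfirst edges:")
print(results[["edge", "best_model", "h2", "e2", "aic", "n_used"]].head(8).to_string(index=False))
print(
    "\nThe AE model dominates because the data carry additive-genetic and "
    "unique-environment variance; h2 is the standardized A of the best model."
)
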