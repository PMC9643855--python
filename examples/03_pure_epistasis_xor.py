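"""Detect pure epistasis that single-SNP analysis cannot see.

Simulates a case-control cohort from an XOR penetrance model: disease risk
0.6 when exactly one of two loci is heterozygous, 0.1 otherwise. At MAF 0.5
neither locus has any marginal effect, yet the pair is strongly predictive
— the canonical benchmark for MDR.
"""

import numpy as np

from cytomdr import (
    CohortSpec,
    crude_model_scan,
    marginal_counts,
    search_best_models,
    simulate_cohort,
    xor_penetrance,
)

model = xor_penetrance("snpA", "snpB", p_high=0.6, p_low=0.1)
print(f"population prevalence at MAF 0.5: {model.prevalence([0.5, 0.5]):.3f}")

spec = CohortSpec(
    n_cases=400,
    n_controls=400,
    mafs={"snpA": 0.5, "snpB": 0.5, "noise1": 0.3, "noise2": 0.3, "noise3": 0.3},
    seed=7,
)
ds = simulate_cohort(spec, model=model)

print("\nsingle-SNP allelic odds ratios (should hover around 1):")
for snp in ("snpA", "snpB"):
    res = [r for r in crude_model_scan(marginal_counts(ds, snp))
           if r.model == "additive"][0]
    print(f"  {snp}: OR {res.or_value:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f})")

result = search_best_models(ds, k_min=1, k_max=2, rng=np.random.default_rng(8))
m1, m2 = result.models[1], result.models[2]
print(f"\nbest 1-locus model: {m1.snps}, test BA {m1.test_balanced_accuracy:.3f}")
print(f"best 2-locus model: {m2.snps}, test BA {m2.test_balanced_accuracy:.3f}, "
      f"consistency {m2.cv_consistency}/10")

# The 1-locus accuracy stays near chance (0.5) while the causal pair jumps
# to ~0.75: the interaction carries all the signal.
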