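"""Generate a synthetic biobank-like cohort and inspect its composition.

Builds a seeded 10,000-patient cohort with latent diabetes archetypes and
curated-phenotype ML flags, then prints the latent composition and the
empirical flag rates.  The ML-T2D flag rate should land near 6.2% of the
cohort — the composition the screening algorithms were designed against.
"""

from collections import Counter

from adscreen import default_config, generate_cohort

cohort, truth = generate_cohort(default_config(n_patients=10_000, seed=1))

print(f"cohort: {len(cohort)} patients ({cohort.provenance})")
print("\nlatent archetype composition:")
for name, count in Counter(truth.values()).most_common():
    print(f"  {name.value:<12} {count:>6}  ({100 * count / len(cohort):.2f}%)")

n_t2d_flag = sum(p.ml_flags.ml_t2d for p in cohort.patients)
n_t1d_flag = sum(p.ml_flags.ml_t1d_high_ppv for p in cohort.patients)
print(f"\nML T2D flag: {n_t2d_flag} ({100 * n_t2d_flag / len(cohort):.2f}%)"
      " <- the screening input population")
print(f"ML T1D flag: {n_t1d_flag} ({100 * n_t1d_flag / len(cohort):.2f}%)")
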