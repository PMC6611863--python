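"""Parental-origin phasing of candidate mosaic DNMs.

Generates read-pair co-observations linking each mosaic DNM to a nearby
inherited informative SNV, assigns each DNM to the maternal or paternal
haplotype, and tests the origin ratio against the 50:50 expectation for
mutations arising in the early embryo.
"""

from triomosaic.phasing import Origin, assign_parental_origin, paternal_fraction
from triomosaic.simulate import SimulationConfig, simulate_read_pairs, simulate_trio_cohort

mosaic_only = {c: 0.0 for c in (
    "constitutive_dnm", "parent_mosaic_low", "parent_mosaic_high",
    "false_positive", "constitutive_inherited")}
mosaic_only["child_mosaic"] = 1.0
cfg = SimulationConfig(n_candidate_dnms=300, class_mix=mosaic_only)

_, truth = simulate_trio_cohort(cfg, seed=4)
read_pairs = simulate_read_pairs(truth, n_pairs_per_site=30, switch_error=0.0, seed=5)
true_origin = dict(zip(truth.table.site_id, truth.table.true_parental_origin))

results, correct = [], 0
n_three_hap = 0
for site_id, (obs, info) in read_pairs.items():
    res = assign_parental_origin(obs, info, min_support=3)
    if res.origin is Origin.UNKNOWN:
        continue
    results.append(res)
    n_three_hap += res.three_haplotype
    correct += res.origin.value == true_origin[site_id]

frac = paternal_fraction(results)
print(f"phased {len(results)}/{len(read_pairs)} mosaic sites "
      f"({correct} match the generating origin; "
      f"{n_three_hap} show the three-haplotype pattern)")
print(f"paternal:maternal = {frac['n_paternal']}:{frac['n_maternal']} "
      f"(fraction paternal {frac['fraction_paternal']:.2f}, "
      f"binomial p vs 0.5 = {frac['binomial_p_vs_half']:.2f})")
print("A p-value near 1 is consistent with the 50:50 parental-origin ratio "
      "expected for postzygotic mutations arising before sexual differentiation.")
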