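# Methods

## Model

A variant present in a fraction *f* of a person's (diploid, autosomal)
cells is sequenced at expected VAF *f*/2; a constitutive heterozygote
has expected VAF 0.5. Read sampling is modelled as binomial:
`alt ~ Binomial(depth, v)` with `v` the expected VAF, and `v` equal to
the per-base error rate at non-carrier sites. All screening statistics
derive from this model; overdispersion (e.g. beta-binomial) is
deliberately not modelled — at exome depths (~50X) the binomial noise
dominates, and the ultra-deep classifier guards against
over-rejection differently (below).

## Screens and their thresholds

* **Child-PZM.** Candidate DNMs (MAF < 0.01, proband VAF > 0.1,
  X/Y excluded in males) are tested with the exact lower-tail binomial
  p against VAF 0.5 and selected by Benjamini–Hochberg FDR within two
  arms: likely-pathogenic (LOF/functional consequence in dominant
  DDG2P context, FDR < 0.2) and synonymous non-DDG2P controls
  (FDR < 0.05). The lower tail is used because mosaicism in the
  sequenced tissue can only depress VAF; the two-sided exact test is
  exposed for completeness. BH is applied within each arm separately:
  the arms answer different questions (diagnosis versus an unbiased
  rate estimate) and mixing their p-value universes would couple their
  error rates. The VAF > 0.1 floor reflects that at ~50X,
  lower-VAF candidates are dominated by sequencing error.
* **Low-level parent-PZM.** Within the likely-pathogenic DNM arm,
  sites where exactly one parent shows ≥ 1 alternative read (and the
  other none) are selected; ≥ 2 reads predicts genuine parental
  mosaicism, since one read at ~50X is usually error. "Any reads in
  one parent" is read as *exactly one* parent because sites with
  mutant reads in both parents are handled by the inherited analysis.
* **High-level parent-PZM.** Rare (MAF < 0.001) inherited heterozygous
  LOF/functional variants in dominant DDG2P context, with proband VAF
  in [0.3, 0.7], unaffected parents and a single carrier parent
  (genotype call when present, else ≥ 2 alt reads), are selected by the
  union of three strategies: BH FDR < 0.1 on the carrier parent's
  lower-tail binomial p; protein-truncating or known-pathogenic with
  parental VAF < 0.4; shared by an affected sibling with parental
  VAF < 0.4. A candidate carries every strategy tag it satisfies.
* **Rule-based predictor.** `0.1 < VAF < 0.27 or p < 1e-4`, both ends
  of the VAF band open. VAF is depth-blind but sensitive; the binomial
  p adds depth-aware specificity.
* **Stringency calibration.** Synonymous DNMs are assumed neutral, so
  an observed excess over a null mutation-model expectation measures
  false-positive load. `calibrate_stringency` returns the smallest
  call-quality threshold at which the surviving synonymous count drops
  to the expectation (−∞ when no filtering is needed; ties resolved
  towards keeping fewer records, by scanning observed score values and
  returning just above the maximum when even that keeps too many).

## Ultra-deep validation classification

At ~100,000x depth the standard error of a VAF estimate is ~0.002, so
exact binomial tests separate the hypotheses sharply. Per
person/tissue: *present* if the one-sided exceedance test against the
error rate (default 0.005/base) rejects at alpha (default 1e-6, chosen
so that ~10⁵-deep tests have negligible familywise error over a
cohort's validations); *constitutive-compatible* if the two-sided test
against 0.5 does not reject **or** the VAF lies in [0.42, 0.58]. The
guard band is an effect-size criterion: at extreme depth the exact
test rejects for biologically meaningless deviations (VAF 0.497), while
genuinely mosaic validated VAFs (0.04–0.39) fall far outside it. Trio
outcomes follow: proband absent → false positive; proband
mosaic/constitutive with silent parents → mosaic/constitutive DNM; one
sub-constitutive present parent under a constitutive proband →
parent-mosaic; both compatible → constitutive inherited. Observations
below 1,000x, contradictory proband tissues, and residual ambiguous
combinations are uninformative. Confusion metrics leave zero-denominator
ratios missing rather than zero.

## Mixture model

`fit_vaf_mixture` is a two-component 1-D Gaussian EM on VAFs above a
floor (default 0.1, matching the candidate-set definition). The
constitutive mean is initialised at 0.5 and constrained to
[0.45, 0.55]; the mosaic mean is free in (floor, 0.45). The anchoring
fixes component identity, so no relabelling step is needed and the fit
is deterministic (no random restarts; the likelihood surface at these
separations is benign — an unconstrained reference implementation
agrees, see the test suite). Stopping: |Δ log-likelihood| < 1e-8 or
500 iterations; component SDs are floored at 1e-3 to prevent collapse.
The reported mosaic fraction is the lower component's weight *among
VAFs above the floor*. Because the EM does not model the floor
truncation, a planted 6% component is recovered at ~5% (low-VAF mosaic
mass is cut away) with the component mean recovered to ~0.005 — the
known, documented bias of this estimator; the validation-based route
is unbiased but requires re-sequencing.

## Enrichment

DNMs are counted in six half-open proband-VAF bins
([0.10,0.15) … [0.35,1.0]) for three *nested* gene-class strata (all
genes / dominant DDG2P / monoallelic-LOF DDG2P). The damaging ratio is
(LOF+functional)/synonymous, undefined when the bin has no synonymous
DNMs. The per-bin ratio is regressed on the mean bin VAF by unweighted
OLS (mirroring the six plotted points; a count-weighted variant was
considered and rejected as the default because bin weighting is not
identifiable from a published table), with a Z-test of the slope
against 0 and of the intercept against the supplied flat
no-enrichment ratio. The no-enrichment expectation is external input
(a scalar per stratum, e.g. from a published mutation-rate model) —
the package does not re-derive gene-specific mutation rates. The
mosaic-versus-constitutive comparison uses a two-sided Fisher exact
test on the damaging/synonymous 2×2 across strata; Fisher was chosen
for exactness at the small synonymous counts involved.

## Phasing

Phasing consumes an abstract table of read-pair co-observations
(DNM allele × informative-SNV allele) rather than alignments: the
decision logic, not BAM plumbing, is the subject. Among DNM-ALT pairs
the majority informative background assigns the origin haplotype;
calls need ≥ 3 supporting pairs and a minority (conflict) fraction
≤ 0.2 — defaults standing in for the visual review a human analyst
would apply. The three-haplotype check requires ≥ 3 observed allele
classes, DNM-ALT confined to one background, and both backgrounds
among DNM-REF pairs. The DNM-vs-inherited VAF contrast uses a paired
Wilcoxon signed-rank test (robust to the bounded, skewed VAF scale; a
paired t is available); origin balance uses the exact binomial test
against 0.5; the parental-age trend uses a log-link Poisson GLM of
per-person mosaic DNM counts on age.

## Synthetic cohort

Defaults emulate the scale of a large developmental-disorder trio
study: 4,293 trios, 8,464 candidate
DNM-like sites, depth Poisson(50) truncated at ≥ 10 (rounding very low
draws up rather than discarding them keeps the site count fixed),
per-base error 0.005, ultra-deep depth Poisson(100,032), proband saliva
and blood sharing the true VAF by default (configurable divergence for
tissue-discordant cases), parents saliva-only. True mosaic VAFs are
uniform over the validated ranges (child 0.04–0.39, low-level parent
0.005–0.20, high-level parent 0.06–0.33) — ranges are reported for the
emulated study, not shapes, and uniform is the least-informative
choice. The mixture preset instead draws mosaic VAFs from
Normal(0.198, 0.05) truncated to [0.1, 0.39], so the planted component
has the stated mean above the fitting floor. The class mix
(constitutive DNM 0.60, child mosaic 0.06, low/high parent mosaic 0.02
each, false positive 0.05, constitutive inherited 0.25) is chosen to
make every screen testable with adequate counts at desk scale; the
`constitutive_inherited` class exists so the high-level parent screen
has a genuine null background. High-level parent-mosaic carriers are
emitted with a HET parental genotype call by construction — they are
defined as the variants a standard caller genotypes in the parent.
Quality scores are drawn Normal(8,1) for real sites and Normal(4,2)
for false positives, giving `calibrate_stringency` a meaningful
ordering without claiming any specific caller's score scale.

## Problem sizes and determinism

All stochastic tests and the acceptance script are explicitly seeded
(NumPy `default_rng`). The test suite runs cohorts of 300–10,000 sites
and 200-seed property loops; the acceptance script fits 10 cohorts of
8,464 VAFs — sizes at which the measured recovery tolerances
(±1.5 percentage points on the mosaic fraction, ±0.02 on the component
mean, ±10 points on rule sensitivity/specificity) comfortably exceed
Monte-Carlo noise.

## Known limitations

* The binomial read model omits caller artefacts (strand bias,
  mapping error, indel realignment); passing tests demonstrate correct
  decision logic and calibration under binomial sampling, not
  robustness to real-data artefact modes.
* The mixture estimator's floor-truncation bias (above) is inherent to
  fitting untruncated Gaussians to floored data.
* Detection power is modelled as P(≥ k alt reads); a real caller's
  behaviour also depends on genotype likelihoods and filters, so
  published cohort-specific power figures (which fold in the empirical
  depth distribution) are approximated, not reproduced — the
  depth-distribution overload accepts an empirical depth list for
  closer emulation.
* Consequence and gene-class annotation are inputs; no annotation,
  liftover or multi-allelic normalisation is performed.
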