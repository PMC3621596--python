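# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open. No empirical claim
here goes beyond what the test suite and `scripts/acceptance.py` compute.

## Dose-response growth model

A strain in a sealed microtiter well is described by four parameters:
maximal specific growth rate `mu0` (h⁻¹), unstressed stationary OD `K0`,
the butanol concentration `c_max` (% v/v) at which growth ceases, and a
Hill steepness `h`. One shared inhibition factor

    f(c) = max(0, 1 − (c / c_max)^h)

scales both the rate, μ(c) = mu0·f(c), and the plateau, K(c) = K0·f(c).
Both observables decline together with concentration in plate data, and a
single shared factor keeps the calibration two-parameter and analytically
invertible: anchoring to the stationary-OD ratio `ratio` at 1% and to
`c_max` gives the closed form h = log(1 − 1/ratio) / log(1/c_max), valid
exactly when ratio > 1 and c_max > 1.

The noise-free trajectory is **exponential growth capped at K(c)** (a
glucose-exhaustion batch model), not a smooth logistic. Sealed-plate
cultures consume all sugar well within the 48-h incubation and then hold a
stationary OD; a smooth logistic only approaches its plateau
asymptotically, so stationary-phase OD *ratios* would carry residual
approach terms of order (K/od0)·e^(−μ·48) (~10⁻⁴ at realistic yeast rates)
and the sensitivity-index calibration would not be exact. With the capped
model the 48-h OD equals K(c) whenever μ(c)·48 ≥ ln(K(c)/od0), and the
generated BSI equals K0/K(1%) to machine precision. A `shape="logistic"`
option provides the smooth curve for rate-fitting work; its early phase is
exponential, which the sliding-window estimator exploits.

Defaults: `mu0 = 0.40 h⁻¹` (a typical maximal rate for this yeast on
glucose), `K0 = 1.0` OD, `od0 = 0.05` (a dense pinned inoculum),
sampling every 30 min for 48 h (the stated acquisition schedule), reference
calibration `ratio = 2.0`, `c_max = 1.45` (the screen background's
anchors; the second background would be 1.43/1.57). Reading noise is
multiplicative lognormal with σ = `noise_sd` — plate-reader error is
scale-proportional — and `noise_sd = 0.02` is used as the working noise
level in tests; the study reports no within-replicate variance, so this is
a free parameter chosen once.

## Screen classification and triage

BSI uses a denominator floor of 0.01 OD so non-growers get a large finite,
sortable index. Classes: hypersensitive (BSI > 10 and final butanol OD
< 0.08), sensitive (2 < BSI ≤ 10 and OD > 0.1), tolerant (1 ≤ BSI < 2),
reference-like (BSI within ±0.25 of 2, configurable). The thresholds leave
a deliberate OD gap [0.08, 0.1]; records falling there, and BSI < 1, are
`indeterminate` rather than silently binned. The literal bands overlap
around BSI = 2; the reference tie band is checked first, so the effective
sensitive band starts at 2.25 and the tolerant band ends at 1.75. Every
record receives exactly one class.

Replicates are aggregated as the **BSI of the replicate-mean ODs**, not the
mean of per-replicate BSIs: one near-dead butanol well would otherwise
dominate the mean of ratios through the denominator floor. A regression
test pins this on a fixture where the two differ by an order of magnitude.

Growth rates are estimated as the maximal slope of ln(OD) over a sliding
window (default 8 readings = 4 h) restricted to readings above a detection
OD (default 0.05); wells with no qualifying window are flagged non-growers
with μ = 0.

The confirmation triage is pure set bookkeeping over gene lists:
n_tested = |hits| − |dubious| + |extra|, n_viable = n_tested − |failures|,
n_confirmed = |confirmed ∩ viable|. The packaged replay names the five
dubious ORFs, the two extra picks and the three transformation failures;
the primary hits beyond the confirmed set are not individually named in
the study tables, so placeholder identifiers stand in (only counts flow
downstream).

## Enrichment

The hypergeometric upper tail is computed in log space (gammaln +
logsumexp) and equals the one-sided Fisher exact test; tests cross-check it
against exhaustive enumeration for every table with N ≤ 30 and against
scipy's survival function and Fisher test. Only over-representation is
tested. Annotations are closed over `is_a` ancestors (reflexive-transitive,
set semantics, idempotent; `part_of` available behind a flag in the OBO
reader). FDR control is Benjamini–Hochberg step-up — the study reports
FDR-adjusted significance without naming a procedure, so BH is this
package's choice and is isolated behind `bh_fdr`. The background population
defaults to the strains actually screened (the deletion collection), which
matches the sampling frame of the screen; terms annotating fewer than 2
population genes are skipped as degenerate (configurable).

The synthetic annotation generator plants categories over specified gene
clusters, pads them with random genes to a realistic size (~40 of 5154),
and surrounds them with ~150 background terms of 5–80 random genes under a
three-level DAG. It emulates annotation *counts*, not real GO structure:
passing tests show the statistics and the propagation are correct, not
that any real category is enriched.

## Variant filtering

SNV-only: indels are set aside first with their own provenance tag. Rule
order is ambiguity → quality → depth → parental subtraction; the first
failing rule is the provenance of a removed call, and since rules i–iii
are per-call predicates the surviving set is invariant to their order
(property-tested). Boundary semantics are inclusive: quality 20, depth 10
and depth 400 all pass ("at least 20"; "below 10 discarded"; 400 is a
caller-side cap and hence attainable). Parental subtraction matches on
(chrom, pos, ref, alt) — allele-aware, because a different allele at a
shared site is a genuine difference; whether the original pipeline matched
on position only is not documented, so the stricter reading was chosen.
Disjoint chromosome name sets between the two call sets trigger a
coordinate-system warning rather than silence.

The synthetic call generator plants evolved-specific calls (quality ≥ 25,
depth 20–100), parental-shared calls present in both sets, and noise calls
that each violate exactly one rule (cycled over the three rule types);
truth labels partition the set, which the tests verify rule-by-rule.

## Annotation

Coordinates are 1-based inclusive throughout, matching the "G1518C"
convention: codon_no = ⌈p/3⌉, offset = ((p−1) mod 3)+1. ORFs are treated
as intronless (the standard convention for this organism's ORF
nomenclature); minus-strand CDS positions count from `cds_end` with
alleles reverse-complemented. Upstream distance 1 is the base immediately
5′ of the A of ATG; the default window is 1000 bp (the furthest reported
promoter variant sits 984 bp upstream). Overlapping gene models all
annotate the call, flagged ambiguous; coding hits outrank upstream hits.

The consistency verdict is an existence check over the standard genetic
code: "consistent" means *some* codon of the reported reference residue
carries the reference base at the computed offset and yields the reported
alternate residue — compatibility, not proof, since the true codon would
require the reference sequence, which is deliberately not a dependency.
One reported row (sto1-2, T2543G / F736V) places position 2543 in codon
848, not 736 — an intron, an alternative numbering or a typographical slip
in the source table; the module reports `position_mismatch` and does not
guess. All other coding rows verify as consistent.

## Backcross simulation

Meiosis is modelled at the spore level. A gamete's inheritance is a phase
chain per chromosome: the first mapped locus picks a parent uniformly and
the phase switches between adjacent loci with the recombination fraction
of their map distance (Haldane r = ½(1 − e^(−2d/100)) by default, Kosambi
as an option; no crossover interference). A tetrad is two independent
gametes plus their complements — this guarantees 2:2 segregation at every
heterozygous locus (hard-asserted in tests) and gives each spore the
correct marginal recombination fraction. Four-strand chiasma bookkeeping
is not modelled, so tetrad-class ratios (PD:NPD:TT) are not claimed to be
realistic; every reported quantity is a spore-level frequency, for which
the construction is exact.

Selection: spores must carry the functional marker allele (the naive
partner's marker is deleted, so this rejects non-recombinant naive
products) and match the evolved phenotype. The default phenotype rule
requires *all* causal alleles — reflecting the finding that single-allele
reconstructions fall short of the evolved strain's tolerance, i.e. the two
transcription-factor alleles act synergistically. An additive-threshold
rule (per-locus effects, tolerance ε) is available for graded phenotypes.
Among eligible spores one is picked uniformly; tetrads are redrawn until
an eligible spore appears, up to a cap (default 1000) before a failure is
declared. Mating type alternates implicitly each cycle and is not a mapped
locus.

Scenario defaults place every allele on its own linkage group at 50 cM —
the study does not model linkage and its mapped genes mostly lie on
different chromosomes — so the unlinked closed form (1/2)^n applies to
neutral alleles, and (1−r)^n to deliberately linked test layouts. The
Monte Carlo estimator (default 10⁴ replicates, vectorised across
replicates) reports retention with normal-approximation 95% CIs; causal
retention is 1.0 exactly by construction of the selection rule. How many
segregants were screened per cross in the original design, and how "same
tolerance" was thresholded, are unstated; they enter only through the
tetrad cap and ε, neither of which affects unlinked retention.

## Replay and problem sizes

`run_replay` executes screen → triage → enrichment → variant generation +
filtering → annotation + reported-table check → backcross retention for
both lineages, with per-stage seeds derived from one master seed by
hashing (all below 2³¹), and emits a JSON report embedding the seed and a
config hash; identical configs give byte-identical reports. Default
problem sizes are the study's where stated (5154 strains with 55 + 50
planted sensitive/hypersensitive, 35-gene study set, 4 planted
evolved-specific SNVs, 3 backcross cycles, 10⁴ retention replicates); the
full-collection screen stage uses one replicate per condition at 60-min
sampling, since only the 48-h endpoint enters the index and the noise-free
classification is exact by construction.

## Known limitations

- The growth model has no lag phase, no butanol evaporation kinetics, no
  edge effects and no well-to-well carryover; classification accuracy on
  noisy synthetic screens says nothing about systematic plate artefacts.
- The enrichment module handles `is_a` (optionally `part_of`) only — no
  evidence codes, no GO slims, no full OBO grammar.
- The filter chain starts from call tables; alignment, pileup and the
  caller's own heuristics (strand bias, end distance) are upstream of its
  scope.
- Consistency verdicts cannot detect a wrong-but-compatible reported
  residue; only the reference sequence could.
- The backcross simulator does not model sporulation efficiency, spore
  viability, segregation distortion or quantitative trait mapping.
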