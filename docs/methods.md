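# Methods

## Genetic model

Gametophytic self-incompatibility (GSI) is modeled as absolute pollen
rejection: a pollen grain with haploid genotype (s, m) fertilises iff its
S-haplotype `s` is pollen-part mutated (member of the model's
`s_compatible_pollen` set, e.g. {S_C}) or its M-haplotype `m` carries the
modifier pollen-part mutation (`m_ppm_haplotypes`, e.g. {m0}). Rejection is
all-or-none — no partial compatibility and no pollen competition — because
the downstream ratio tests assume clean progeny classes. Ovule transmission
is always Mendelian (pollen-part action only), the S- and M-loci assort
independently (different chromosomes), and recombination within the M-locus
SSR block is fixed at zero: the seven markers span a short physical interval,
so a haplotype is transmitted intact, and the phasing code counts any progeny
it cannot explain as an explicit recombination/mutation exception rather than
absorbing it.

Closed-form selfing expectations follow directly: selfing S_x/S_C with only
{S_C} compatible gives progeny {S_x/S_C : S_C/S_C} = 1:1 with the S_x/S_x
class structurally absent; selfing S_a/S_b with a modifier PPM in coupling
with one M-haplotype gives S classes 1:2:1 and M classes 1:1 with the
repulsion-phase M homozygote absent. The expectation routine conditions the
joint pollen gamete (s, m) on acceptance before marginalising, so acceptance
correlation between the two loci is handled exactly.

## Segregation tests and the mutation-location classifier

`chisq_ratio` is the Pearson goodness-of-fit statistic without continuity
correction (df = classes − 1, expected counts proportional to the stated
integer ratio; scipy's `chisquare` does the arithmetic). The uncorrected
statistic is the one that reproduces the reference progeny values
(e.g. 33:45 vs 1:1 → χ² = 1.85).

The classifier fits two models to a selfing progeny's three S-genotype
classes (hom-A : het : hom-B):

- **S-linked PPM**: the non-mutated homozygote class is structurally absent;
  any observed count there disfavours this model outright. The remaining
  classes are tested 1:1. Both orientations (either parental allele mutated)
  are tried; the orientation requires its absent class to be empty.
- **S-unlinked PPM**: all classes present, tested 1:2:1. When M-linked SSR
  progeny classes are supplied and the repulsion-phase homozygote is absent,
  a retained 1:1 test on the remaining two classes upgrades the call to
  "S-unlinked (M-linked)".

A call is made only when one model is retained at `alpha` (default 0.05,
configurable) and the other rejected; anything else — including fewer than
`min_n = 10` analysed progeny — returns "undetermined" with both test
results attached. One reference progeny (counts 16:24:4) rejects both models
at 0.05; it is returned undetermined with the excess-homozygote flag set
(the over-represented mutated-allele homozygote class is the documented
signature of a possible second, allele-specific mutation). The `min_n = 10`
floor is far below the 36–78 analysed progenies of the real trials.

## S-allele calling

Each catalogued allele has an expected signal per assay: a fragment size in
bp, "no amplification" (informative — part of the signature), or a boolean
for the insertion assay. Tolerances follow the measurement technology:
±1 bp for capillary-sized assays, ±10 % of the expected size for
agarose-estimated second-intron fragments, exact for presence/absence. An
attempted assay with no product matches exactly the "no amplification"
alleles; untested assays are neutral.

Diploid calling enumerates all unordered allele pairs and keeps those whose
predicted fragment pattern matches the observed pattern in every attempted
assay (expected sizes closer than the tolerance are merged first, so a
homozygote or a shared-size heterozygote correctly predicts one band). One
surviving pair is a resolved call; several yield an explicit ambiguity list
plus, per unattempted assay, whether it would separate the candidates (the
insertion assay for {S_C, S_8}); none is a conflict naming the amplifying
assays. Ambiguity is always flagged, never silently resolved.

`discriminating_power` reports two metrics because the field uses both: the
number of distinct signature classes among amplifying alleles (what a single
assay "distinguishes") and the number of alleles with a globally unique
combined signature (what a battery resolves "unambiguously").

### The packaged allele reference is synthetic

The exact per-allele fragment sizes live in a supplementary table that is
not redistributed with this package. The packaged reference
(`s_allele_reference_synthetic.csv`) is a synthetic stand-in constructed
from the documented qualitative relations: which alleles amplify in which
assay, which pairs collide per assay ({S1,S7} and {S_C,S_8} in the first
intron; {S5,S6}, {S_C,S_8} and {S19,S20,S_V} in the second; {S2,S11},
{S_Z,S31} and {S_C,S_8} in the SFB intron), and the published range anchors
(260–427 bp first intron, 300–2800 bp second intron, 189–210 bp SFB intron).
Distinct synthetic sizes are spaced beyond the matching tolerances. This
preserves the combinatorics — 13, 15 and 9 distinguishable classes for the
three single assays and 18 of 20 alleles uniquely resolved by the full
battery — but not the real sizes, so tests validate the calling logic and
the collision structure, not numerical agreement with real electropherograms.
Under this structure the combined-signature collision is the {S19, S20}
pair (two alleles the source survey itself suggests may be identical).

## M-haplotype inference

**Phasing.** For a parent heterozygous at h of the 7 linked loci there are
2^(h−1) phase splits. Each candidate split is scored by the number of
progeny explainable as an ovule gamete × pollen gamete combination without
recombination (selfing: both gametes from the parent; outcross: the other
parent's haplotypes supplied). The maximising split is returned with the
exception count; ties return "unphased" rather than an arbitrary pick.

**EM.** Haplotype frequencies maximise the multinomial likelihood of
unordered genotype pairs. The support set is the union of all phase
completions of fully observed genotypes plus any seeded known haplotypes;
genotypes with missing loci are marginalised over compatible support pairs
(never imputed), and a genotype compatible with no support pair is excluded
and reported. E-step: posterior weights `(2 − [h1=h2]) f(h1) f(h2)` over
compatible pairs; M-step: expected haplotype counts over 2N. Initialisation
is uniform over the support, `tol = 1e-8` log-likelihood units,
`max_iter = 10 000` (the 7-locus configuration space keeps this cheap).
Monotonicity of the log-likelihood and unit-sum of frequencies are asserted
on every run; on phase-unambiguous data the estimate equals direct counting
exactly.

**Main classes.** The grouping rule — same class when differing at ≤3 of the
7 SSR alleles — is pairwise and not transitive, so classes are defined as
connected components (single linkage) of the ≤3-difference graph; this is
the reading under which the full haplotype set forms 20 disjoint classes.
Class and subtype numbering is deterministic (lexicographic by allele
vector), which intentionally does not reproduce historical subtype numbers;
published labels are carried as metadata. Haplotypes missing more than half
their loci are excluded and reported.

The packaged haplotype table (`m_haplotypes_synthetic.csv`) is likewise a
synthetic stand-in: 38 haplotypes whose labels span 20 main classes, with
subtypes differing at ≤3 loci, classes separated at ≥4 loci, and the M1
subtypes ordered M1-2 < M1-1 < M1-0 by Bruvo distance from m0-0 as reported
for the real panel. The real supplementary allele sizes would be needed to
reproduce the printed Bruvo values (0.18/0.22/0.26); with integer repeat
differences over 7 loci the middle value is in fact unattainable
(no combination of per-locus terms 1 − 2^(−k) averages into [0.215, 0.225)),
so those printed values evidently reflect fractional repeat offsets in the
real data and are not asserted anywhere. The seven markers are modeled as
dinucleotide repeats (2 bp/unit), a declared assumption.

## Distances, trees, bootstrap

Bruvo's per-locus distance is `1 − 2^(−|x|)` with `x` the size difference in
repeat units; haplotypes carry one allele per locus, so no polyploid
allele-matching combinatorics arise. Non-integral offsets are rounded to the
nearest repeat count with a warning; missing loci are averaged over the loci
observed in both haplotypes; no shared loci is a "no data" error, surfaced
before tree building. Jaccard distance is `1 − |A∩B|/|A∪B|` on binary
(marker, size) incidence.

Neighbor joining is the standard Saitou–Nei agglomeration on the Q
criterion, ties broken toward the lowest label-pair index. Negative branch
lengths are clamped to zero with the deficit transferred to the sibling
branch, preserving path lengths through the joined pair. On additive
matrices the generating tree is recovered exactly (tested against a
closed-form 4-taxon case and an independent implementation). Output is
newick; bootstrap supports are encoded as internal node labels.

The bootstrap resamples the 7 marker columns with replacement (matrix
bootstrap over loci, not over haplotypes), rebuilds the tree per replicate,
and reports for each original split the fraction of replicates containing
it; everything is reproducible under a fixed seed.

## Synthetic-data generators

`simulate_selfing_progeny` draws ovule gametes Mendelian-uniformly and
pollen gametes uniformly over the accepted classes (with absolute rejection
this conditional sampling is exactly equivalent to rejection-resampling).
`simulate_germplasm_panel` places ancestral haplotypes
`ancestor_separation_repeats` (default 6) repeat units apart at every locus
and derives descendants by ≤3 symmetric single-repeat steps at distinct loci
(geometric step counts, mean 1), guaranteeing by construction that
main-class recovery equals ancestry; diploids pair haplotypes uniformly;
missing calls at 2 % by default. `simulate_fragment_profiles` perturbs
expected sizes by uniform integer noise within ±`size_noise_bp` (default
1 bp for noisy runs; the insertion assay is noiseless). The survey itself
reports no genotyping-error rates, so the missingness and noise defaults are
declared test parameters, not estimates. What the generators do **not**
emulate: pollen competition, partial SI, fruit-set/embryo survival,
population structure or selection — so passing recovery tests shows the
inference chain is correct under its own model, not that real data meet the
model's assumptions.

Every stochastic operation takes an explicit integer seed and uses one
`numpy` Generator per call; identical seeds give byte-identical outputs.

## Problem sizes

The test suite and the acceptance script use: EM recovery at n = 100
genotypes over 4 haplotypes; EM monotonicity over 50 seeded instances;
phasing from 200 selfed progeny; simulator checks at n = 10 000 progeny
(3-SE binomial bounds); classifier accuracy over 20 seeds × 80 progeny per
design; bootstraps at B = 50–100 over 6–8 taxa. These sizes were chosen to
make sampling error negligible relative to the tested tolerances while
keeping a full run in about a minute.

## Known limitations

- Synthetic reference tables validate structure, not real-world sizes (see
  above); calls on real electropherograms require transcribing the real
  reference into the same CSV schema.
- The EM support construction requires at least some fully observed
  genotypes (or seeded haplotypes) to anchor the support set.
- The classifier is a frequentist decision rule at a fixed alpha; it does
  not weigh models by likelihood ratio and will return "undetermined" on
  progenies that genuinely reject both single-mutation models.
- One germplasm progeny row is annotated as carrying printed statistics that
  do not match Pearson recomputation from its own printed counts; the fixture
  keeps the counts and the annotation, and no code is tuned to reproduce the
  printed statistic.
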