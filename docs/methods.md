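# Methods

This note documents the statistical models, conventions and design choices
behind `uorfsel`, the assumptions of its synthetic-data generator, and what
the passing tests do and do not establish about real data.

## Coordinate and sequence conventions

Internal coordinates are 0-based half-open genomic intervals; VCF positions
are converted from 1-based on read, BED stays 0-based. An ORF's
`spliced_sequence` is stored as RNA in translation orientation: minus-strand
ORFs are reverse-complemented on read, and a variant's alleles are
complemented before codon substitution. Every downstream statistic is
therefore invariant under reflecting the genome to the opposite strand — a
property enforced by tests rather than assumed.

Mutation contexts are reference-strand DNA triplets centred on the reference
base, collapsed so the centre is A or C (reverse-complementing triplet and
alternate otherwise). This yields one canonical representative per
strand-symmetric mutation class: 32 triplets × 3 alternates = 96 classes,
onto which all 192 raw (triplet, alt) pairs map two-to-one. Triplets
containing N yield no context and are excluded from MAPS. An optional
methylation level {0, 1, 2} can refine CpG-containing classes when both the
variant records and the rate table carry it; it is off by default because
none of the package's standard analyses require it.

## Consequence model

A variant inside a translated ORF is classified purely from the mapped codon
substitution:

- first codon: substitutions of position 1 that leave the codon in the NUG
  set {AUG, CUG, GUG, UUG} are `start_maintain`; any substitution of
  positions 2–3 is `start_disrupt`. Translated uORFs initiate at non-AUG
  codons frequently, which is why the first position is treated as
  context-neutral;
- elsewhere: membership of the ref/alt codon in {UAA, UAG, UGA} decides
  `stop_gain`, `stop_loss`, and — when both are stops — `stop_strengthen` or
  `stop_weaken` along the termination-efficiency ranks UGA(1) < UAG(2) <
  UAA(3); otherwise the standard genetic code decides
  `synonymous`/`missense`.

`stop_weaken` and `stop_loss` are emitted even though the headline analyses
use only gain/strengthen; this keeps the category set a true partition of
all 9L possible SNVs, which the test suite verifies against a brute-force
oracle on all 64 × 9 codon substitutions. The terminal annotated stop codon
is excluded from stop-creating enumeration (substitutions there are
weaken/strengthen/loss events). Variants hitting several overlapping ORFs
are classified against each; class-level tallies deduplicate to the single
most severe call (stop_gain > stop_strengthen > start_disrupt > stop_loss >
stop_weaken > missense > synonymous > start_maintain) so no variant is
double-counted.

Codon optimality direction is the sign of CSC(alt) − CSC(ref); any stop
codon involved gives `n/a` since stability coefficients are defined only for
the 61 sense codons.

Two length thresholds are carried as parameters with their conventional
defaults: 118 codons for long/short missense stratification and 20 codons
for start-disruption stratification.

## MAPS

The mutability-adjusted proportion of singletons for a class *C* is
(observed singletons − Σ p̂(context)) / |C|. The calibration p̂ is fitted on a
neutral class by weighted least squares of per-context singleton proportion
on the context's mutation rate, with weights equal to per-context variant
counts; fitted values are clamped to [0, 1]. With a single distinct rate the
design is rank-deficient and the fit saturates to the pooled proportion. A
grouped-binomial logit link is available behind `link="logit"` but the
linear fit is the default, matching the established practice this metric
comes from. Because the fit has an intercept, weighted training residuals
sum to zero, which gives the exact calibration identity MAPS(training) = 0 —
the suite asserts it to 1e-9.

Uncertainty is a percentile bootstrap over variants (default 10,000
iterations; 5th/95th percentiles, i.e. a 90% interval, configurable to 95%).
Class comparisons use a paired bootstrap: both classes are resampled each
iteration and the one-sided p-value for "A exceeds B" is
(1 + k)/(n_iter + 1), where k counts iterations in which A's score fails to
exceed B's, **with exact ties counting one half**. The mid-p tie rule
matters: resampled scores of small or discrete-valued classes tie with
non-negligible probability, and counting ties fully makes the null
distribution visibly conservative (mean ≈ 0.54 rather than 0.5 in our null
simulations); with ties at half weight the p-values pass a KS uniformity
check and the floor 1/(n_iter + 1) under complete separation is unchanged.
The +1 correction means a p-value of exactly zero is never reported.

Context-matched controls are drawn per context so the control's context
histogram equals the target's exactly; sampling is without replacement where
the pool stratum allows and with replacement (logged) where it is thin.

## Stop-codon usage

uORF stop-codon proportions over (UGA, UAG, UAA) are compared against a
background built per iteration by drawing one stop-matching trinucleotide
uniformly from each eligible 5′UTR — scanning transcript orientation only,
counting overlapping occurrences at every offset — and recording the
proportions among drawn codons. UTRs with no occurrence contribute nothing
that iteration; the expected background proportion of codon k is therefore
the average over eligible UTRs of each UTR's occurrence fraction, which the
sampler is tested against at 3 Monte-Carlo standard errors. With
`exclude_orf_overlap` the scan masks trinucleotides touching any
translated-uORF base, giving the "uORF-containing UTRs outside uORFs"
control. Depletion/enrichment p-values use the same paired-stream mid-p rule
as above. One transcript per gene defines the UTR universe in the synthetic
world.

## Conservation

A base is strongly conserved when its phyloP-like score is strictly greater
than 2.0 (2.0 itself is not conserved; the boundary is tested). Positions
absent from the track are dropped with a logged count — never scored 0,
because a missing alignment column is not evidence of neutrality. CIs are
percentile bootstraps over positions; group comparisons resample both groups
(mid-p ties). Control positions are matched by distance to the downstream
CDS start in 10-bp bins ([0,10), [10,20), …), measured in transcript
coordinates; matching draws one pool candidate per target from the same bin,
guaranteeing bin-histogram equality. Outside translated ORFs no reading
frame exists, so "stop-creating" control positions are enumerated in any of
the three local frames by default (`frame="fixed"` restricts to the frame
anchored at the UTR 5′ end).

## Association layer

Case/control status for a phenotype code: ≥ 2 distinct event dates → case;
no event → control; exactly one date → excluded (diagnostic ambiguity). A
one-encounter mode (`min_case_dates=1`) supports cohorts where repeat coding
is rare. An optional control-exclusion code list removes controls carrying
related diagnoses. Eligibility requires ≥ 5 total alternate alleles, ≤ 50%
missing genotypes and ≥ 20 cases, with machine-readable failure reasons.

Association is additive-dosage logistic regression (statsmodels ML fit) with
Wald inference, adjusted by convention for age, age², sex and PC1–PC10.
Complete or quasi-separation — the realistic regime for rare carriers — is
detected (warning capture plus a standard-error sanity bound) and flagged on
the result rather than silently returned as an enormous finite OR; flagged
fits are excluded from thresholding and meta-analysis. A Firth-penalised
fit (Jeffreys-prior score correction) is available behind `firth=True` and
remains finite under separation. Strata are combined by fixed-effect IVW:
β = Σwᵢβᵢ/Σwᵢ, se = (Σwᵢ)^(−1/2), wᵢ = seᵢ⁻²; monomorphic or unreliable
strata are dropped with a log note. Gene burdens sum dosages of rare
(MAF ≤ 0.1%) pLOF and REVEL ≥ 0.5 missense variants; missing genotypes
contribute zero. Panel lines are Bonferroni α/(n_variants × n_phenotypes)
and the plotted FDR line fdr_level/n_phenotypes — the only formula
consistent with the conventional printed values for a 10 × 800 panel
(6.25e-6 and 1.25e-4) — with a true Benjamini–Hochberg step-up also
available for reporting.

## Synthetic-data generator

The generator emulates the study's inputs with known ground truth. Defaults
were chosen once, as the study conditions:

- **transcriptome**: 60 genes, single-block 5′UTRs of 150–300 nt on a
  50/50 strand mix, uORF presence probability 0.85, uORF lengths 6–40
  codons; start-codon weights AUG/CUG/GUG/UUG = 0.35/0.30/0.20/0.15 (non-AUG
  majority, qualitatively matching ribosome-profiling start-usage
  distributions; exact published proportions are not available, so these are
  illustrative); stop-codon weights UGA/UAG/UAA = 0.45/0.36/0.19 — a UAA
  share matching the ~19% reported for translated uORFs, against ~1/3
  expected from background;
- **mutation model**: rates for all 96 collapsed classes drawn U(0.01, 0.09)
  in arbitrary units with baseline singleton proportion 0.05 + 5·μ
  (0.10–0.50, bracketing realistic singleton proportions); class-specific
  excesses δ(stop_gain) = 0.05, δ(stop_strengthen) = δ(start_disrupt) =
  0.04, zero for missense/synonymous/background;
- **variants**: every possible SNV at covered positions is emitted with
  probability 0.6 inside uORFs and 0.25 in UTR background, plus 20,000
  synonymous-coding calibration variants on a dedicated chromosome; AC/AN,
  FILTER and low-complexity contamination at 2% each exercise the QC filter.
  Singleton status is simulated directly as Bernoulli(baseline + δ) rather
  than through a population-genetic model: MAPS consumes only the
  (context, singleton) pair, so this is the minimal sufficient generative
  model. It deliberately omits linkage, demography and recurrent mutation;
- **conservation**: designated stop-creating and start-disrupting positions
  conserved (score > 2) with probability q = 0.6, drawn U(2.5, 8);
  background N(0, 1), whose conserved tail is the analytic Φ̄(2) ≈ 2.3%;
- **biobank**: logistic disease model logit P(case) = β₀ + log(OR)·dosage +
  0.2·age_z + 0.1·sex, with β₀ solved by root-finding for 5% prevalence;
  carriers at 1% frequency under Hardy–Weinberg; true OR 3; cases receive
  2–3 distinct event dates and 5% of non-cases exactly one date so the
  exclusion rule is exercised; two ancestry strata (80/20) for the IVW path.

The generator derives each uORF variant's true class with its own
transcript-space rule, independent of the genomic classifier; the pipeline
test that the classifier reproduces every sidecar label is therefore a real
integration check of the coordinate/strand machinery. Because the generator
plants truth directly at the level each statistic consumes, passing
recovery tests show the estimators are correct and calibrated — they do not
show that real uORF variants behave like the synthetic ones (no LD, no
population structure in the variant table, single-isoform transcripts,
no splicing inside UTRs).

## Numerical choices

- Bootstrap engines are vectorised in blocks of 2,000 iterations to cap
  index-matrix memory; all randomness flows through `numpy.random.Generator`
  seeded per call, and the pipeline derives per-stage seeds from the run
  seed so a manifest re-run is byte-identical.
- Fitted calibration proportions are clamped to [0, 1]; out-of-range
  predictions can only arise for extreme extrapolated rates.
- The AN (allele-number) QC cutoff is 80% of the maximum AN within the
  analysed variant set.
- Degenerate inputs fail loudly: empty classes, unmatched contexts or
  distance bins, sense codons passed to the stop-strength rank, rate tables
  with missing contexts, and CSC tables missing sense codons all raise with
  the offending keys listed.
- Problem sizes in the test suite (2,000 variants per MAPS recovery class,
  100 recovery replicates, 500 null replicates at 1,000 iterations, 200
  association replicates at n = 20,000, a 30–60 gene demo pipeline) were
  chosen as the smallest scales at which the stated coverage and uniformity
  properties are statistically resolvable.

## Known limitations

- The synthetic transcriptome is intron-free; multi-block (spliced) ORFs are
  fully supported and unit-tested through the I/O and classifier layers, but
  no generated scenario exercises them end to end.
- LOEUF-style gene-constraint stratification is supported only as grouping
  by a user-provided per-gene score column; the score itself is out of scope.
- The PheWAS layer assumes covariates are complete and principal components
  precomputed; sample-level sequencing QC and relatedness pruning are
  upstream of this package.
- Firth inference uses Wald standard errors from the penalised information;
  profile-likelihood intervals are not implemented.
- MAPS is reported as a score with bootstrap uncertainty; converting it to a
  selection coefficient is intentionally out of scope.
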