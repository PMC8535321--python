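# Methods

## Pedigree model and conventions

A pedigree is a set of individuals in which founders have no parents and
every non-founder has exactly two; founders are assumed non-inbred and
mutually unrelated.  Affection status is three-valued (affected /
unaffected / unknown) following the PED phenotype convention.  All
genomic coordinates are 1-based GRCh37; variant keys are normalized by
trimming the shared allele suffix first and then the shared prefix
(advancing the position), which makes keys joinable across exome, chip
and summary-statistics sources.  Genotypes are alternate-allele dosages
in {0, 1, 2}; missingness is an explicit sentinel (NaN), never dosage 0.

Kinship coefficients use the classic parents-first recursion
(`phi(i,i) = (1 + phi(f_i, m_i))/2`, `phi(i,j) = (phi(f_i,j) +
phi(m_i,j))/2`), so inbred descendants are handled correctly even though
founders themselves are non-inbred.

## Non-parametric linkage

**Inheritance vectors.**  Each non-founder contributes two meiosis bits
(paternal, maternal); bit value 0 transmits the parent's own paternal
allele.  The engine enumerates the full space of `2^(2n)` vectors (cap:
24 bits, i.e. 12 non-founders) with vectorized founder-allele label
propagation.  The built-in index family has 12 bits (4096 states).

**Sharing statistic.**  The NPL-all statistic picks one allele from each
of the `a` affected members and averages `prod_f b_f!` over all `2^a`
picks, where `b_f` counts occurrences of founder allele `f` in the pick.
The null mean and standard deviation are computed exactly over the
uniform vector distribution, so the standardized `Z` has mean 0 and
variance 1 to machine precision for every pedigree.  Families with
fewer than two affected members are rejected; a family whose `S_all` is
constant (uninformative) gets `Z = 0` with a warning.

**Marker likelihoods.**  For a biallelic marker with population
alternate-allele frequency `p`, founder alleles are i.i.d.
Bernoulli(`p`).  `P(genotypes | v)` sums over founder-allele assignments
consistent with the vector and the observed dosages; missing calls
impose no constraint.  Two implementations exist and are tested against
each other: a bit-packed fast path that enumerates the `2^(2F)` founder
assignments once per pedigree and reduces each marker to gathers, ANDs
and weighted popcounts (used when `2F <= 14`), and a per-vector
constraint-coloring reference (union-find with parity) that factorizes
the likelihood over equality/inequality components.

**Multipoint chain.**  Markers within a chromosome form a hidden Markov
chain over inheritance vectors; each meiosis bit flips independently
between adjacent markers with probability given by the Haldane map
function `theta = (1 - e^(-2d/100))/2` of their cM gap (genetic
positions come from linear interpolation in a physical-to-cM anchor map,
with constant extrapolation beyond the terminal anchors).  The
transition operator factorizes over bits and is applied axis-wise in
`O(bits * 2^bits)`.  Forward–backward scaling yields per-marker
posterior vector distributions.  Sex chromosomes are excluded by
default: the transmission model is autosomal.  Marker–marker linkage
disequilibrium is not modelled; founder alleles are independent across
markers given the map.

**Kong & Cox exponential model.**  Per marker, the evidence is
`L(delta) = E_w[e^(delta Z)] / E_0[e^(delta Z)]` with `w` the posterior
and `E_0` the uniform null; `exLOD = log10 L(delta_hat)` maximized over
`delta in [0, 10]` by a 33-point bracketing grid plus golden-section
refinement to 1e-6.  The model is one-sided: when the posterior mean of
`Z` is non-positive the result is `exLOD = 0`, `p = 0.5`.  When the
maximizer sits at the search boundary the analytic supremum
`log10( w(argmax Z) / P_0(argmax Z) )` — the `delta -> infinity` limit —
is reported instead; for a fully informative maximal-sharing
configuration this equals `-log10 P_0(maximal class)`, which for the
index family is `log10 64 = 1.806`.  The tail probability is the
standard normal-approximation transform
`p = 1 - Phi(sqrt(2 ln10 * exLOD))`.

**Region calling.**  Peaks are variants within 1e-6 of the track's
global maximum (floating-point-safe reading of "reaching the maximum");
each peak extends to the nearest variant with `exLOD <= 0`, whose
position becomes the region endpoint (chromosome ends terminate
regions); overlapping or shore-sharing regions merge.  Coordinates are
1-based inclusive.

**Known limitation — single-family tail calibration.**  The
normal-approximation p is asymptotic in the number of families.  For a
single pedigree the null distribution of `Z` is discrete and
right-skewed; exact enumeration for the index family (a test computes
this) puts the complete-information null probability of the nominal
`p < 0.05` event at 0.0781 rather than 0.05.  With partially
informative markers the realized fraction shrinks toward (and in the
shipped calibration run slightly below) 0.07.  Linkage p-values from a
single family should therefore be read as ranking evidence, not exact
tail probabilities — which is also why peak calling uses the track
maximum rather than a fixed significance cut.

## Weighted genetic risk score

Panel loci carry a published odds ratio and a protective flag.  Weights
are `ln(OR)`; a protective locus is scored as `ln(1/OR)` per
non-protective allele, which is algebraically identical to a risk locus
with the reciprocal odds ratio (a tested invariant).  Dosages passed to
the scorer are always counts of the scored (risk-direction) allele.
Missing dosages are skipped by default — skipping never fabricates risk;
optional mean imputation (`2 * panel frequency`) is available when panel
frequencies are configured, since cohort practice varies.  Group
comparison uses the classical equal-variance two-sample t test (Welch
behind a flag; at the intended group sizes the difference is
negligible).  Zero pooled variance with equal means returns `p = 1` by
convention.

## Prioritization cascade

The five stages are independent predicates; a variant survives iff it
passes all, so stage order affects only bookkeeping, never the surviving
set (tested against a one-pass conjunction).

* Segregation: all affected members must be carriers.  Carriage by a
  healthy member does not exclude — it is recorded as an optional
  annotation flag for prioritization commentary.
* Frequency: strict `MAF < threshold` (default 5 %) in **every**
  populated database column among 1000 Genomes EUR, GnomAD NFE and ExAC
  NFE, or absence from all three.  The strict all-populated reading is
  the default because the databases are listed conjunctively; a
  permissive any-column mode is exposed (`freq_mode="any"`).
* Function, by category: high-impact classes (splicing, frameshift and
  non-frameshift indels, stopgain, stoploss) always qualify; missense
  needs `CADD_Phred > 10` or a damaging call from at least 2 of 5
  missense tools (SIFT deleterious; PolyPhen probably/possibly damaging;
  MutationTaster disease-causing; MutationAssessor high/medium; FATHMM
  damaging — the tools' standard damaging labels); synonymous, and in
  the exome context the non-coding classes (ncRNA, UTR, intronic,
  upstream), need any one of `CADD > 10`, `GWAVA > 0.5`, `GERP > 4`,
  `|SPIDEX| > 4`, `SpliceAI > 0.4`; in the genome context non-coding
  classes need `SpliceAI > 0.4` alone.  Absent scores never satisfy a
  criterion: a missing prediction is not evidence of impact.
* Linkage intersection (optional): position within any called region,
  inclusive endpoints.
* Association evidence: nominally significant (`p < 0.05`) in at least
  one external cohort where the key is present, or absent from every
  cohort.  Matching is by exact normalized key; allele-flip rescue is
  deliberately out of scope to avoid silent strand errors.

## Burden testing

Per-subject burden is `b_i = sum_v w_v d_iv` (default `w_v = 1`;
Madsen–Browning `1/sqrt(2p(1-p))` weights behind a flag).  With centered
phenotype `c = y - ybar`, the score is `U = c'b` and the null variance
`V = (sum_v w_v^2 2 p_v (1-p_v)) * c'(2 Phi)c`, giving a signed
statistic `U/sqrt(V)` whose positive direction means enrichment in
affected subjects, with a two-sided normal p.  Allele frequencies are
estimated from one randomly chosen member per family (seeded) to avoid
kinship-inflated estimates, or can be supplied directly.  With all
families of size one the statistic reduces exactly to the classical
unrelated score test (tested to 1e-9).  Genes with a single qualifying
variant are reported descriptively through the one-subject-per-family
collapsing rule (a family counts once, as a case family if any of its
carriers is affected; unrelated unaffected carriers count once each as
controls) and are not tested.  The normal approximation is used rather
than permutation; at the default cohort structure (28 nuclear multiplex
families plus 30 unrelated controls, low-frequency variants at 1–5 %)
the measured type-I error at the 5 % level over 2,000 null genes is
within the calibration band of the acceptance suite.

## Enrichment

Over-representation uses the hypergeometric upper tail
`P(X >= k)` for overlap `k` between a query of `n` genes and a term
annotating `K` of `N` genome genes; the universe size `N` is a required
configuration value (default 20,000 protein-coding genes) because web
enrichment tools do not document per-category backgrounds — published
enrichment p-values are therefore order-of-magnitude references only.
Bonferroni adjustment multiplies by the user-supplied number of
annotations in the term's category.  The colocated-gene sensitivity
rerun drops, for every linkage region contributing two or more overlap
genes, all but the lowest-position gene and recomputes; unresolvable
gene positions are retained with a warning.  Gene symbol matching is
case-insensitive; alias resolution is out of scope.

## Synthetic data: what it emulates and what it does not

`gene_drop` emulates the marker data of a family linkage scan: founder
alleles drawn i.i.d. at each marker's population frequency, Mendelian
transmission with Haldane recombination along a regular cM grid
(defaults: 20 markers, 2 cM spacing, 1 Mb/cM, alternate-allele frequency
0.4 — a sparse panel of common biallelic markers on one chromosome).
An optional disease locus conditions inheritance by rejection sampling
of whole-genome drops until the carrier rule holds: `shared` requires
every affected member to carry one designated founder haplotype
identical by descent; `penetrant` additionally forbids carriage in
unaffected non-founders (founders are exempt, since the transmitting
founder necessarily carries).  Rejection sampling is exact and fast at
the pedigree sizes of interest (acceptance probability 1/32–1/64 for
the index family).

A single integer seed drives one `numpy` Generator per call; fixed seed,
identical output.

Deliberately not modelled: linkage disequilibrium between markers,
genotyping error, sex-chromosome transmission, and population
stratification.  Passing calibration tests on this generator therefore
demonstrates correctness of the inheritance and scoring machinery under
the stated model, not robustness to LD or data-quality artifacts in
real scans.

`simulate_annotated_variants` builds filter-cascade fixtures in which
every variant either survives by construction or fails exactly one
designated stage while passing all others, making per-stage failure
attribution checkable exactly.  `simulate_wgrs_cohort` draws
Hardy–Weinberg genotypes and assigns case/control status from a
logistic liability model with configured per-locus odds ratios, the
intercept anchored so the risk at the mean burden equals the configured
prevalence (default 15 %).

## Problem sizes in the shipped calibration runs

The acceptance suite uses: 1,000 gene-drop replicates of the default
20-marker panel for null calibration; 200 replicates for penetrant-locus
recovery; 100 seeds of the 20-variant cascade fixture; 2,000 null genes
over the 28-family cohort for burden type-I error; and exhaustive
enumeration of every hypergeometric parameter combination with
`N <= 12`.  These sizes keep the full suite within a few minutes on one
CPU while leaving Monte-Carlo error well inside the stated tolerance
bands.
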