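# Methods

`proteobin` reconstructs the computational core of a proteogenomic study
design for enrichment-culture consortia: population genomes are recovered
from an assembled metagenome by composition-based binning, a non-redundant
protein database is distilled from the gene calls, and label-free
metaproteome measurements across culture fractions are normalized and
tested for differential representation under left-censoring.  A seeded
synthetic-data layer supplies communities and proteomes with known ground
truth so that every stage can be validated quantitatively.

## Composition model and score

DNA composition is modelled as an order-3 De Bruijn chain: the
distribution of the next base conditioned on the preceding 3-mer,
equivalently 4-mer (tetranucleotide) statistics.  A `CompositionModel`
stores raw 4-mer counts; transition rows are derived with add-one
smoothing on request (unsmoothed rows are available, with unseen k-mers
flagged as NaN rather than invented).  Windows containing `N` are
skipped.  The default strand policy is *canonical* — each window is
counted together with its reverse complement — because contig orientation
in an assembly is arbitrary; a single-strand mode exists for tests.

The dissimilarity between a contig and a bin is the total-variation (TV)
distance between their 4-mer frequency distributions,
`0.5 * sum_w |p(w) - q(w)|`.  TV is a true metric, bounded in [0, 1],
zero iff the distributions coincide, which makes an absolute threshold
interpretable.  A mean negative-log-likelihood-per-base chain score is
available behind a flag as an alternative.

A practical consequence of the TV scale: the empirical 4-mer distribution
of a 5–50 kbp contig deviates from its own source distribution by
~0.03–0.08 purely through sampling noise (256 cells, thousands of
windows), so an absolute acceptance threshold of 0.01 is met only by very
long contigs.  The conservative early rounds therefore assign little, and
overall recovery is carried by the final exhaustive round; see below.

## Binning procedure

1. **Seeding.**  Contigs carrying single-copy phylogenetic marker genes
   are labelled by the taxon that wins a *strict majority* of the
   markers on that contig; ties seed nothing.  One seed bin per observed
   taxon, its model built from its member contigs.
2. **Conservative rounds (two).**  Every contig ≥ 1000 bp is scored
   against all bins.  It is assigned to the lowest-scoring bin only if
   that score is < 0.01 *and* the second-best score is at least 1.2×
   the best.  The margin condition removes contigs that fall between two
   bins.  Written as "second best no more than 120% of the best", the
   rule would do the opposite — keep exactly the ambiguous contigs — so
   it is implemented in the direction of its stated purpose; the literal
   reading is selectable by flag.  Existing members that fail only the
   absolute cutoff are retained (marker evidence outweighs a weak
   composition score); members vetoed for *ambiguity* are dropped, which
   is the only way a bin shrinks.
3. **Merge/delete.**  Bin pairs whose model-to-model TV score is below
   0.01 are merged (largest partner's label, `+merged` suffix).  A bin
   that shrank and found no merge partner — the signature of a bin whose
   oligonucleotide profile duplicates another's — is deleted and its
   contigs freed.  Round 2 repeats the conservative assignment against
   the revised bins.
4. **Final classification.**  Every contig ≥ 1000 bp goes to its
   best-scoring bin with no veto.  Exact ties go to the lexicographically
   smallest label and are logged.

Every decision (contig, best bin, best and second score, outcome) is
logged per round; identical inputs reproduce the log exactly.

**Coverage clusters.**  Within a bin, read-coverage modes are found by a
Gaussian kernel density on log2 coverage (bandwidth 0.5 log2 units,
contig-length weights, grid resolution bandwidth/25); each local maximum
is a mode and density minima between modes delimit basins.  Each basin is
reported with its mode coverage, coverage interval, total bp, N50 and
length-weighted mean GC.  The original analysis picked these clusters by
eye per bin; the kernel rule is an explicit, reproducible surrogate for
that judgement, not a claim about the optimal bandwidth.

## Genome statistics

*Completeness* of a reconstruction is the weighted fraction of a 54-gene
single-copy marker set present, with the 30 ribosomal markers counted at
1/30 weight each because ribosomal proteins co-occur in a few large
operons and are not independent evidence; the default denominator is
24 + 30/30 = 25.  The bundled marker list is a documented stand-in with
the correct 54/30 structure.

*AAI* against a reference proteome keeps, per query gene, the single best
hit (highest bitscore; ties by identity, then subject id) and retains it
iff identity ≥ 30% over ≥ 70% of the query length ("length of the gene"
is interpreted as query protein length in residues); the AAI is the
unweighted mean of retained identities, reported as undefined — never
zero — when nothing passes.  Hit tables are consumed in the standard
12-column tabular alignment dialect (a 13th `qlen` column or a length
map supplies query lengths); for desk-scale proteomes the package
produces exact hit tables itself (local alignment, BLOSUM62, affine gap
open 11 / extend 1) so tests need no external aligner.

*Assembly statistics*: N50 is the largest contig length L such that
contigs ≥ L hold at least half the assembled bases; GC is computed over
non-N bases.

## Reference-database construction

Each called protein receives a reliability score.  The published formula
exists only as an unreproduced figure, so the score implements the stated
ordering rationale explicitly:

    total = log10(1 + contig_coverage) + w_len·log10(length_aa) − w_edge·[near_edge]

with default unit weights; higher coverage (fewer sequencing errors),
greater length (fewer truncations) and distance from contig ends
(complete gene models) all increase it.  `near_edge` is true when the
gene starts within 200 bp of the contig start or ends within 200 bp of
the contig end (a single flag, strand-agnostic, on nucleotide
coordinates).  A strict lexicographic comparator (coverage, length,
not-near-edge) is available as an alternative ordering.

Dereplication is greedy centroid clustering at 95% global identity:
records are processed in descending score; each joins the first existing
cluster whose representative it matches at ≥ 95% (identity = matches over
alignment columns of a global alignment; gaps count against), else founds
a cluster.  Representatives are thus the highest-scoring members by
construction.  A 5-mer prefilter (shared fraction of the shorter
sequence's 5-mers ≥ 0.5) skips pairs that cannot reach the threshold; a
brute-force variant computing the full pairwise identity matrix serves as
the oracle in tests and is quadratic by design.

## Quantitative proteome statistics

**Rollup.**  Protein abundance per sample is the mean of the top
`ceil(0.33·n)` (minimum 1, so a protein with any unique peptide is never
discarded) most intense peptides among the n observed peptides mapping
*uniquely* to that protein; shared peptides contribute to nothing.

**Normalization** is division by two levels of median-of-ratios size
factors.  Within fraction k, the reference for protein i is the geometric
mean of its abundances over the fraction's replicates, computed on
proteins complete in that fraction; the factor for replicate j is the
median of `a_ijk / ref_i`.  Across fractions the same construction is
applied to per-fraction average abundances over the proteins complete in
*every* replicate of *every* fraction (the globally complete set, whose
count is reported).  Two exactness notes:

* After dividing by the factors, the median ratio to the (stored)
  reference is 1 exactly, by construction.
* Exact idempotence and the exact median-1 property cannot both hold for
  this estimator: rerunning the normalization recomputes the reference
  from normalized data, and the second-pass replicate factors all equal
  the geometric mean of the first-pass factors, which is 1 exactly only
  when replicate columns are scalar multiples of one vector.  On noisy
  data the second pass changes the matrix by a single global constant
  (typically within ~1% of 1) and nothing else; all downstream statistics
  are invariant to that constant.  The implementation keeps the literal,
  paper-faithful estimator rather than re-anchoring factors.

**Variance model.**  For every globally complete protein and fraction,
the sample mean and variance over replicates give one (m, v) point; a
power law `v = a·m^b` is fitted by ordinary least squares of log v on
log m over points with v > 0.  The law supplies pooled variance estimates
where censoring leaves too few observations.

**Censored differential test.**  Missingness is treated as
left-censoring: values absent because they fell below the detection
threshold.  Missing entries are imputed at a floor of 0.75× the lowest
observed normalized abundance (data-relative; an absolute floor can be
set instead — the original configuration used 10,000 against a lowest
observed value of 13,111, the same ~0.75 ratio).  Group variances follow
a hybrid rule: no missing values — the observed sample variance; exactly
one missing — the average of the (floor-imputed) sample variance and the
pooled power-law variance at the group mean; otherwise — the pooled
variance alone.  The published rule covers groups of three; for the
pooled 6-sample cellular group the uncovered middle cases (2+ missing
but 2+ observed) default conservatively to the pooled variance.  The
statistic is the Welch t comparing the supernatant replicates against
all cellular replicates combined, with Satterthwaite degrees of freedom
bounded below at 1; a protein is flagged when its supernatant/cellular
fold change (on censor-imputed means) is ≥ 2 and p < 0.05 (both
configurable).  Group-mean differences below a relative epsilon (1e-9)
are treated as exact nulls so that floating-point rounding on constant
proteins cannot manufacture a statistic.

**Enrichment.**  Per pathway/category, a 2×2 table of flagged/not ×
in/out over the background is tested with a two-sided Fisher exact test;
Benjamini–Hochberg q-values over all tested categories, significant at
FDR 0.10.

**Bin-level summary.**  Censor-imputed per-fraction protein means are
summed by phylogenetic bin and renormalized per fraction, giving the
relative contribution of each population to each culture compartment.

## Synthetic data: what it emulates, and what it does not

**Community.**  Each population has its own order-3 chain.  The baseline
is the i.i.d. model matched to the population's GC target; distinctness
is a Dirichlet perturbation of each transition row with concentration
`10 / composition_divergence` (divergence 0 reproduces the baseline
exactly).  At divergence 0.3 this yields between-population 4-mer TV
distances around 0.2, comparable to inter-genus tetranucleotide
separation in real assemblies.  Contig lengths are log-normal (median
8 kbp, log-sd 1.0) clipped to [1, 50] kbp; per-contig coverage is the
population mean times log-normal noise (CV 0.1, matching the tight
coverage clusters such communities show on a log axis); the 54 markers
are planted on random contigs, labelled with the population's taxon.
Not emulated: sequencing error, chimeric contigs, strain microdiversity,
repeat-driven misassembly, marker mislabelling.  Recovery rates measured
here are therefore upper bounds on real-assembly performance.

**Proteome.**  A proteins × (3 fractions × 3 replicates) design:
log-normal base abundances (natural-log mean 11.5, sd 1.8 — a realistic
four-decade dynamic range), per-protein fraction effects (log-sd 0.5,
first fraction as reference; specific effects can be planted, including
−∞ for true absence), log-normal replicate noise (log-sd 0.3, ~30% CV,
representative of label-free replicate variation), 2–8 peptides per
protein with log-normal response factors (10% shared between two
proteins), peptide-level noise with variance `0.01·mean²` (10% CV), and
hard censoring below a detection floor of 3×10⁴ (~25% missingness at
the default abundance scale).  Missingness is purely threshold
censoring, because that is the mechanism the statistics assume; a
missing-at-random dropout rate (default 0) exists for robustness tests.
Not emulated: spectral interference, retention-time drift, digestion
variability, identification error.

A consequence worth stating: with ~30% replicate CV and three
replicates, the Welch test on a fully censored cellular group has ~2
degrees of freedom, which caps its power at roughly 75–85% for
supernatant-only proteins regardless of fold change (the statistic tends
to √3/CV as fold grows).  The type-I error of the full pipeline on null
data is calibrated (≈0.05); the power of this specific scenario is
reported by the acceptance script as measured.

## Numerical and design choices

* Randomness: every generator is a pure function of its integer seed
  (NumPy PCG64); the pipeline derives stage seeds from one config seed.
* Coordinates are 1-based inclusive in every gene table.
* All tabular I/O is TSV with one header line, `#` comments and `NA`
  for missing; FASTA is wrapped at 80 columns; DNA is validated over
  {A,C,G,T,N} and upper-cased on read.
* Argmin ties in classification go to the smallest bin label; score
  ties in dereplication and best-hit selection break on sequence /
  subject id.  All such ties are deterministic and logged where they
  occur.
* Problem sizes in the test and acceptance workloads (3 Mbp genomes for
  recovery, 1.5 Mbp for the twin scenario, 2000-protein proteomes) are
  chosen so each check completes in seconds while leaving estimator
  noise well inside the asserted tolerances.

## Known limitations

* The exact dissimilarity formula and threshold scale of the original
  binning classifier are not published in text; the TV metric with the
  published 0.01 cutoff is a faithful-by-intent reconstruction, and the
  early conservative rounds are accordingly sparse at contig scale.
* The reliability-score functional form and the two size-factor
  formulas reproduce stated constructions, not published equations.
* The greedy dereplication matches greedy-centroid semantics at desk
  scale; it is not a bit-for-bit reimplementation of the published
  clustering tool's heuristics.
* Completeness is presence-based only; contamination/duplication are
  not estimated.
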