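# Methods

`apobec3kit` re-implements, as a tested library, the computational chain
that links a germline *APOBEC3B* (A3B) deletion polymorphism to
*APOBEC3A* (A3A) expression and the APOBEC mutational signature in oral
squamous cell carcinoma (OSCC): copy-number genotyping of the deletion
from exome depth, junction-aware quantification of the A3A_B fusion
transcript, bootstrap-NMF mutational-signature analysis with APOBEC
source attribution, and the downstream expression and survival
statistics.  Because the underlying patient data are controlled-access,
every stage is exercised on a synthetic cohort with recorded ground
truth; this note describes the models, their assumptions, the defaults,
and what the synthetic benchmarks do and do not demonstrate.

## The synthetic locus and cohort

The deletion polymorphism joins the A3A coding region to the A3B 3'UTR,
creating a fusion gene (A3A_B) whose transcript is sequence-identical
to A3A over its coding region and to A3B over its 3'UTR.  Everything
downstream — junction databases, read ambiguity, genotype-aware EM —
depends only on that sharing topology, so the simulated locus is a
parameterised miniature (~3 kb deletion, exons of 260–360 bp) rather
than the real ~29.5-kb hg19 region.  Two haplotype contigs are built
(the deleted one is the non-deleted one with the deletion interval
excised), plus a separate housekeeping contig with two spike-in
transcripts that are active in every sample and anchor the TPM
denominator.  A3B's coding sequence is a noisy copy of A3A's at a
configurable identity (default 0.92, in the range of the real
paralogs); the shared 3'UTR and coding segments are identical by
construction.

Cohort defaults are the study conditions of the motivating scenario:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 200 | cohort size |
| `deletion_allele_freq` | 0.5 | Hardy–Weinberg allele frequency (East-Asian-like) |
| `mean_depth` | 100 | WES depth, reads/base |
| `depth_dispersion` | 2.0 | variance/mean of per-window depth (gamma–Poisson) |
| `depth_noise_floor` | 0.02 | off-target depth floor inside a homozygous deletion |
| `read_length` | 151 | single-end RNA-Seq reads |
| `rnaseq_error_rate` | 0.002 | i.i.d. substitution errors per base |
| `mutations_per_sample` | 120 | somatic SNV burden |
| `signature_weights` | 40/37/23% | APOBEC / aging / smoking-like mixture |
| `yt_fraction_true` | 0.7 | A3A-like share of APOBEC-context mutations |
| survival | HR 0.5 (high vs low), 30% censoring | exponential proportional hazards |

Exome depth for a region is reported as the mean of many (25/50)
independent gamma–Poisson windows: a depth ratio over a multi-kilobase
region averages away most single-site noise, and modelling it as a
single negative-binomial draw would exaggerate the ratio spread far
beyond what region-level means show.  The inside-region mean is
`mean_depth * max((2 - c)/2, floor)` for c deletion-allele copies, so
the three genotypes sit at ratio means 1.0, 0.5 and the noise floor.

Mutations are drawn per sample from a multinomial over the 96
trinucleotide classes with probabilities proportional to `P·e_s`
(signatures times exposures) and placed at genome positions whose
context matches the class, on either strand of a random background
contig.  For APOBEC-context classes (C>T/C>G at TCW) the −2 base
encodes the deaminase preference: TCA-class mutations receive a
pyrimidine (Y) at −2 with probability `yt_fraction_true`, TCT-class
mutations with the complementary probability.  This is the feature that
distinguishes A3A-driven (YTCA-enriched) from A3B-driven
(RTCA-enriched) catalogs; a generator that used one Y-probability for
both TCA and TCT would make the per-sample YTCA/YTCW and RTCA/RTCW
fractions equal in expectation and the attribution test powerless.

RNA-Seq reads start uniformly along each transcript, with per-transcript
counts proportional to molar abundance × effective length.  Abundances
couple to genotype by allele dosage: A3A and A3B scale with the intact
haplotype count (2−c), A3A_B with c, and tumor tissue multiplies the
A3A-promoter transcripts by 8.3× and A3B by 3.2×.  Read names carry
truth tags (`sample|tissue|transcript|start|serial`) that analysis code
never reads; they exist for tests only.

Not emulated: GC and capture bias, indels, quality decay, paired-end
fragments, transcription-strand asymmetry, subclonality.  Passing
benchmarks therefore demonstrate correctness of the algorithms under
their own modelling assumptions, not performance on real sequencing
artifacts.

## Deletion genotyping

The depth-ratio genotyper is a three-component Gaussian mixture on the
per-sample ratio r, fitted by EM with the component means
order-constrained (relabelling after each M-step) and initialised at
(0.02, 0.5, 1.0).  Means, variances and weights are re-estimated —
fixed means would break under capture-efficiency bias inside the
region — with a variance floor of 1e-8 for empty components.
Convergence is declared when the log-likelihood improves by less than
1e-8 (cap 1000 iterations); the trace is asserted non-decreasing.
Mixing weights carry no Hardy–Weinberg prior; HWE adherence is reported
as a diagnostic chi-square instead.  Calls are posterior argmax (ties
broken toward the heavier component); samples with maximum posterior
below 0.9 are flagged low-confidence but still called, and samples with
zero control depth are flagged uncallable rather than dropped.

In-silico PCR places primer pairs by exact IUPAC matching (no
mismatches, since no mismatch tolerance is defined for the assay) and
reports product length from the forward primer start to the reverse
primer 3' end; the two allele-specific pairs reproduce the three gel
band patterns (wild-type only / both / deletion only).

## Junction database, read assignment, fusion detection

The junction database stores `read_length − 1` bases of exonic sequence
on each side of every annotated splice junction (150 bp for 151-bp
reads).  Flanks are cut from the spliced transcript sequence, which
makes the extension rule — continue into the next exon when an exon is
shorter than a flank — automatic; junctions closer than one flank to a
transcript end are skipped with a warning.

Reads are assigned by a deliberately simple ungapped aligner: exact
31-mer seeds at three offsets (pigeonhole-safe for ≤ 2 mismatches on
151-bp reads), full-length mismatch counting on both strands, hits kept
at ≤ 2 mismatches.  A read is *unique* iff exactly one hit attains the
best mismatch count.  Duplicate removal — per (reference, offset,
strand), keep the best-scoring read — is applied on the detection-side
alignment only, mirroring how duplicate marking precedes junction
inspection in a BAM-based workflow; quantification keeps every read,
as abundance estimators do, because collapsing to one read per start
position destroys depth-proportionality at realistic coverage.

A fusion event is reported when at least 2 uniquely mapped reads cover
the A3A_B junction point with ≥ 8 bases of overhang on each side, the
alignment references being the haplotype genomes plus the junction
database (so a junction-spanning read has nowhere unique to go except
the junction entry).  Both thresholds are package choices, set for
robustness against edge alignments.

## Genotype-constrained EM quantification

Reads are collapsed into equivalence classes by the set of transcripts
compatible with their best hits.  The genotype fixes the active set:
c = 0 excludes A3A_B; c = 2 excludes A3A and A3B (the deletion removes
the A3A 3'UTR, so a homozygous carrier has no intact copy of either
gene); spike-ins are always active.  The EM treats the per-transcript
read fraction as the parameter, allocating each class across its
compatible active transcripts proportionally to (read fraction /
effective length); reported θ is the molar fraction and TPM = θ × 10⁶.
Effective length is transcript length − read length + 1, floored at 1.
Convergence: max-change in θ below 1e-8, cap 1000 iterations, uniform
initialisation; the observed-data log-likelihood is asserted
non-decreasing.  Gene-level A3A is reported as A3A + A3A_B (identical
protein product).  Running a homozygous-deletion sample with the
non-carrier transcript set mis-assigns the shared 3'UTR reads to A3B —
kept as a regression test, since that mis-assignment is precisely why
genotype-aware quantification matters.

## Mutational signatures

Catalogs are 96 × S count matrices in COSMIC class order
(substitution-major C>A…T>G, then 5' and 3' flanks in A,C,G,T order);
purine-reference SNVs are reverse-complemented onto the pyrimidine
strand, non-SNVs are skipped and counted, and records whose context
contradicts the reference base are rejected and logged.

Extraction follows the bootstrap-stabilised NMF scheme: each bootstrap
resamples every sample's mutations multinomially (totals preserved),
runs multiplicative-update NMF under generalized Kullback–Leibler
divergence (floor 1e-12, cap 10,000 updates, stop at relative
improvement < 1e-8 over 10 iterations, best of `n_restarts` random
starts), and contributes k unit-sum signatures.  Pooled bootstrap
signatures are partition-clustered on cosine distance under a
one-signature-per-run constraint: each run's k vectors are assigned
bijectively to the k clusters (Hungarian matching against the current
centroids), so a cluster can never absorb two signatures from the same
run.  The constraint is what makes stability discriminate — a spurious
extra component collects each run's unstable leftover vector and its
silhouette collapses.  *Stability* s(k) is the average silhouette width
of that clustering (for k = 1,
the mean cosine similarity to the centroid).  K is the largest k in the
scanned range with s(k) ≥ 0.85; if none qualifies the argmax is
returned with a below-cutoff flag.  Reported signatures are cluster
centroids; exposures are refit on the original catalog by fixed-
signature multiplicative KL updates — the Poisson-matched loss — rather
than nonnegative least squares, which underweights the many low-count
classes of diffuse signatures and biases category fractions by several
points.  The standalone NNLS refit remains available
(`refit_exposures_nnls`) for the per-sample burden used in
exposure–expression correlations.

Matching against a reference catalog (a user-supplied 96-row TSV, or
the bundled *synthetic* six-signature analog set used by the tests)
takes the cosine-nearest reference per extracted signature; category
contributions (APOBEC = 2/13, aging = 1A/1B, smoking = 4/5, other)
sum per-sample-normalised exposures within categories, and the cohort
value is the mutation-count-weighted mean.

Known limitation: a diffuse, near-flat signature (the 5-like clock
profile) cannot be recovered at high cosine from catalogs of a few
hundred mutations per sample — the flattest NMF component
systematically absorbs the nonnegative Poisson residual, an effect we
reproduced with an independent NMF implementation and which selecting
restarts by divergence makes worse, since better bootstrap fits are
better noise fits.  The recovery benchmark therefore uses three sharp,
well-separated analogs (APOBEC C>T, APOBEC C>G, aging CpG); flat
signatures still participate in cohort mixtures, where their *category
fraction* (driven by the KL exposure refit) remains accurate even when
their profile cosine is not.

YTCA/RTCA attribution counts C>T/C>G mutations at TCA and TCW on the
pyrimidine strand, split by the −2 base (Y vs R) read from the genome,
and compares the per-sample YTCA/YTCW and RTCA/RTCW fractions with a
two-sided Wilcoxon rank-sum test (exact when both groups have ≤ 12
samples and no ties; otherwise the normal approximation with tie and
continuity corrections).  Samples with an empty denominator are
excluded and reported.

## Clinical statistics

Expression stratification splits at the median, with values equal to
the median assigned to the low group (a fixed tie rule; the convention
is otherwise arbitrary).  Kaplan–Meier estimation and the log-rank test
are delegated to lifelines (Greenwood variance computed from the event
table); Cox proportional hazards uses the statsmodels partial
likelihood with Efron tie handling by default and Breslow as an option.
Zero-variance covariates are reported with β = 0 and a flag, collinear
designs are flagged via conditioning, and non-convergence or monotone
likelihood produces a flagged result rather than silent output.  The
2×2 tests are closed-form: Yates-corrected chi-square with the
correction clipped at zero (`max(0, |O−E|−0.5)²/E`, 1 df), uncorrected
Pearson, and Fisher's exact two-sided test; zero-margin tables return
p = 1 with a degenerate flag.  p-values are kept at full precision
internally and rounded to 3 decimals only in the report layer.

Differential expression applies three filters: median TPM > 0.5 across
all libraries, a paired t-test (or paired Wilcoxon) on log2(TPM+1) with
Benjamini–Hochberg adjustment, and |fold change| > 2; a gene passes
only if all three hold.

## Pipeline and reproducibility

`run_pipeline` executes simulate → genotype → quantify → signatures →
clinical under a single root seed; each stage derives a stable child
seed from the root seed and the stage name, so runs are byte-identical
given the same config and stage failures are attributed by name without
corrupting earlier outputs.  The run report records per-stage status,
SHA-256 checksums of every analysis output and the headline numbers.

Problem sizes in the shipped benchmarks — 200 samples at 100× for
genotyping, 200 × 500 mutations with 30 bootstraps and 2 restarts for
signature extraction, 50,000 reads for quantification recovery, 1000
replicates for the log-rank null — were chosen so the full suite and
the acceptance script each complete in a few minutes on one CPU while
keeping Monte-Carlo standard errors small relative to the tolerances
they are checked against.
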