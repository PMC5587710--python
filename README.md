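# apobec3kit

Analysis toolkit for the computational chain that links a germline
*APOBEC3B*-deletion polymorphism to *APOBEC3A* expression and the
APOBEC mutational signature in oral squamous cell carcinoma (OSCC),
written for researchers who want each stage of that chain as a tested,
reusable library rather than a one-off script collection.

The ~29.5-kb deletion fuses the *APOBEC3A* (A3A) coding region to the
*APOBEC3B* (A3B) 3'UTR, creating the *A3A_B* fusion gene whose
transcript is sequence-ambiguous with both parents.  The package
implements:

* **Deletion genotyping from exome depth** — the ratio
  r = depth(inside deletion) / depth(control) clusters near 1, ½ and a
  noise floor for the three genotypes A3B+/+, A3B+/−, A3B−/−; an
  order-constrained three-component Gaussian mixture fitted by EM
  returns copy-number calls c ∈ {0,1,2} with posteriors, plus in-silico
  PCR of allele-specific primer pairs.
* **Junction-aware fusion quantification** — a splice-junction sequence
  database (read_length − 1 flanks), a k-mer seeded ungapped read
  aligner with uniqueness and duplicate-removal rules, detection of
  reads spanning the A3A_B fusion junction, and an EM over
  read–transcript compatibility in which the genotype constrains the
  active transcript set (TPM output; gene-level A3A = A3A + A3A_B).
* **Mutational signatures** — 96-class trinucleotide catalogs
  M ≈ P·E with P (96 × K, column-stochastic signatures) and E (K × S
  exposures) extracted by bootstrap-stabilised KL-NMF; the number of
  signatures K is the largest k whose bootstrap-cluster silhouette
  stability s(k) ≥ 0.85; cosine matching to a reference catalog,
  per-category contribution sums (APOBEC / aging / smoking / other) and
  the YTCA-vs-RTCA tetranucleotide attribution that separates A3A-like
  from A3B-like activity.
* **Clinical statistics** — median-split stratification, Kaplan–Meier /
  log-rank / Cox proportional-hazards survival analysis (Efron or
  Breslow ties), Yates-corrected 2×2 tests, and the differential
  expression filter chain (median TPM > 0.5, BH-adjusted p < 0.05,
  fold change > 2).
* **A synthetic cohort generator** with known ground truth — Hardy–
  Weinberg genotypes, copy-number-proportional exome depth, RNA-Seq
  reads from the three partially identical transcripts, signature-
  mixture mutation catalogs with controlled YTCA/RTCA composition, and
  proportional-hazards survival times — so the whole chain runs and is
  tested without any controlled-access download.

The EM mixture genotyper and the bootstrap NMF are also exposed as
scikit-learn-style estimators (`DepthRatioGenotyper`,
`BootstrapSignatureNMF`) with `fit` / `predict` / `transform` and
trailing-underscore fitted attributes.

## Worked example

An end-to-end run on a simulated 60-patient cohort (1000 reads per
library, 400 somatic SNVs per tumor, default 40/37/23 APOBEC/aging/
smoking signature mixture, deletion-allele frequency 0.5):

```python
from apobec3kit.pipeline import run_pipeline

report = run_pipeline({
    "outdir": "demo",
    "seed": 11,
    "simulate": {"n_samples": 60, "n_reads_per_library": 1000,
                 "mutations_per_sample": 400, "context_genome_len": 30000},
    "signatures": {"k_range": [1, 2, 3, 4], "n_bootstraps": 20, "n_restarts": 2},
})
print(report["headline"])
```

which completes in under a minute and prints

```
{
 "genotype_concordance": 1.0,
 "allele_freq_estimate": 0.55,
 "genotype_counts": {"A3B+/+": 14, "A3B+/-": 26, "A3B-/-": 20},
 "fusion_positive_tumors": 46,
 "chosen_k": 4,
 "category_fractions": {"APOBEC": 0.4704, "aging": 0.3297,
                        "smoking": 0.2, "other": 0.0},
 "ytca_fraction": 0.6956827780384796,
 "logrank_p": 0.410451785210844,
 "cox_hr_high_expression": 0.7835044927167969
}
```

Reading the numbers: every sample's deletion genotype was recovered
from depth ratios (concordance 1.0; the estimated allele frequency 0.55
is the cohort's realised frequency); all 46 tumors carrying at least
one deletion allele — and no non-carrier — show reads spanning the
A3A_B fusion junction; stability-based selection kept four signatures
whose category contributions (47% APOBEC, 33% aging, 20% smoking)
recover the generated 40/37/23 mixture within sampling error; 70% of
APOBEC-context mutations sit in the A3A-like YTCA context, matching the
generator's setting of 0.7; and the survival stage estimates a
protective hazard ratio (0.78) for high A3A expression on this small
cohort (the generator's HR is 0.5; the log-rank p of 0.41 reflects the
low event count at n = 60, not a method failure).  Per-stage outputs
(genotype calls, TPM matrix, fusion counts, 96-class catalog,
signatures, exposures, KM curves, run report with checksums) are
written under `demo/`.

The same stages are available individually — e.g. genotyping a depth
table from the shell:

```bash
a3kit genotype --depths depths.tsv --out calls.tsv --summary fit.json
a3kit clin crosstab --counts 87,85,7,9        # -> {"statistic": 0.068, "p": 0.794, ...}
```

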