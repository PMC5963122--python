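# Methods

## Model and assumptions

`exocascade` prioritizes candidate variants in cohorts of unrelated patients
under an autosomal-dominant hypothesis: a single heterozygous variant is a
sufficient candidate, so all filtering starts from heterozygous calls and no
compound-heterozygote or recessive logic is applied. The cascade consumes a
multi-sample VCF with per-sample GT, AD, DP and GQ, and per-variant
annotations (population MAFs, ten categorical predictor verdicts, CADD Phred
and REVEL scores) supplied as INFO keys or a sidecar TSV keyed by
chrom:pos:ref:alt; it does not compute any score itself.

The false-positive-heterozygote screen assumes that a genuine heterozygote's
allele depths are an approximately symmetric split of the site depth
(AD1 ~ Binomial(DP, ½)), while artifact heterozygotes — truly homozygous
sites miscalled het — show a systematically skewed minor-allele fraction.
The screen therefore accepts a het call iff DP ≥ `dp_min` and
|AD1 − AD2| / DP < `ratio_max`. AD1 + AD2 is not required to equal DP, and
the two depths are used exactly as ordered in the AD field (the statistic is
symmetric, so ordering cannot matter; this is property-tested).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `gq_min` | 99 | minimum Phred-scaled genotype quality (VCF caps GQ at 99, so the bound is inclusive; a strict reading would select nothing) |
| `dp_min` | 50 reads | minimum site depth, inclusive |
| `ratio_max` | 0.3 | strict upper bound on \|AD1 − AD2\|/DP |
| `maf_max` | 0.01 | inclusive rarity bound per consulted database |
| `maf_databases` | kg1000, esp | databases consulted by the rarity gate; exac and gnomad can be added by config |
| `consensus_k` | 4 of 10 | damaging votes required; `unknown` and `tolerated` both count as non-damaging (a strict-exclusion stance) |
| `cadd_min` | 20 (strict) | CADD Phred; >20 marks the top 1% most deleterious substitutions |
| `revel_min` | 0.75 (inclusive) | REVEL high-specificity cutoff for rare missense variants |
| `func_classes_kept` | missense, nonsense | classes admitted to annotation stages |
| `missing_score_policy` | fail | how the combined gate treats a missing CADD or REVEL; `pass_if_nonsense` exists because truncating variants are unscored by several missense-only predictors |

Thresholds are compared on full-precision values; two-decimal ratios are a
display convention only. Boundary semantics follow the rule as stated:
depth and REVEL bounds inclusive, balance and CADD bounds strict.

## The synthetic cohort

The generator emulates exactly what the cascade can observe, with a single
seeded RNG stream consumed in (variant, sample) order so identical
parameters give byte-identical files.

* **Depths** — negative binomial with mean 100 and dispersion 10
  (`dp_dispersion = 0` fixes depth at the mean, used for calibration runs).
  The mean is placed above the screen's 50-read floor so the reference
  operating range (depths ~50–130) is well represented.
* **Genotypes** — per call: 8% true hets (AD1 ~ Bin(DP, ½)), 2% artifact
  hets (minor depth ~ Bin(DP, 0.1)), the rest homozygous. These fractions
  give each site a handful of carriers in a 48-sample cohort — an
  approximation of a rare-variant exome chosen for testability; real rare
  variants are mostly singletons. The artifact mechanism is modeled only as
  a skewed allele-fraction draw: the screen sees nothing but AD and DP, so
  mapping error, index hopping etc. are indistinguishable to it.
* **Quality** — GQ is 99 except for a 5% low-GQ decoy fraction that
  exercises the primary filter.
* **Frequencies** — 10% of variants are novel (absent from all databases);
  the rest draw a base frequency that is rare (≤1%, beta-tailed toward 0)
  with probability 0.7, otherwise common; per-database values jitter ±20%
  around the base and are present with probability 0.85.
* **Scores** — a latent per-variant damaging indicator couples the ten
  predictor verdicts, CADD and REVEL: each channel follows the shared
  indicator with probability `score_correlation` (default 0.7) and redraws
  independently otherwise. Damaging variants draw CADD ~ N(28, 5) and
  REVEL ~ Beta(8, 2); benign ones N(9, 6) and Beta(1.2, 8). Scores are
  rounded at generation (CADD 2 dp, REVEL 3 dp, MAF 6 dp).
* **Planted candidates** — `n_planted` variants are constructed to pass
  every default filter (balanced het with DP ≥ 60 and GQ 99 in one carrier,
  all MAFs ≤ 0.01 or absent, ≥4 damaging votes, CADD in 22–35,
  REVEL in 0.78–0.98, missense, gene drawn from the bundled example lists).

What passing tests on this cohort do **not** show: robustness to real
artifact structure (strand bias, mapping quality, batch effects), linkage
or haplotype structure, indel representation differences, annotation-version
drift, or realistic carrier-count distributions. The generator validates the
logic and calibration of the filters, not their field performance.

## Numerical and design choices

* **Order invariance.** All stages are conjunctive predicates; the staged
  survivor set is tested to equal a one-shot conjunction on random cohorts.
  The staged form exists to produce the funnel report.
* **Per-call vs per-variant stages.** Primary selection and the het screen
  are per-call; a variant survives if at least one call survives, and those
  calls define the carriers counted per stage. Annotation stages are
  per-variant.
* **Missing data.** Missing FORMAT fields are kept as missing, never zero;
  a call missing GQ/DP fails primary selection, one missing AD fails the
  screen (`missing_fields`). A variant absent from all consulted frequency
  databases is novel and treated as rare. A wholly missing annotation
  bundle fails consensus (0 votes) and, under the default policy, the
  combined gate. Runs abort when annotation is missing for more than
  `max_missing_annotation_fraction` (default 0.5) of variants, since the
  downstream gates would silently eliminate everything.
* **Screen verdict order.** The failure reason records the first criterion
  failed in the order not_het → missing_fields → low_dp → high_imbalance.
* **Degenerate inputs.** DP = 0 makes the balance ratio undefined
  (`allele_balance` raises; in classification the call simply fails the
  depth bound first). Empty cohorts run cleanly and produce all-zero
  reports; evaluating the screen on an empty cohort is an error rather than
  a NaN.
* **Biallelic only.** The balance statistic is defined for exactly two
  alleles; multiallelic records are skipped with a logged warning and
  counted. Split multiallelics upstream (e.g. `bcftools norm -m-`) to
  retain them.
* **Float fidelity.** VCF INFO floats pass through htslib's float32; on
  read the shortest decimal representation of the float32 is recovered, so
  values with ≤6 significant digits round-trip exactly. The sidecar TSV
  carries full-precision text and takes precedence over INFO on conflict.
* **Gene selection.** Keyword gene sets are explicit input files (exact,
  case-insensitive symbol match, no alias resolution) rather than a
  literature-network query: transparent and versionable, at the cost of
  fidelity to any proprietary curation. The bundled PD/neuron lists are
  small illustrative examples.
* **Same-gene recurrence.** A patient carrying two distinct surviving
  variants in one gene is reported, not filtered: under a dominant model it
  is a flag for follow-up, not an exclusion criterion.

## Problem sizes

The test suite and acceptance script use simulated cohorts of 20–2,000
variants and 3–50 samples (10,000 calls for screen calibration, 100 random
1,000-variant cohorts for the order-invariance check, 20 seeds for planted
recovery, 50 cohorts for round-trip fidelity) — sizes chosen so the full
validation runs in minutes on one CPU while keeping Monte-Carlo standard
errors small enough for three-sigma oracle comparisons.

## Known limitations

* Thresholds are consumed as given; no data-driven recalibration,
  sensitivity analysis, or strand-bias/mapping QC is provided.
* Indels are accepted but their functional-class assignment is delegated
  entirely to the annotation source.
* The patient-level summaries count het carriers of selected variants; with
  simulated carrier fractions above real rare-variant levels, percentages
  are illustrative rather than comparable to a real cohort.
* No liftover, normalization, BCF/gVCF or structural-variant support.
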