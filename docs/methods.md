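# Methods

`cnvland` implements the desk-scale analysis of a clinical chromosomal-
microarray (CMA) cohort: raw CNV/LOH calls are size-filtered, annotated with
population frequency by reciprocal overlap against a control cohort,
classified into pathogenic / VOUS / benign by a deterministic evidence
cascade, and summarised into gene-level candidates and cohort burden
statistics. A seeded synthetic-cohort generator emulates the structure of a
212-patient neurodevelopmental-disorder (NDD) cohort so that every stage is
testable without access to raw microarray data.

## Coordinates and interval arithmetic

Coordinates are 1-based as printed in clinical reports; the length of
`chrom:start-end` is `end - start`. Applied to printed report coordinates
this convention reproduces the sizes quoted next to them (e.g.
chr15:22,838,642-28,314,382 → 5,475,740 bp = 5.476 Mb), and it makes overlap
arithmetic closed-form. BED input/output converts to and from 0-based
half-open coordinates.

Reciprocal overlap (RO) of two intervals is `min(o/len_a, o/len_b)` where
`o` is the intersection length; a pair *matches* when RO strictly exceeds
the threshold (default 0.5, i.e. ">50% reciprocal overlap"). The minimal
critical region of a set of same-chromosome intervals is `[max(starts),
min(ends))`; for 1-D intervals pairwise intersection implies a common point,
so the maximal mutually-overlapping patient groups found by the shared-region
sweep always have a non-empty critical region.

A variant is *subtelomeric* when it starts within `w` bp of position 1 or
ends within `w` bp of the chromosome end. Published CMA reports label
subtelomeric variants without stating a positional window, and no single
window reproduces such label sets exactly; `w` is therefore configuration
(default 5 Mb) and the subtelomeric yield of a cohort (reported values such
as 2.83% of patients) is not treated as a reproduction target.

## Filtering and frequency annotation

Size filters reflect the resolution floor of SNP-array calling: deletions
< 30 kb and duplications < 50 kb are excluded (boundary kept), and LOH runs
are kept only in the closed 2–10 Mb window (shorter runs are noise on a
low-resolution array; longer ones usually reflect whole-arm events or
genotyping artefacts).

Each surviving call receives:

* a **control frequency** — the fraction of control-cohort *samples*
  (default denominator 9,689 at study scale; the generator's scaled default
  is 500) carrying ≥ 1 same-type call with RO > 0.5; a sample with several
  matching calls counts once, so the statistic is invariant to duplicated
  calls within a sample;
* a **cohort frequency** — the same statistic within the patient cohort.
  The *reported* value is the observed fraction (a singleton prints 1/212 =
  0.00472 because a call matches itself). The *rarity rule*, however, is
  leave-one-out: a variant cannot count as evidence of its own commonness,
  so the rule compares the fraction of other patients carrying a match.
  With self-inclusion, a recurrent pathogenic variant seen in three of 212
  patients (observed frequency 1.42%) would be forced benign, contradicting
  how such variants are classified in practice; leave-one-out (2/212 =
  0.94%) retains them.

A call is **rare** when every frequency source (controls, optional second
control table, leave-one-out cohort) is strictly below the cut-off (default
1%, "frequency < 0.01"). Calls common in any source are excluded from
clinical interpretation.

## Classification cascade

Clinical ACMG-style CNV interpretation is a curation exercise over external
databases; this package implements a transparent deterministic surrogate
over locally supplied annotation (syndrome regions, dosage-sensitive /
imprinted / CEG gene flags), with every decision recorded as an evidence
code. First match wins:

1. not rare → benign (`COMMON_VARIANT`);
2. RO > 0.5 with a syndrome region applicable to the call's type →
   pathogenic (`SYNDROME_REGION_MATCH`);
3. deletion fully containing a dosage-sensitive gene → pathogenic
   (`DOSAGE_GENE_HIT`);
4. LOH → VOUS (`LOH_EVENT`; `IMPRINTED_GENE_HIT` appended when imprinted
   genes are exonically hit — extended homozygosity over an imprinted locus
   is compatible with uniparental disomy);
5. ≥ 1 exon of ≥ 1 gene hit → VOUS (`GENE_CONTENT`);
6. otherwise → benign (`NO_GENE_CONTENT`).

This is deliberately *not* the quantitative ACMG/ClinGen point system: the
goal is a reproducible, auditable mapping whose evidence codes make every
label explainable from the local annotation tables.

Cohort accounting counts a patient once per class when carrying ≥ 1 call of
that class (a patient can appear in several classes), and percentages are
rounded half-up to two decimals.

## Gene-level analyses

A gene is **disrupted** when a variant overlaps ≥ 1 bp of ≥ 1 exon;
intron-only overlap does not count (exon-sparing variants leave transcripts
intact, and published candidate-gene counting excludes them). Span-level
overlap is available separately for descriptive counts.

* **CEG burden**: per-call count of distinct critical-exon genes (CEGs —
  genes with exons highly expressed in brain and under low population
  mutation burden) exonically hit, with per-class totals, unique-gene counts
  and means. Only DEL/DUP calls enter the burden: it is a dosage metric, and
  the published per-class CNV denominators exclude LOH. The CEG list itself
  is an input flat file; the published list is proprietary, so unique-CEG
  counts from the original study (153 pathogenic / 31 VOUS) are not
  reproduction targets.
* **Focal candidates**: pathogenic/VOUS DEL/DUP calls under 1 Mb with ≥ 1
  exonic CEG, sorted by size — the strongest single-gene candidates.
* **Shared critical regions**: maximal groups of mutually-intersecting
  same-type calls from ≥ 2 distinct patients, each reduced to its minimal
  critical region with the exonically-hit genes inside it (the mechanism
  behind reports such as a 7.7 kb shared-deletion region over a single
  proteasome-subunit gene, or a 38.4 kb shared-duplication region over two
  genes).
* **LOH / consanguinity burden**: per-patient LOH counts and mean lengths by
  parental consanguinity, compared with Welch's t-test; patients with
  unknown status are excluded and counted. Offspring of consanguineous
  unions show elevated counts (the emulated rate is 12.95 LOH/patient) and
  longer runs.
* **Imprinted-gene LOH**: LOH calls exonically hitting ≥ 1 imprinted gene,
  with the distinct-gene union.

## Statistics

* **Fisher's exact test** (2×2): two-sided p by the sum-of-small-
  probabilities convention (delegated to `scipy.stats.fisher_exact`, which
  implements exactly that; an exhaustive hypergeometric enumeration over all
  tables with total ≤ 60 verifies agreement to 1e-12). The odds ratio is
  the sample cross-product `(a·d)/(b·c)`; with any zero cell the
  Haldane–Anscombe +0.5 correction is applied to the OR (flagged) while the
  p-value uses the uncorrected table. On the published carrier tally
  (16 female / 10 male carriers against 67 F / 145 M) the OR is 4.235 →
  4.2 as printed; the two-sided Fisher p on that same table is 0.0011, not
  the printed 0.0007, which likely reflects a different table orientation or
  test variant in the original analysis — the OR, not the p, is treated as
  the checkable quantity.
* **Welch's t-test**: unequal-variance statistic with Welch–Satterthwaite
  degrees of freedom; degenerate inputs (n < 2 or zero variance) raise an
  error naming the offending group. A 10,000-replicate null simulation
  keeps the empirical type-I error within [0.045, 0.055] at α = 0.05.
* **Over-representation**: upper-tail hypergeometric p per gene set;
  Benjamini–Hochberg adjustment runs across the sets surviving the size
  window (strictly more than 50 and fewer than 1,000 genes), and the
  ≥ 5-overlap rule acts as a report filter, not part of the multiplicity
  family. Significance requires p < 0.001 and FDR < 0.01. Enrichment
  p-values from specific published runs depend on pathway-database versions
  and are not reproduction targets.
* **ddPCR quantification**: λ = −ln(1 − k/n) for k positive of n droplets;
  copies/µL = λ / droplet volume (default 0.00085 µL, an instrument
  constant exposed as configuration); diploid copy number =
  2·λ_target/λ_reference. Saturated wells are rejected. Wet-lab validation
  rates (e.g. 8/9 assays confirming) are experimental outcomes, not
  computable targets.
* **ADOS-2 comparison**: Welch tests on each score component between
  patients carrying ≥ 1 rare duplication and patients with no clinically
  rare variant; components with a group under two scored patients are
  skipped with a reason.

## Synthetic cohort generator

The generator emulates the study conditions of a 212-patient NDD CMA
cohort; its defaults *are* those conditions and are not tuned per run:

| parameter | default | source/rationale |
|---|---|---|
| patients | 212, 145 male / 67 female | cohort composition |
| consanguinity | status known for 109; 26 consanguineous | 23.85% (26/109) of families |
| pathogenic carriers / calls | 26 / 27 | one patient carries a double terminal deletion |
| VOUS carriers | 121 | 57.08% carrier rate |
| control cohort | 500 samples (9,689 at study scale) | scaled down for desk-scale runs; size is configuration |
| LOH rate, consanguineous | Poisson mean 12.95/patient | published rate |
| LOH rate, outbred | Poisson mean 1.0/patient | chosen so the expected cohort total ≈ 528 LOH calls (26·12.95 + 186·1.0 ≈ 523) |
| ADOS effect | +1.5 severity, +2.5 social affect for duplication carriers | produces the reported direction of effect at realistic magnitude |
| genome | 3 chromosomes, 60 Mb, 300 genes | toy default; full hg38 lengths bundled for real data |
| gene flags | CEG 15%, imprinted 6%, dosage-sensitive 6% | plausible flag densities on a gene-dense toy genome |
| size mixtures | per-class/type truncated log-normals | medians set to the reported per-class size scales (pathogenic ≫ VOUS; VOUS DEL ≈ 110 kb, VOUS DUP ≈ 300 kb) |

Planted mechanisms: pathogenic calls either match a syndrome region with
RO > 0.55 (at most two carriers per region, so the leave-one-out cohort
frequency stays below 1%) or are deletions fully containing a
dosage-sensitive gene; common calls are catalogue loci replicated into
> 1.2% of control samples; VOUS calls are rare exon-hitting variants;
most LOH is drawn from a common run-of-homozygosity pool (consanguineous
patients preferentially draw long loci), and a configurable slice of VOUS
carriers' LOH is rare, half of it placed over imprinted genes. Every rare
placement is rejection-sampled against syndrome regions, the common
catalogue and other rare plants so that planted labels stay recoverable;
when a dense toy genome leaves no rare-compatible position for an LOH run,
the draw falls back to a common locus (keeping the per-patient Poisson
count intact).

One integer seed drives a named substream per component
(`numpy.random.SeedSequence((seed, stream))`), so adding a component never
perturbs the others and identical seeds give byte-identical outputs.

What the generator does **not** emulate: probe-level intensities and
B-allele frequencies, call-quality artefacts (the 775.77 kb false-positive
class that ddPCR validation catches), breakpoint uncertainty, mosaicism,
sex-chromosome calls, and genuine linkage structure between loci. Passing
tests therefore demonstrate the correctness of the analysis machinery under
the cohort's statistical structure, not the behaviour of upstream CNV
calling on real arrays.

## Numerical and reporting choices

* Percentages round half-up to two decimals; Mb/kb formatting rounds
  half-up at the requested precision.
* Rarity and RO thresholds are strict inequalities (> 50% RO, < 1%
  frequency); size-filter boundaries are kept inclusive.
* Report TSVs are written with fixed column order and row sort keys, so a
  rerun from identical inputs is byte-identical; the run manifest records
  stage-by-stage counts and conservation checks.
* Default run sizes (full 212/500 synthetic cohort for acceptance runs, a
  110-patient cohort for unit fixtures) keep the whole suite in the
  seconds-to-minutes range on one CPU.

## Known limitations and non-reproducible published values

* The evidence cascade is a surrogate for expert ACMG curation; on real
  data it will under-call pathogenic variants whose evidence lives in
  literature or databases rather than in the local annotation tables.
* Published mean pathogenic CNV sizes (5365.26 kb for deletions,
  17,451.72 kb for duplications) disagree with the arithmetic means of the
  printed per-call deletion sizes (5,685.5 kb for the 16 deletions); the
  package reports its own means and does not chase the printed values.
* The published CEG-burden t statistic (t = 4.33) requires per-CNV CEG
  vectors that were never printed; only the per-class means (7.50 and 0.19)
  are checkable, and those are exercised on constructed fixtures.
* Published subtelomeric yields (2.83% pathogenic, 20.28% VOUS) depend on
  an unstated subtelomere definition that no positional window reproduces;
  the window is configuration and these counts are not targets.
* Published enrichment p-values and the ddPCR validation rate depend on
  database versions and wet-lab outcomes respectively.
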