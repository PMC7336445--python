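# Methods

## Problem setting

Matched FF/FFPE pairs from the same tumor should carry the same somatic
SNVs, but formalin fixation shifts the observed VAF distribution downward
and adds C>T deamination artefacts, so per-caller concordance between the
two preparations is imperfect and caller-dependent. The package quantifies
that concordance, evaluates remediation strategies (significance
thresholds, multi-caller consensus, germline-leak filtering), and asks how
much of the residual discrepancy is explained by intra-tumor heterogeneity
(subclonal variants being harder to recover at shrunken VAF).

## Data model and conventions

A variant is identified by (chromosome, 1-based position, ref, alt), single
bases only; indels/MNVs are dropped at read time and multiallelic records
are decomposed per alternate allele, because the matching rule compares
single ref/alt pairs. Chromosome labels are normalized (no `chr` prefix,
`MT` for the mitochondrion). Tumor and normal VAFs are recomputed uniformly
as alt reads / total reads from the VCF allele-depth fields (`AD`, or the
Strelka2 tier-1 per-base counts), because callers differ slightly in their
own VAF definitions; a uniform definition makes cross-caller VAF
comparisons meaningful. When a caller emits no normal depths, the normal
VAF is recorded as 0 with a warning, which makes the zero-normal-VAF filter
a no-op rather than a mass rejection.

Significance scores and their polarity per dialect: Strelka2 `SomaticEVS`
and Mutect2 `TLOD` (higher = more confident); VarScan2 somatic p-value and
Shimmer q-value (lower = more confident). The VarScan2/Shimmer tag names
are configurable (`SPV`/`QVAL` defaults) since output conventions vary
between versions.

VCFs written by the package store exact float VAFs in private INFO tags
(`TVAF`/`NVAF`) alongside integer allele depths; the reader prefers those
tags, which gives a lossless write→read round trip (integer depths cannot
encode arbitrary fractions). Segment files are tab-delimited 1-based
inclusive intervals with either an explicit amplified/deleted/neutral
status or a log2 copy-ratio column; the symmetric neutrality threshold is
|log2| ≤ τ with τ = 0.1 by default.

## Concordance and consensus

All ratios derive from raw counts: sensitivity o/|FF|, precision o/|FFPE|,
F1 = 2o/(|FF|+|FFPE|). Zero denominators yield 0 so batch reports never
fail on empty call sets. The at-least-k consensus keeps keys supported by
≥ k distinct callers (k=1 union, k=#callers intersection); a consensus
variant's representative VAF is the median over its supporters. The
germline-leak filter retains exactly the calls with zero VAF in the
matched normal; by default it is applied to the Shimmer-style caller only
(the one observed to leak germline variants), with a switch to apply it
globally, and it is applied *before* consensus construction. The
top-fraction filter keeps the ⌈q·n⌉ most significant calls under the
caller's polarity, including all score ties at the cutoff so the selection
is order-independent.

## Threshold optimization

Per caller, an exhaustive grid search over the FFPE significance threshold
maximizes F1 against the FF at-least-two ground truth. Screening spaces:
EVS 5→20 step 0.25; TLOD 0→200 step 1; somatic p 5·10⁻⁵→0.01 step 5·10⁻⁵;
q 5·10⁻⁴→0.05 step 5·10⁻⁴. Grid values are generated by integer index
(lo + i·step) to avoid floating-point accumulation; endpoints are
inclusive; scores exactly at the threshold are retained (≥/≤). Ties in
best F1 break toward the more stringent threshold — deterministic and
conservative.

## Mutational profiles and signature fits

Profiles count SNVs over the 96 SBS classes in the conventional layout:
substitution (C>A, C>G, C>T, T>A, T>C, T>G), then 5' base, then 3' base
(labels like `A[C>A]T`); purine-reference variants are reverse-complemented
first, so classification is strand-symmetric. Signature catalogues are
96×K column-stochastic matrices (COSMIC SBS v3 file layout accepted) with a
configurable subset flagged as sequencing artefacts. Exposures solve the
NNLS problem min‖p − S·e‖₂ s.t. e ≥ 0 on the count scale (scipy's
Lawson–Hanson solver); the artefact fraction is the exposure mass on
artefact columns over total exposure mass. Fits whose reconstruction has
cosine < 0.9 with the original profile are flagged unreliable and their
artefact estimates should not be trusted. Which signatures count as
artefacts is configuration, not hard-coded: the real artefact list is
cohort- and cancer-type-specific, and the tests use synthetic catalogues so
no external download is needed.

## Clonality

*Bona fide diploid* variants are consensus (k ≥ 2) variants lying in
segments copy-number neutral in **both** samples, excluding X, Y and MT;
positions not covered by any segment count as non-neutral (conservative —
unsegmented territory is not silently admitted). This avoids VAF biases
from copy-number differences without attempting copy-number or purity
correction (purity estimates for the same sample are notoriously
inconsistent; labelling from each sample's own VAF distribution is
purity-invariant).

The VAF density is a Gaussian KDE evaluated on a fixed 512-point grid over
[0,1]. The bandwidth is chosen from 10 log-spaced values in [0.01, 0.1] by
5-fold cross-validation maximizing mean held-out log-likelihood; folds come
from a fixed shuffle so the choice is deterministic, ties prefer the
smaller bandwidth, and above 1500 points the CV (cost quadratic in n) runs
on a fixed-seed subsample while the final density always uses all points.
At least 10 distinct values are required; identical values are an error
(density unidentifiable).

Local extrema are detected by sign changes of first differences on the
grid; plateaus are attributed to their leftmost point; a density falling
away from the left edge or rising into the right edge contributes a
boundary maximum, so minima and maxima interleave. [0,1] is cut at the
interior minima, and the clonal interval is selected by rule — the interval
whose mode is the highest VAF below a germline cut (default 0.45) while
holding at least 10 % of the variants — as a deterministic, configurable
stand-in for per-sample visual inspection; an explicit override interval
bypasses the rule. Variants in lower intervals are subclonal; variants
above the clonal interval are excluded from the clonal/subclonal
concordance as residual-germline-like rather than counted as clonal.
Concordance is then computed separately over clonal-labelled and
subclonal-labelled keys; a side with no variants of a class leaves that
metric flagged undefined rather than misleadingly 0, and a 3×3 FF-vs-FFPE
label cross-tabulation over shared keys is reported.

## Synthetic study conditions

The generator works at call-set level, not read level: the phenomena the
analysis consumes (VAF shrink → lost sensitivity, score–VAF correlation,
germline leakage, context-biased artefacts) are all expressible there, and
a read simulator would add cost without adding test power.

Defaults define the study conditions: 3000 clonal variants with FF VAF ~
N(0.25, 0.04); 800 subclonal at N(0.05, 0.015); FFPE VAF = FF VAF × 0.47
plus N(0, 0.01) noise, putting the FFPE clonal median near 0.11 (the
shrink factor matches the ratio of observed FFPE/FF clonal medians,
0.1083/0.2323 ≈ 0.466); 300 germline-leak variants near VAF 0.5 in both
tumor samples with positive normal VAF; 500 FFPE-only artefacts at
N(0.08, 0.02) with 96-classes drawn from a C>T-heavy artefact signature;
tumor depth Poisson around 100× with a 1.5× variance inflation in FFPE.
Positions are uniform without collision over two 10 Mb contigs.

Caller error models are logistic in true VAF (midpoint/slope per caller:
Strelka2-style 0.03/35, Mutect2-style 0.035/30, VarScan2-style 0.12/25,
Shimmer-style 0.06/25 with a 0.9 germline leak rate), with caller-private
false positives at low VAF (1000/1700/600/900 per sample, ×1.5 in FFPE)
and scores monotone in observed VAF plus Gaussian noise — linear on the
score scale for higher-is-better callers, 10^(−linear) on the p/q scale
for lower-is-better ones, scaled so FF clonal-cluster scores land near the
observed per-caller averages (EVS ≈ 17, TLOD ≈ 50, p ≈ 2·10⁻³, q ≈ 10⁻²).
Each FFPE artefact is visible to each caller with probability 0.5 before
the logistic draw, making artefacts mostly caller-private the way
independent noise is. CN segmentations are one neutral segment per contig
for FF, plus five 50 kb spurious amplified/deleted fragments for FFPE.

What the generator does **not** emulate: mapping and alignment pathologies
(the outlier-sample failure mode), strand-orientation (FoxoG) structure in
artefacts, correlated false positives between callers, mutation-rate
heterogeneity along the genome, and real COSMIC signatures. Passing tests
therefore demonstrate correctness of the pipeline's logic and its
directional behavior under the modelled mechanisms, not performance claims
on real FFPE cohorts.

Everything derives from one integer seed through independent named
substreams; identical configuration and seed give byte-identical VCF, SEG
and TSV outputs.

## Problem sizes used in checks

Worked examples are exact count arithmetic (instant). Oracle-equivalence
checks run on fixtures of ≤ 1000 variants against brute-force enumeration.
Parameter recovery uses n = 2000 VAFs for KDE clonal-fraction recovery
(±0.05), noiseless mixtures for NNLS recovery (1e-6), and 10,000 sampled
mutations for artefact-fraction recovery (±0.03). The directional
replication runs 50 seeded replicates at the default study conditions and
requires the at-least-two consensus to beat every single caller in ≥ 90 %
of replicates, clonal F1 > subclonal F1 in ≥ 95 %, and consensus artefact
fraction below the union's in ≥ 95 %; a replicate whose FFPE side has no
subclonal variants counts subclonal F1 as 0, mirroring how such samples
are reported.

## Known limitations

- The clonal-interval selection rule is a heuristic stand-in for visual
  inspection; multimodal densities with modes straddling the germline cut
  may need the manual override.
- The reliability gate (reconstruction cosine ≥ 0.9) flags but does not
  repair poor signature fits; profiles far outside the catalogue's span
  produce unreliable artefact fractions.
- Consensus representative VAFs (median over supporters) smooth over
  caller-specific depth models; per-caller VAFs remain available in the
  consensus payload when that matters.
- The F1-from-counts convention can differ in the 3rd–4th decimal from
  published tables that derive F1 from pre-rounded sensitivity/precision;
  counts govern everywhere in this package.
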