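# Methods

`methylhet` analyses intratumour DNA-methylation heterogeneity in Illumina
EPIC-style β-value data, in two study geometries: *spatial* (3–7 biopsies
taken from different regions of one tumour at one surgery) and *temporal*
(paired primary and relapse specimens). This note records the models,
conventions and numerical choices behind each stage, what the synthetic
cohort generator does and does not emulate, and the known limitations.

## DMP calling with copy-number filtering

A differentially methylated position (DMP) between two samples is a CpG
probe with |Δβ| = |β_b − β_a| > 0.3. The inequality is strict at both this
threshold and the deletion threshold below, so boundary values are never
called. Before calling, probes are removed when they fall inside a segment
with log2 copy-number ratio strictly below −0.4 (homozygous deletion) in
*any* sample of the patient being analysed: a deletion in either member of
a pair makes its Δβ meaningless, so the filter scope is per patient rather
than per sample. SNP genotyping probes are always removed. A probe also
drops out of a pair when its β is missing in either sample; the retained
denominator reported with every result counts probes that survived the
filter *and* were measured (for a multi-biopsy summary: measured in every
biopsy), which is the denominator used for burden percentages (one decimal).

Per-tumour burden is the size of the union of DMP sets over all unordered
biopsy pairs. The union is the primary number because the accompanying
pair-multiplicity histogram shows how often alterations are confined to a
single pair; the per-pair maximum is reported alongside since burden is
sometimes quoted that way. For ordered primary→relapse comparisons the
signed Δβ (relapse − primary) is split into hypomethylated (Δβ < −0.3) and
hypermethylated (Δβ > +0.3) counts, which always sum to the DMP total, and
a majority direction.

## Genomic-region enrichment

Each probe carries a CpG-island relation (Island / Shore ≤2 kb / Shelf
2–4 kb / OpenSea >4 kb; N/S orientation in input manifests is folded) and a
set of gene-region labels (TSS200, TSS1500, 5'UTR, 1st exon, exon boundary,
body, 3'UTR); an empty set is the intergenic category IGR. CGI proportions
partition a probe set; gene-region proportions are membership fractions and
may sum past one for multi-annotated probes.

The enrichment test is a two-sided one-sample Wilcoxon signed-rank on
per-patient differences (patient's DMP proportion in a category minus the
background proportion of the retained, post-filter, non-SNP probe set).
This per-patient construction was chosen over pooling all DMPs because it
matches per-patient bar representations of the data and is robust to one
high-burden patient dominating; a pooled binomial test is available via
`method="binomial"`. The null is exact for ≤25 patients and a normal
approximation with continuity correction above; zero differences are
dropped before ranking (standard signed-rank practice) and an all-zero
category returns p = 1. A category is flagged enriched/depleted at
p < 0.01 with the sign of the median difference. No multiple-testing
correction is applied to the flags — the test is reported per category at
its nominal level, so over the 12 categories roughly one in ten null
cohorts will show some flag — but Benjamini–Hochberg q-values accompany
every report for readers who want familywise control.

## Phylogenies, clustering, ordination

Per patient, probes are ranked by sample variance (denominator n−1) over
the patient's tumour samples; a normal-tissue reference sample participates
in the distance computation but never in the ranking. The top 5,000 probes
(default) define Euclidean distances. Only probes measured in every sample
of the computation are eligible, and ties in variance break
lexicographically by probe id, so selection is deterministic.

The minimal-evolution tree is built as: neighbour joining (deterministic
first-minimum tie-breaking) for the starting topology; ordinary
least-squares (OLS) branch lengths on a fixed topology, fitted by linear
least squares on the leaf-pair path-length system; then a
nearest-neighbour-interchange hill climb that scans internal edges in a
fixed order and accepts the first swap that strictly reduces the OLS total
tree length, repeating until no move improves. The OLS variant (rather
than balanced/weighted ME) was chosen because it admits an exact
exhaustive-enumeration oracle at small leaf counts; the search criterion is
always evaluated on unclamped fits, and negative branch lengths are clamped
to zero only after convergence. Newick serialization is canonical (children
ordered by smallest leaf label, labels quoted when they contain
metacharacters), so identical inputs give byte-identical trees. Rooted
renderings place the root at the reference leaf's attachment point, which
preserves all leaf-to-leaf path lengths.

Cohort-level structure uses complete-linkage agglomerative clustering
(average linkage available; the linkage was a free choice) on the top
10,000 variable probes and classical (Torgerson) metric scaling — double
centring of −½D², eigendecomposition, coordinates as eigenvectors scaled by
root eigenvalues — on the top 20,000. Negative eigenvalues are truncated
with a warning; axis signs are fixed by making the largest-magnitude
loading positive.

## SNP-probe identity verification

EPIC-style arrays carry ~59 SNP genotyping probes whose β-values are
tri-modal genotypes, constant within an individual. Samples are compared by
Euclidean distance on these probes alone; a sample is flagged when it lies
strictly nearer to another patient's sample than to any sample sharing its
patient label. The strict form is used (rather than "nearest neighbour must
be same-patient") because with patient-constant genotypes an exact distance
tie between own- and other-patient samples carries no evidence of a mixup.
Patients represented by a single sample have no same-patient neighbour and
are never flagged. The pipeline halts with exit code 3 on any violation
unless `--allow-mismatch` is given.

## Association statistics

*Group comparisons.* Welch's unequal-variance t with Satterthwaite degrees
of freedom between per-patient DMP burdens of tumour-type groups. A group
with fewer than two patients yields an explicit not-computable marker,
never a number.

*Purity.* Pearson correlation (two-sided p from the t transform, n−2 df)
between the intratumour purity difference (spatial: max−min over biopsies;
temporal: |relapse − primary|) and the patient's DMP count. Zero-variance
input returns an undefined marker; patients with missing purity are dropped
with a warning.

*Time to relapse.* A univariate Cox proportional-hazards regression treats
the relapse interval as the outcome and the temporal DMP count as the
covariate, with every pair an event (a censoring vector is accepted for
generality). This inverted usage — survival time as outcome, burden as
covariate — is deliberate: it reproduces the way the drift/time association
is conventionally tested in this setting. Ties are handled by Breslow's
approximation (day-resolution intervals rarely tie, and Breslow admits a
simple closed-form oracle; Efron agrees exactly on tie-free data). The
partial likelihood is maximized by Newton–Raphson from β = 0 with
step-halving, declared converged when |score| < 1e−9 (cap 50 iterations,
non-convergence is an error with diagnostics); the covariate is centred
first, which leaves the fit invariant but conditions the solver. Raw counts
are the default covariate; `log1p=True` fits log(1+count). p-values are
two-sided Wald, reported to 3 significant digits. Note that under monotone
likelihood (e.g. two subjects, perfectly separated covariate) the score
criterion is met at a large finite coefficient; this matches the behaviour
expected of the stopping rule.

## Synthetic cohort generator

The generator produces a manifest, β matrix, SEG segments, sample sheet and
ground truth with these mechanisms:

* **Baselines.** Per patient, per probe, β is drawn from a bimodal mixture
  (45% Beta(2,18), mode ≈0.05; 45% Beta(18,2), mode ≈0.95; 10% Beta(8,8)
  intermediate mass), reflecting the strongly bimodal marginal distribution
  of array β-values.
* **Alterations.** Each biopsy carries a private set of altered sites of
  fixed magnitude Δ = 0.5, sign toward the opposite mode (so shifts stay in
  [0,1] without heavy truncation; truncations are logged in the ground
  truth). Sites are drawn without replacement with categorical weights of
  3× on OpenSea and 3× on IGR probes (multiplicative when both), mimicking
  preferential alteration of non-regulatory regions; sets are disjoint
  within a patient, and from SNP probes and deleted regions, so every
  pairwise truth is a clean symmetric difference. Spatial biopsies get
  30–250 sites each (times a tumour-type multiplier); relapse samples get
  Poisson(λ · interval) sites at λ = 0.3/day over intervals of 100–1500
  days, hypomethylating with probability 0.6. Requesting more sites than
  the eligible pool holds is a hard error.
* **Cohort composition.** Defaults mirror a realistic paediatric cohort:
  11 spatial patients (7 low-grade glioma at 1×, 3 medulloblastoma at
  2.25×, 1 ependymoma) with 3–7 biopsies each, and 33 temporal pairs in
  five groups (LGG 0.4×, ependymoma 0.8×, medulloblastoma 1.2×, high-grade
  glioma 2×, embryonal 2.8× the base rate), so group comparisons have real
  signal. Single-group designs (`temporal_groups=None`) give the pure
  λ-accumulation model.
* **Measurement.** Observed β = purity·tumour + (1−purity)·normal profile,
  truncated to [0,1], plus N(0, σ=0.02) noise, re-truncated. Purity is
  drawn per sample from (0.65, 0.95). The contaminating normal profile is
  the cohort's single normal-reference profile — an approximation (a real
  patient's stroma is their own), adequate because normal methylomes are
  far more alike than tumour methylomes. SNP probes get patient-constant
  genotypes from {0.05, 0.5, 0.95} plus noise, with no purity mixing
  (germline is shared by tumour and stroma).
* **Copy number.** With probability 0.3 a tumour sample carries one
  homozygously deleted run of 40 consecutive probes (SEG mean −1.0 < −0.4);
  its probes' β-values are replaced by Uniform(0,1) noise, which is what
  forces the copy-number filter to matter.

The design validator enforces Δ > 0.3 + 3σ so injected sites are
recoverable by construction, and equal seeds give bit-identical cohorts.

**What the generator does not emulate** — and hence what green tests do not
establish about real data: probe-level measurement biases (type I/II
chemistry, cross-hybridisation), batch and FFPE effects, spatially
correlated or regional (DMR-like) alteration structure, a distribution of
per-site effect sizes (Δ is fixed per design, a simplification), genuine
subclonal mixtures within a biopsy, and real linkage between copy-number
state and methylation. Parameter-recovery results show the pipeline is
correct under its own model, not that the model captures every property of
EPIC data.

## Problem sizes and reproducibility

Simulated checks run at desk scale: 2,000–8,000 probes rather than the
~866k of a real array, because burden counts, direction splits and
rank-based statistics depend on alteration rates and cohort size, not on
array size. Consequences of the scaling: simulated burden *percentages* run
higher than a real array's (same numerator, smaller denominator), while
counts, directions, enrichment flags and association p-values are
comparable. The exhaustive minimal-evolution oracle enumerates all 105
six-leaf topologies; Wilcoxon exactness is verified against full 2^n sign
enumeration up to n = 10; the Cox solver is verified against a 10,001-point
likelihood grid and an independent O(n²) Breslow evaluation.

Every stochastic component takes a NumPy `Generator` or integer seed; the
pipeline fans a single config seed out to fixed per-stage offsets so stages
are independently reproducible, and reruns with equal seed and inputs give
byte-identical JSON reports.

## Report schema

`dmp_report.json`: `params` (thresholds), `cohort_retained_probe_ids`,
`spatial` (per patient: `samples`, `union_count`, `max_pair_count`,
`retained_probe_count`, `union_fraction_pct`, `multiplicity_histogram`,
`pairs` [a, b, count, retained_probe_count], `union_probe_ids`), `temporal`
(per patient: `primary`, `relapse`, `count`, `hypo_count`, `hyper_count`,
`majority_direction`, `retained_probe_count`, `probe_ids`), and per-kind
`*_sharing_histogram` (patient multiplicity → probe count).
`enrich.json`: per kind, a list of per-category records (axis, category,
array_proportion, patient_proportions, median_difference, p_value, q_value,
flag). `assoc.json`: `cox_relapse_interval_vs_dmps` (CoxFit fields),
`group_comparisons`, `purity_vs_dmps_{spatial,temporal}`. `identity.json`:
`ok`, `violations`, `n_snp_probes`, per-sample records. `run_manifest.json`:
config echo, version, seed, input digests, per-stage status and outputs.

## Known limitations

The minimal-evolution search is a local NNI hill climb; it matches the
exhaustive optimum on all tested near-additive inputs but carries no global
guarantee for arbitrary distance matrices. The enrichment flags are
uncorrected by design (see above). The Cox model is univariate with no
proportional-hazards diagnostics. Differentially methylated *regions*,
β-mixture modelling, batch correction, raw IDAT processing, copy-number
inference and purity estimation are out of scope: segments and purity enter
as inputs.
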