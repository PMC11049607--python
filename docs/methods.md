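# Methods

`panelcna` re-implements, as an open and testable pipeline, a clinical
workflow for detecting somatic copy-number alterations (CNAs) on a
24-gene targeted panel from FFPE solid-tumor sequencing, and the
diagnostic-concordance analysis used to validate such a workflow against
an orthogonal platform. This note records the model, the defaults and the
design choices, in the package's own words.

## Pipeline model

**Reference (dynamic bins).** A cohort of healthy controls (default
10 male + 10 female, 5–10× coverage) defines expected coverage. Each
control's window-level read counts are library-size normalized (scaled to
the cohort-median total), and the cohort-mean track is cut greedily,
left to right within each chromosome, into *dynamic bins*: a bin closes
as soon as its running read total reaches the target (default **1000
reads per bin**), so bin width adapts inversely to local depth. Bins
never cross chromosome boundaries or gaps in the panel footprint; a
trailing remainder under half the target is absorbed into the previous
bin of the same contiguous block. A chromosome whose pooled reads fall
short of the target collapses to one bin per contiguous block, with a
warning. Per bin the reference stores the cohort mean (`expected_reads`,
≈ the target by construction) and a dispersion (cohort standard
deviation floored at the Poisson level √mean). Bins with expected reads
below 10% of the target are flagged unreliable and excluded downstream.

**Normalization.** A test sample's window counts are summed into the
reference bins, scaled so its total matches the reference total, and
converted to log2 ratios `log2((s + ε)/(e + ε))` with a symmetric
pseudo-count ε = 0.5 (a sample exactly matching expectation maps to
exactly zero; zero-count bins stay finite). GC bias is removed by a
decile-median curve: the median log2 ratio within each GC decile
(deciles under 5 bins merge with a neighbor), linearly interpolated in
GC, is subtracted. The decile-median curve was chosen over loess for
determinism and easy testing. The profile is then centered on its median
— robust to event-carrying bins as long as most of the panel is neutral.
B-allele frequencies are `alt/(ref+alt)` at heterozygous SNPs with total
depth ≥ 20; BAF is *not* mirrored about 0.5, so the emission model can
use both alleles symmetrically.

**Segmentation (copy-number HMM).** Hidden states are total copy numbers
0–6 (stronger amplifications collapse into the top state; gene-level
calling only needs "≥ 4"). At tumor purity *p*, state CN predicts a log2
ratio `log2((p·CN + (1−p)·2)/2)` (ratio floored at 2⁻⁵ so homozygous
loss at *p* = 1 stays finite) observed with Gaussian noise, and a set of
het-SNP BAFs `(p·b + (1−p))/(p·CN + (1−p)·2)` for b = 0..CN observed
through an equal-weight Beta mixture (concentration κ = 80, component
means clamped to [0.005, 0.995]). The Gaussian sd defaults to a robust
per-profile estimate, 1.4826 × MAD of the centered log2 values (floor
0.02). Transitions are uniform over non-self states with per-bin
self-transition 1 − 10⁻⁴; per-bin (not per-base) steps are appropriate
because dynamic bins equalize information content. Decoding is exact
log-space Viterbi, run independently per chromosome and per contiguous
footprint block — a segment never spans an unobserved gap between panel
regions, so reported segment spans are always backed by data (this also
keeps two distinct single-gene events on one chromosome from merging
into a fictitious multi-megabase segment). Purity is taken from the
sample annotation when known (the clinical situation: pathologist-
estimated cellularity) or grid-searched over {0.2, …, 1.0} by total
path log-likelihood, ties toward higher purity; event-free profiles are
purity-uninformative and return the grid maximum with a warning.

**Gene calls.** Classes are a pure function of total copy number:
≤1 loss, 2 neutral, 3 gain, ≥4 amplification. For each panel gene the
supporting segment is the one with the largest reciprocal overlap
(`min(overlap/len_gene, overlap/len_segment)`); ties go to the segment
covering the gene midpoint. A non-neutral call whose supporting segment
spans more than **5 Mb** (configurable) is suppressed — reported neutral
with the raw class kept in provenance — reflecting the clinical decision
to exclude very large CNVs; keeping suppressed calls as neutral rows
keeps the (sample × gene) matrix complete for concordance. Exactly one
call per (sample, gene) is emitted, always.

**Concordance.** Test and truth call sets over the identical matrix are
reduced to a 2×2 table. In the default *presence* mode an event is any
non-neutral, unfiltered call; *exact_class* additionally requires class
agreement for a true positive (a class mismatch counts against
sensitivity). Sensitivity, specificity, PPV, NPV and diagnostic accuracy
follow the standard contingency formulas; zero-denominator metrics are
reported as undefined, never 0 or 1. Reports add exact Clopper–Pearson
95% intervals (an addition beyond the validation-study tables, chosen
for bit-for-bit reproducibility).

## Synthetic cohort

The generator emulates the validation study's conditions: 50 tumors
(breast 10, ovary 8, pancreas 8, melanoma 4, prostate 20), purities
uniform on [0.2, 1.0], 20 controls at 5–10×, and a 54-event truth set —
34 gains (CN 3), 12 amplifications (CN 4), 8 losses (CN 1) — whose
per-gene, per-type placement matches the published frequencies (MYC 9/50
with 4/8 in ovary, TP53 6/50, BRAF 4/50; no melanoma amplification, no
pancreatic loss). The published per-type gene enumeration accounts for
47 of the 54 events; the remaining 7 are placed on panel genes the
enumeration does not mention (CDKN2A, PTEN, RB1, FGFR2), only in samples
that already carry events, so no stated frequency is disturbed.

Counts are negative-binomial at 500 bp window resolution with mean
∝ window length × coverage × GC factor; the GC factor is a smooth
unimodal bump, `2^(−a·((gc−0.45)/0.15)²)`, with per-sample amplitude
drawn around the configured 0.3 so that test samples and the control
reference genuinely disagree and the correction stage has work to do.
The GC track itself is a smooth seeded sinusoid (period 150 kb) with
small jitter, clipped to [0.28, 0.68]. Defaults chosen once as
field-realistic values: tumor coverage uniform on [300, 500]× (typical
deduplicated hybrid-capture tumor depth), dispersion k = 300 — together
≈ 0.09 sd per-bin log2 noise, in the range of good-quality FFPE panel
profiles. About 10 heterozygous SNPs are placed uniformly per region;
alt depths are binomial at the expected BAF under (CN, p), with the
amplified allele picked at random per SNP, and SNP depth scales with the
local copy ratio. Identical seeds reproduce datasets bit for bit.

What the generator does **not** model: read-level artifacts (FASTQ/BAM
are upstream of this pipeline), FFPE deamination and SNVs, mappability
or replication-timing bias, subclonal heterogeneity (one purity per
sample), allele-specific states beyond a single B-allele copy choice,
and sex-chromosome dosage (chrX is treated as diploid; the panel's AR
region is simulated like an autosome). Passing tests therefore
demonstrate correctness of the algorithms under a plausible noise model,
not performance on real FFPE libraries.

## Numerical and design choices

- 0-based half-open coordinates (BED convention) throughout.
- Symmetric pseudo-count in the log2 ratio (exact zero for exact match).
- Copy-ratio floor 2⁻⁵ in the state model; BAF observations clamped to
  [10⁻⁴, 1−10⁻⁴]; Beta component means clamped to [0.005, 0.995] — all
  emissions are finite for any input.
- Dispersion floor √mean keeps degenerate (identical-control) cohorts
  usable.
- Viterbi ties resolve by `argmax` (lowest state index); with continuous
  emissions exact ties have measure zero.
- Purity-grid ties resolve toward larger purity.
- The reciprocal-overlap gene rule and midpoint tie-break are
  deterministic by construction.

## Problem sizes and validation

The bundled validation (`scripts/acceptance.py` and the test suite) runs
the full cohort — 20 controls + 50 tumors over the 24-region panel
(~15,800 windows, ~500 dynamic bins) — in a few seconds, and scores the
pipeline's calls against the planted truth over the 1200-cell matrix.
Viterbi correctness is checked against exhaustive path enumeration on
200 random instances (≤ 12 bins, ≤ 4 states) and against an independent
HMM library's decoder under Gaussian-only emissions. The low-cellularity
calibration point — CN = 4 events spanning ~10 bins at purity 0.2 — is
exercised end to end on a small dedicated panel.

## Known limitations

The proprietary algorithms this workflow mirrors (the multi-scale
reference builder and the SNPFASST2 segmenter) are undocumented beyond a
sentence each; this package implements standard, defensible versions of
those ideas (greedy equal-read binning; fixed integer-CN HMM states) and
claims no fidelity to the vendor's internals. The 5 Mb exclusion rule is
implemented as stated and made configurable; it is in tension with
arm-level events, which is why segments are confined to contiguous
footprint blocks. Whole-genome scope, tumor ploidy estimation and
allele-specific copy number are out of scope.
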