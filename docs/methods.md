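# Methods

## Scope and model

invadomics implements the quantitative path of a core-vs-invasive GBM
invasion study: a pooled CRISPR knockout screen selected by invasion
through a 3D hydrogel device, rule-based quantification of invasion assay
masks, fractal scoring of tumour outlines, and paired differential
analysis of omics matrices. Each stage is a pure function over plain
containers (pandas DataFrames, numpy masks); the pipeline module wires
them together behind a JSON config.

## Pooled screen scoring

Counts from replicate samples of the same fraction are **summed before
normalization** — each fraction is treated as a single pooled condition —
then scaled to counts-per-million. Guide fitness is the log2 ratio of
invasive over core CPM with a pseudocount added inside the ratio
(default 0.5 CPM; the smallest value that keeps fitness finite for
zero-count guides without visibly biasing well-covered ones). Fitness is
centred by subtracting the **median fitness of nontargeting guides**, so
nontargeting guides read exactly 0 and a targeted guide's fitness is its
deviation from neutral. Centering can be disabled
(`center_on_nontargeting=False`) for libraries without controls, and the
comparison to nontargeting controls is deliberately implemented as this
median shift rather than a permutation null: it is transparent,
deterministic, and exactly invertible.

Gene score = median of the gene's guide fitnesses (robust to a single
outlier guide); significance from a classical two-sided one-sample
*t*-test of the guide fitnesses against 0. Genes with one guide get a
score but no p-value. If all of a gene's guide fitnesses are identical the
*t* statistic is undefined: the score 0 case returns p = 1 (no deviation),
any other constant returns p = 0. Raw p-values are reported by default
(an FDR column is available through `omics.bh_adjust`); hit calling uses
symmetric thresholds on score and p, with negative scores =
core-enriched = invasion-essential candidates.

## Synthetic screen generator

Counts are negative-binomial with `var = mu + mu^2 * dispersion`
(dispersion 0.2, typical screen overdispersion) around guide-level
baselines that are log-normal with log-SD 0.5 (library skew) and
mean-preserving around the configured depth. Essential-gene guides have
their invasive-fraction means multiplied by `2^effect_log2`; nontargeting
guides are never shifted. Default dimensions mirror a metabolism-focused
library (2,981 genes × 10 guides + 1,000 nontargeting, 6 devices read as
3 core + 3 invasive samples); tests and the acceptance run use reduced
sizes (100–500 genes) that preserve the per-guide statistics. Truth
labels travel beside the data, never inside the files.

What the generator does *not* emulate: PCR jackpotting, guide-efficiency
heterogeneity, cell-sampling bottlenecks during selection, or
chromatin-driven guide biases. Passing recovery tests therefore shows the
scorer is correct under the stated noise model, not that real screens of
this size always separate this cleanly.

## Invasion imaging rules

All rules take calibrated masks (pixel size in μm; PNG/TIFF plus a JSON
sidecar). Area = foreground pixel count × pixel area; invasion index =
(*A*f − *A*i)/*A*i; control normalization divides by the control-group
mean. Connected components use 8-connectivity. Aspect ratio is the
major/minor axis ratio of the intensity-equivalent ellipse (rotation
invariant, unlike a bounding box); 1-px-wide lines get infinity, single
pixels 1. Form factor is 4πA/P² with skimage's weighted perimeter
estimator, capped at 1 for tiny objects whose discrete perimeter
underestimates the true boundary (ImageJ's circularity convention).

Thresholds follow their literal wording: elongated iff aspect ratio ≥ 2
(inclusive), highly invasive iff distance beyond the channel edge is
strictly > 200 μm, and a neighbour at exactly 10 μm blocks detachment.
The detached-cell rule measures **centroid-to-centroid** distance by
default; an `edge` mode approximates boundary gaps by subtracting
area-equivalent circle radii, for users who read "within 10 μm" as a gap
between cell boundaries. The spheroid core/reservoir is not a single
cell: callers exclude it (by an area cutoff) before applying the
detached-cell rule, as the pipeline stage and CLI (`--max-cell-area`) do.

The mask generator places background cells in close pairs so each has a
neighbour within the 10 μm rule (at the default 1 μm/px), and pins
requested isolated cells at exact coordinates with a 30 μm exclusion
zone — giving distance-rule tests exact ground truth.

## Fractal dimension

Box counting over either the mask outline (`boundary`, the default for
tumour masks, since a planar outline has dimension in [1, 2]) or the
filled mask (for analytic fixtures). For each scale the grid is evaluated
at 4 diagonal offsets (0, s/4, s/2, 3s/4) and the **minimum** count kept:
the box-counting number is defined by the smallest cover, and the minimum
removes the upward bias of an unlucky grid placement while leaving
grid-aligned analytic fixtures exact (offset 0 is always a candidate).
Default scales are powers of 2 from 2 px to image_size/4; for triadic
fixtures (Sierpinski carpet) triadic scales 3^k are the natural choice
because the analytic identity N(3^k) = 8^(d−k) holds only there. The
slope comes from ordinary least squares on (log 1/s, log N) with R²
reported; robust regression was rejected for reproducibility and because
residual diagnostics are exposed instead.

The branched-growth simulator grows persistent random-walk branches from
a seeded core; branch number and branching probability scale with
`branch_intensity`, with a hard segment cap keeping generation fast.
Boundary dimension rises monotonically over intensities 0.25–4 (mean D
≈ 1.25 → 1.53 over 10 seeds); above that, overlapping branches merge into
blobs and the boundary smooths, so the canonical ladder stops at 4.

Group comparison reports medians, their difference, and a two-sided Welch
*t*-test; two identical constant groups return p = 1.

## Paired omics

Fold change defaults to the **ratio of group means** across pair members
(per-pair-ratio mean available via `fc_mode="ratio_mean"`); tests are
two-sided *t*-tests on log abundances, paired across units by default
because the designs this serves are paired (an unpaired mode is exposed).
The zero-guard pseudocount is 1e-6 × the matrix median — abundances are
modelled as multiplicative, so the guard must be negligible relative to
scale. Zero-variance features return p = 1. FDR is Benjamini–Hochberg.

`geomean_normalize` is median-of-ratios: per-feature geometric-mean
reference over zero-free features, per-sample factor = median ratio to
the reference, factors rescaled to geometric mean 1. The rescaling makes
normalization idempotent and pins the overall scale; only factor ratios
are identifiable anyway. Outlier handling and shrinkage-based testing for
count data are deliberately out of scope — this covers the normalization
step only.

`ora_enrichment` computes the upper hypergeometric tail P[X ≥ overlap]
per set after harmonizing sets to the universe, with BH q-values and fold
enrichment. It is a standard over-representation analysis and is the
package's enrichment method wherever a topology-weighted pathway-impact
score might otherwise be used; reports should label it as such.

`concordance` uses Pearson r on shared features and counts strict sign
disagreements; the percentage is reported to one decimal. Features with a
log2 fold change of exactly 0 in either profile are never discordant.
`subset_metabolic` reports the catalogue-intersection percentage rounded
to the nearest integer, matching how such shares are quoted.

PCA (screen and omics) operates on log-transformed, feature-centred
matrices via SVD; replicated identical samples yield exactly zero scores.

## Synthetic abundance generator

Log-normal abundances (ln-scale feature means N(5, 1), pair noise SD 0.4)
over n pairs (default 7, a typical device-experiment size); changed
features are multiplied by `2^effect_log2` in the invasive member of each
pair. It does not emulate missingness, batch effects, or
intensity-dependent variance of real MS data, so null-calibration results
speak to the statistics under a clean multiplicative model.

## Determinism, sizes, degenerate inputs

Every generator takes an explicit integer seed; identical config + seed
is bit-identical, and pipeline reruns reproduce output checksums exactly.
Test and acceptance problem sizes (500-gene screens, 256-px masks,
500-feature matrices, 3 null seeds) were chosen as the smallest sizes at
which the examined statistics are stable; the full-scale defaults remain
available. Degenerate inputs fail loudly (all-zero fractions, empty
masks, sub-minimal group sizes) or warn (empty mask area, missing
nontargeting guides, no planted signal).

## Known limitations

- No raw-data processing: no FASTQ guide mapping, no micrograph
  segmentation, no MS feature extraction; inputs are count tables and
  masks.
- The screen scorer is the median/t-test path it implements; it is not a
  robust-rank-aggregation or Bayesian essentiality model, and gene
  p-values assume guides are exchangeable replicates.
- Box-counting dimension depends on scale range and resolution; values
  are comparable within a fixed configuration, not across instruments.
- The edge-distance mode of the detached-cell rule approximates cells as
  area-equivalent disks.
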