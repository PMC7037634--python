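# Methods

## The statistic

For an undirected PPI graph over gene symbols and one expression sample, the
package computes

- concentrations: c_i = (e_i − e_min) / (e_max − e_min), with e the log2
  expression values and the range taken over the genes of that sample;
- chemical potentials: μ_i = ln(c_i / Σ_{j∈Adj(i)∪{i}} c_j);
- the sample score: G = Σ_i c_i μ_i.

Because c_i appears in its own denominator and all concentrations are
non-negative, every log argument is ≤ 1, every contribution c_i μ_i is ≤ 0,
and G ≤ 0. Structural consequences, all covered by property tests: an
edgeless graph gives G = 0; nodes with c = 0 are neutral no matter how they
are wired; adding an edge between two positive-concentration nodes strictly
decreases G; scaling all concentrations by k > 0 leaves every μ_i unchanged
and multiplies G by exactly k (μ is scale-free, G is 1-homogeneous).

The statistic assumes mRNA abundance is an acceptable proxy for protein
concentration and that the interaction network is a fixed, unweighted,
undirected topology shared by all samples. Nothing here is calorimetric; the
"Gibbs" naming reflects the c·ln(c/Σc) functional form.

### Conventions and numerical choices

- 0·ln(0) := 0 and μ_i := 0 when c_i = 0 — the analytically forced limit,
  keeping G finite. Likewise μ_i = 0 when the closed-neighborhood sum equals
  c_i (isolated node, or all neighbors at zero): the log argument is exactly
  1 with no tolerance involved.
- Natural logarithm throughout; the log2 in the data refers only to upstream
  expression normalization.
- A constant sample (e_max = e_min) has no well-defined rescaling; all
  concentrations are set to 0 (G = 0) with a warning, rather than erroring
  out mid-cohort.
- Summation runs in sorted-gene order and scoring is fully vectorized
  (closed-neighborhood sums as a sparse (A + I)·c product), so repeated runs
  are bitwise identical.
- Self-loops in input networks are dropped at parse time: the denominator
  already unions a node with its own neighborhood, and a self-edge would
  double-count c_i.

### Rescaling scope — a genuinely open choice

Whether the min–max range is per sample or matrix-wide is not forced by the
method's definition. The default is per sample (each sample is an
independent snapshot; this also makes every sample span the full [0, 1]
range), with `rescale_scope="global"` exposed on the scorer and pipeline.
Similarly, the range is taken over the whole transcriptome by default (the
matrix is rescaled first, then overlaid on the network);
`rescale_over="network"` restricts it to network-overlapping genes. The
choice in force is echoed in every output's provenance block.

## Ingestion rules

Probe-level matrices are collapsed to genes by: deleting probes with no gene
assignment, and averaging the per-sample **log2** values of probes sharing a
gene (no de-logging — the upstream data are distributed log2-normalized and
averaged on that scale). Gene symbols are uppercased and whitespace-stripped
on both the expression and network side so the namespaces join reliably.
Samples whose region label is not one of the 16 recognized brain-region
codes are discarded and counted. Ages are years, birth = 0, prenatal
negative (e.g. −0.4); unknown sex excludes a sample from sex-stratified
summaries but not from per-sample scoring.

## Cohort aggregation

Default age-bin edges (years): −0.75, −0.55, −0.3, 0, 1, 4, 8, 23, 27, 40,
55, 100 — a reconstruction assembled from the age brackets the source data
are conventionally described in (fetal trimester-like brackets, 1–4, 8–23,
27–40, 40+, 55+), with 4–8 kept as its own bin so the edges partition the
range; the binning is fully overrideable because the original binning was
data-driven. Intervals are left-closed (age 0 lands in the postnatal 0–1
bin); the last bin is closed. Bin summaries report the arithmetic mean, the
n−1 standard deviation divided by √n (missing when n = 1), and n.

Per-sex curves average region *means* with equal weight per region
(regions, not samples, are the averaging unit; sample-weighted averaging is
available). A crossover is a strict sign flip of (female − male) between
consecutive shared bins; a zero difference is a tie, never a flip.
Convergence is declared when the final bin's |female − male| falls below a
tolerance, by default one pooled standard error of that difference — the
qualitative "converge to the same value" claim needs an explicit scale, and
1 SE is the natural one given that only means ± SE are reported. Trajectory
extrema are the global-maximum bin (ties to the earlier bin, flagged) and
the minimum among strictly later bins (degenerate when the peak is last).

Hemispheres are separate observations by default; `hemisphere_handling:
average` collapses L/R per donor-region before binning, which is what
"suppressed hemisphere information" amounts to when plotting pooled curves.

## Synthetic cohorts

The generator emulates the *statistical shape* of a developmental brain
cohort, not its biology: a genes × samples log2 matrix, per-sample metadata
(donor, age incl. negative prenatal ages, sex, region, hemisphere), and a
scale-free interaction network over the same gene namespace.

The single control handle is hub loading α ∈ [0, 1]: a sample with loading α
places linear-scale expression mass α/|H| on each top-decile-degree node
("hubs" H) and (1−α)/|rest| elsewhere, mixed with a 2% uniform floor (so
log2 stays finite at α ∈ {0, 1}), converted to log2, plus Gaussian noise
(default sd 0.25 log2 units, a realistic microarray replicate noise level).
Concentrating mass on hubs leaves most low-degree nodes near zero
concentration after rescaling, so closed-neighborhood sums carry less mass
and G moves toward zero: **E[G] is strictly increasing in α**. This was
established by a one-off calibration on the default network (300 genes,
Barabási–Albert m = 2): E[G] rises monotonically from ≈ −240 at α = 0 to
≈ −94 at α = 1, passing through the near-uniform point α = 0.1 (where hub
and non-hub mass coincide and sampling noise peaks). A per-bin, per-sex α
schedule therefore induces a known ordering of expected G, recorded as the
cohort's `truth`.

The default schedule encodes: a rise through the three fetal bins to a birth
peak (bin 0–1), a dip to an adolescent trough (8–23), and a late rise after
40; female above male prenatally, the offset reversing in the 1–4 bin. The
same calibration measured the sampling noise of bin means at the default 10
samples per bin per sex (per-sample sd of G ≈ 9–14 in the working α range,
so bin-mean differences have SE ≈ 4–5); offsets were sized at ≥ ~3 such SEs
(α gaps of 0.13–0.16) so the configured sign pattern is stable across seeds.
For the same reason the post-crossover male-above-female gap *shrinks*
toward the older bins but never reaches exactly zero: an exactly-zero
expected difference would make the final bins' sign a coin flip and the
"exactly one crossover" recovery property unattainable at any sample size —
the curves converge within the convergence tolerance instead. These defaults
were frozen after the calibration and are not tuned further.

What a green trajectory-recovery test establishes: the pipeline's binning,
stratification, region averaging, crossover and extrema machinery correctly
recover a trajectory *known to be present* at realistic noise. What it does
not establish: anything about real cohorts — the generator makes no attempt
to match real expression distributions, 16-region structure, donor/
hemisphere correlation, or unbalanced bin occupancy.

## Known limitations

- The statistic depends on the network release used; results are only
  comparable within one network. The provenance block records input
  checksums for this reason.
- Min–max rescaling is outlier-sensitive: a single extreme gene rescales the
  whole sample. No robust-quantile alternative is implemented.
- Bin summaries are purely descriptive (means ± SE); no formal tests, no
  smoothing across bins.
- The probe→gene map is a user input; annotation-release differences
  propagate directly into gene coverage.
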