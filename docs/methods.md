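# Methods

`ivdkit` implements the computational core of a comparative study of
diabetic intervertebral-disc (IVD) pathology in mouse models: differential
screening of multiplex cytokine panels, construction and comparison of
cytokine correlation networks, contrast-enhanced micro-CT disc morphometry,
cyclic-compression viscoelastic analysis, and glucose-tolerance
phenotyping. Every stage can be exercised on synthetic data with planted
ground truth, which is what the test suite does.

## Synthetic data: the stated world

The generators default to the design of a four-group mouse study — db/+
and db/db littermates, chow+vehicle controls, and STZ-HFD diabetic animals
at n = 3/3/3/9 — with two pseudo-replicates per animal.

**Cytokine panels.** Concentrations are log-normal: assay readouts are
positive and right-skewed, and log-normality is the simplest model whose
log-scale Pearson structure the network stage can target directly. The
log-scale value of cytokine *c* in animal *a* is

    log x_ac = log(μ_c · m_gc) + σ · (√r_b·G_a + √(r_w−r_b)·B_a(block c)
               + √(1−r_w)·ε_ac + σ_n·η_ac)

where μ_c is a per-cytokine baseline (log-uniform over 10–500 pg/ml),
m_gc a group-specific fold multiplier, G/B/ε standard-normal latent
factors shared globally / per block / per cytokine, σ = `base_sigma`
(default 0.4, ≈40% CV — typical multiplex biological variation), and
σ_n = `noise_sd` an independent dilution term. The construction gives
log-scale Pearson correlation `within_block_r` inside a block and
`between_block_r` across blocks, attenuated by 1/(1+σ_n²). Technical
noise of log-SD `replicate_sd` (default 0.05) separates pseudo-replicates.
Missingness is left-censored: the lowest `missing_rate` quantile of each
cytokine's readings is flagged out-of-range (OOR), matching the mechanism
by which multiplex assays lose the bottom of their dynamic range. The
generator does not emulate plate effects, heavy-tailed outliers, or
upper-range censoring, so a green recovery test establishes correctness of
the pipeline under the factor model, not robustness to those artifacts.

**Disc phantoms.** Parametric solids (ellipsoid / elliptic cylinder / box)
are voxelized by center membership on a 64³ grid at 10 µm voxel size; the
NP core is brightest (the contrast agent partitions into the
proteoglycan-rich NP), then the disc envelope, then background, plus
optional Gaussian noise. Exact voxel masks are returned as ground truth;
voxelized NPVF agrees with the analytic volume ratio within 2% at ≥64³.
Real scans have partial-volume gradients, beam hardening and anatomical
asymmetry that phantoms do not.

**Loading traces.** x(t) = X₀ sin(2πft), F(t) = F_pre + kX₀ sin(2πft+δ)
+ noise, sampled at 100 Hz for 20 cycles at 1 Hz, 35 µm amplitude, 0.03 N
preload. Real tests show preconditioning drift and slight nonlinearity the
generator omits; the last-10-cycle default selection exists for that
reason.

## Cytokine screen

Pseudo-replicates collapse to the per-animal median over detected values
only (flagged only if all replicates are flagged; idempotent). Cytokines
with strictly more than 25% OOR entries pooled across all animals are
excluded. Welch's unequal-variance t-test (two-sided, Welch–Satterthwaite
df) declares a cytokine upregulated when p < α (default 0.05) **and** the
case mean exceeds the control mean; no multiple-testing correction is
applied across the 45-plex panel — a deliberate screening convention that
inflates family-wise error, documented as a caveat. Fold changes are
per-case-animal ratios to the control-group mean of detected values;
cross-model differences in fold change use the same Welch test. OOR values
are never imputed.

Calibration facts established by simulation (and asserted in the tests):
at balanced n = 9/9 with low noise the per-cytokine type-I error is ≈0.047,
within 2 binomial SE of α. Two caveats a user should know: (i) Welch's
test itself is liberal at the study's unbalanced design — ≈0.061 at
n = (9,3) on Gaussian nulls, a property of the Welch–Satterthwaite
approximation, not of this implementation (scipy reproduces it); (ii) at
the default 40% CV the log-normal skew makes the two-sided test
conservative (≈0.039) at balanced n.

GTT AUC uses the trapezoidal rule on the 0/0.5/1/1.5 h samples (exact for
piecewise-linear curves), in mg·h/dl; the diabetic call is strictly
AUC > 435.

## Correlation networks

Per experimental group, Pearson correlations are computed pairwise-complete
over detected values; pairs with <3 complete observations or a constant
cytokine are undefined and never form edges. Edges exist where |r| > τ
(default 0.7, strict), including strong negative correlations; graphs are
undirected and unweighted for all metrics, with r kept as an attribute.

- *Eigenvector centrality*: dominant eigenvector of the full 0/1
  adjacency by power iteration on A + I (the shift prevents sign
  oscillation on bipartite components), non-negative, L2-normalized,
  tolerance 1e-10. On disconnected graphs, components not carrying the
  dominant eigenvalue decay to ~0 — a documented convention, since with
  n = 3 animals per control group networks are frequently fragmented. An
  edgeless graph returns the uniform vector.
- *Betweenness*: Brandes convention, fractional credit over tied shortest
  paths, unnormalized.
- *Average path length*: mean hop count over unordered pairs at finite
  distance; disconnected pairs are excluded from numerator and denominator.
- *Louvain* (resolution 1, seeded visit order) with Newman–Girvan Q of the
  returned partition.
- *k-hop reachability* by boolean adjacency powers (BFS-equivalent,
  verified against an independent BFS oracle); *Jaccard similarity*
  between two reachability relations over the label-union alignment of
  unordered off-diagonal pairs. Two empty relations over identical node
  sets are identical, J = 1.
- *Hub ranking*: top-k (default 5) per metric per model with a
  deterministic (value desc, name asc) tie-break; shared = intersection,
  unique = set difference.
- Layout export uses a seeded Fruchterman–Reingold embedding; nodes carry
  eigenvector centrality as color and betweenness as size.

A known small-sample caveat: at n = 3, |r| > 0.7 has high false-edge
probability; the per-pair sample counts are reported but not filtered on.

## Morphometry

Volumes are smoothed with a 3-voxel Gaussian window per axis (σ =
kernel/4 so the window spans ±2σ; edge-replicated borders preserve
constants). The whole-disc mask is built from closed perimeter contours on
every tenth transverse slice: each polygon is rasterized and converted to
a signed distance field, and intermediate slices threshold the linear
blend of the two bounding fields at zero — a precise definition of
"morphing by linear interpolation" that is linear in radius for concentric
circles. The NP is segmented within the disc mask by Otsu threshold (or a
fixed override), a 3×3×3 morphological close then open, and retention of
the largest connected component, intersected with the disc mask.

Metrics: NPVF = NP/disc voxel ratio; NI/DI = NP mean intensity over
whole-disc mean intensity (disc includes NP); DHI = mean height/width of
the disc mask over five sagittal slices centred on the mask centroid
column, height along the stack axis. Numerical choice worth noting:
segmentation runs on the smoothed volume, but intensity metrics are taken
on the original volume — blur at the NP boundary otherwise biases NI/DI by
>2% for small cores, while on the raw volume recovery is within 0.6%
(NPVF within 1.3%) across planted NPVF 0.05–0.4.

## Mechanics

Cycles are delimited at positive-going zero crossings of the mean-centered
displacement, tolerating 1% timing jitter; analysis defaults to the last
10 of 20 cycles (preconditioning discard). The loading slope is the
least-squares force-displacement slope on the rising branch restricted to
the central 20–80% of the cycle's displacement range — a symmetric window,
so for an elliptic loop the even-in-x curvature term cancels and the slope
estimates k·cos δ. Tan δ comes from single-frequency sin/cos least-squares
fits to displacement and force at the nominal frequency (more robust than
an FFT peak on 20-cycle records); a fit residual above 50% of signal power
rejects non-sinusoidal input, and the delay is wrapped to [0, π/2).
Hysteresis energy is the mean absolute shoelace area of the per-cycle
force-displacement polygon, exact to O((2π/n)²) for sampled ellipses and
invariant to preload. The three metrics are mutually consistent on lagged
sinusoids: E/(πF₀X₀) = sin δ and tan(Δphase) = tan δ within 1%.

## Limitations

Units are fixed (pg/ml, µm, N, mg/dl, hours); no unit inference is done on
file input. DICOM input is not supported (no DICOM reader in the
dependency set); volumes are TIFF stacks with a JSON voxel-size sidecar.
Multi-group ANOVA post-hocs, correlation-significance filtering, weighted
network variants and histological scoring are out of scope. The
literature-reported network numbers for the original animal cohorts cannot
be reproduced without the raw per-animal panel, which is not public;
correctness is instead established against planted ground truth and
brute-force oracles.
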