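# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `neurocult`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Synthetic culture fields

`simulate.generate_frame` renders a square field (default 1.5 mm at
1.0 µm/pixel, i.e. 1500×1500 px) containing `n_cells` (default 220)
somata modelled as filled discs with radii drawn uniformly from
5–12 µm. Somata are placed by rejection sampling with a minimum
boundary-to-boundary gap of 8 µm; failure to place the requested count
raises an error naming the achieved count. An optional `clump_fraction`
places somata overlapping a host to emulate cell clumps (default 0 — the
reference field is clump-free; clump handling is exercised explicitly in
tests).

**Connection model.** Every pair of somata within `distance_cutoff_um`
(default 150 µm) is a candidate; each candidate independently becomes a
dendrite with probability `synapse_prob` (default 0.12). A dendrite is a
straight center-to-center segment with a small perpendicular mid-point
jitter (±4 µm), stroked at a width drawn from 1.5–3 µm. "Stub"
dendrites — attached to one soma only, pointing into free space — are
added at `stub_fraction` (default 0.05 per cell) to verify they never
count as synapses.

**Geometric clearance.** A candidate dendrite is rejected (and then does
not exist, in the image *or* in the truth graph) if its stroke, clipped
to outside its endpoint discs, would come within 8 µm of another
dendrite's stroke or of a non-endpoint soma disc. Two reasons:
(i) crossing strokes would merge into one connected foreground
structure, so the rendered image would no longer express the recorded
ground truth — the simulator's contract is that truth and render agree
exactly; (ii) the clearance (8 µm) deliberately exceeds the masking
chain's attachment tolerance (5 µm), so a passing stroke can never be
mistaken for an attached one. Real cultures of course contain crossing
neurites; frames rendered here are therefore "sortable" in a way real
images are not, and pass rates on them bound what the chain can do on
real data from above (see §7).

Rendering uses exact Euclidean rasterization: a pixel belongs to a disc
or stroke iff its *center* lies inside the shape (pixel (row, col)
center at ((col+0.5)s, (row+0.5)s), pixel size s). The image is
background 30 / foreground 200 on a 0–255 scale, with optional additive
Gaussian noise clipped to range. All randomness flows from one
`numpy.random.default_rng(seed)`; identical parameters give bit-identical
scenes.

The documented noise level for robustness claims is `noise_sd = 12`
(`simulate.ROBUSTNESS_NOISE_SD`): at a foreground–background separation
of 170 this leaves the two intensity modes ~7 standard deviations apart,
which is representative of well-exposed phase-contrast masks rather than
of low-light imaging.

## 2. Masking chain

`enhance` applies a mean-anchored linear stretch — the adopted reading of
"increase contrast by 30 %": deviations from the image mean scale by
1.30, clipped to range — followed by unsharp masking with amount 0.45
and a 1 px Gaussian radius for "sharpen by 45 %". No specific operator
is canonical for either phrase; both choices are configurable.

`segment_foreground` uses global Otsu thresholding by default (strategy
`fixed` is available). The threshold maximizes between-class variance
over a 4096-bin histogram and is reported as the *upper edge* of the
optimal bin: with a bin-center convention, a nearly-delta background
mode (exactly what a constant-background render produces) can sit in the
upper half of the threshold bin and be classified as foreground
wholesale. A constant image raises a degenerate-threshold error.

`detect_cell_bodies` opens the mask with a Euclidean disc of radius
4 µm (implemented as two distance transforms, which is exact and O(N)).
Opening removes every structure thinner than 8 µm — all dendrites — and
leaves the cell bodies, which are registered as circles (centroid +
equivalent-area radius). Regions are filtered by area (≥40 µm²) and
circularity (4πA/P² ≥ 0.6, clipped to [0,1]); regions larger than
`clump_area_multiple` (default 3) × the median region area are flagged
as clumps with `estimated_cell_count = round(area / median area)`
(configurable to count clumps as one). The multiple of 3 was chosen so
that the largest single soma the simulator draws (radius 12 µm,
~2.1× the median area) is never flagged. Detections are sorted by
position for deterministic ids.

`mask_dendrites` subtracts the detected soma discs (padded by 1.5 µm)
and keeps thin residual structures. Local width is 2× the Euclidean
distance transform; any connected structure containing a point wider
than the 0.06 mm threshold is excluded whole. The threshold is read as
the *maximum* width for a dendrite — 60 µm far exceeds any neurite
caliber, so it separates lines from bodies/debris; the opposite reading
(minimum) would classify nothing in a culture image as a dendrite.
Components under 3 px are dropped as speckle.

`trace_dendrites` thins the dendrite mask (morphological thinning rather
than Zhang–Suen skeletonization: thinning preserves the tips of thin
diagonal strokes, which Zhang–Suen retracts by many pixels — enough to
defeat any reasonable attachment tolerance) and emits one trace per
connected component: the longest path through the component's thinned
skeleton, found by double breadth-first search (exact on trees, which
clean strokes are; robust to short spurs). Trace length is the polyline
segment sum × pixel size; mean width is 2× the mean distance-transform
value along the path. A path endpoint within 5 µm of a soma circle (or
inside it) attaches to the nearest soma by boundary distance, ties going
to the lower id. One consequence of per-component tracing: two truly
crossing neurites would yield a single trace; under the simulator's
clearance rule this does not occur, and on real images it would
undercount synapses (a conservative failure mode).

## 3. Connectivity graph and counts

Cells are vertices; each trace with two attachments to *distinct* somata
adds one edge (self-loops are discarded; traces with 0–1 attachments add
nothing). Synapse events are counted on the multiset — parallel
dendrites between the same pair are separate events, because an
events-per-cell frequency is event-level. Networks are connected
components with ≥3 members of the *simple* (deduplicated) graph — a
"group of cells" is set-level. Nodes default to synaptic connections
inside a network (intra-component simple edges), following the reading
that networks "include synaptic connections, which are defined as
nodes"; the grammatically possible alternative (node = member cell) is a
switch (`node_mode="cell"`), and outputs record which was used.
Frequencies divide by total detected cells, including clump-estimated
counts (configurable), and are per-frame.

## 4. Plate statistics

Shapiro–Wilk per group (n ≥ 3 required; zero variance is a degeneracy
error; non-normality emits a flag, never an automatic switch to
nonparametric tests). One-way ANOVA from closed-form sums of squares.
The post-hoc default is Tukey HSD — the standard companion when all
pairs are of interest — with Dunnett many-to-one available since most
reported contrasts are versus a control. Fold change is the ratio of
group means, percent change `(fold−1)×100`, summaries are means ± SEM,
and stars map strictly: `*** p<0.001`, `** p<0.01`, `* p<0.05`, `ns`
otherwise (p = 0.05 is `ns`).

Calibration of the chain's Type-I error is measured with the ANOVA
F-test as the family-level gatekeeper (a replicate "rejects" iff ANOVA
p < α); Tukey's own familywise error under the null is checked
separately. The null simulation is vectorized (closed-form F over a
replicate axis), so 10,000 replicates of 4 groups × n=6 cost well under
a second.

## 5. Proteomics chain

Input is a proteinGroups-style TSV; intensity zeros are missing (the
MaxQuant convention), as are NA. Processing order: drop
contaminant/decoy rows → keep proteins present in ≥50 % of samples
(inclusive boundary: 2-of-4 passes) → impute → log2 → normalize. The
two filters commute (both are row predicates), which the tests assert.

**Imputation** defaults to the down-shifted Gaussian standard in
label-free work: per sample, missing values are drawn (on the log2
scale) from N(mean − 1.8 sd, (0.3 sd)²) of that sample's observed
distribution, then back-transformed; `half_min` is the alternative.
Observed values are never touched; draws are seeded per sample in fixed
column order.

**Normalization**: "classic" is read as per-sample median centering to
the grand median on the log2 scale (afterwards all sample medians agree
to machine precision); quantile normalization is a switch, and outputs
record which ran.

**Differential expression**: per protein, log2 fc = mean(A) − mean(B)
and Welch's two-sample t-test on log2 values (robust to unequal
variances; the underlying test is unnamed in most reports of this rule).
The call is `max(fc, 1/fc) > 1.5 AND p < 0.1`, both inequalities strict,
applied to *raw* p-values — the rule as stated carries no
multiple-testing correction, and the planted-recovery numbers document
how permissive that is rather than hiding it. Sensitivity in those
checks is computed over planted proteins that survive the presence
filter: a spike whose intensities fall below the detection limit in
enough samples is never tested by *any* rule, so it does not measure the
rule's power. The count of untested spikes is reported alongside.

**PCA** centers per protein and decomposes the sample × protein matrix
by SVD; variance fractions are non-increasing and sum to 1 over retained
components; each component's sign is fixed by making its
largest-magnitude loading positive. **ORA** is a hypergeometric
upper-tail test per user-supplied set (sets are intersected with the
background first) with Benjamini–Hochberg adjustment across sets; no
external annotation databases are consulted.

**Protein simulator.** log2 base abundances are uniform on 21–28 plus
N(0, 0.5²) spread; within-group noise sd 0.25 (log2) — mid-range for
replicate label-free LFQ; exactly `round(n_proteins × spike_fraction)`
spikes (default 50 of 1000) at ±1 log2 unit with random sign, planted
only in unflagged rows; 5 % contaminant rows; 10 % missingness,
intensity-dependent by default (a value goes missing when it falls below
a detection limit placed at the missing-rate quantile, with N(0, 0.3²)
probit jitter) because that below-detection mechanism is what
down-shifted imputation models; MCAR is a switch.

## 6. Pipeline, seeds, determinism

A single global seed fans out to per-stage seeds via
`numpy.random.SeedSequence([seed, stage])`, truncated below 2³¹, so any
stage reruns in isolation. Every tabular output embeds a SHA-256 hash
(first 16 hex digits) of the canonical JSON of the configuration plus
the seed; two runs with the same configuration are byte-identical in
every data artifact. The run report additionally records wall-clock
times per stage and is therefore excluded from byte-identity. Physical
pixel size is a required input everywhere an image is interpreted —
there is no silent default.

## 7. Problem sizes and what passing shows

The full-scale checks use 20 frames of 1500×1500 px with 220 cells each
(clean and at noise sd 12), 500 random graphs of ≤12 vertices against an
exhaustive-reachability oracle, 10,000 null replicates for ANOVA
calibration, and one 1000-protein planted matrix; unit tests use
0.4–0.6 mm fields with 20–40 cells. These sizes make the default suite
and the acceptance script each run in a few minutes on one CPU.

Exact ground-truth recovery on clean renders shows the chain's counting
logic is correct, not that it would be exact on micrographs: real
phase-contrast images have uneven illumination, out-of-focus halos,
touching and crossing neurites, non-circular somata and debris, none of
which the generator produces. The noise robustness result covers
additive Gaussian noise only. Likewise the plate and proteomics
generators draw from exactly the distributions the tests assume
(Gaussian wells, log-normal intensities), so calibration results
transfer to real data only to the extent those assumptions hold.

## 8. Known limitations

- No optics model (PSF, shading) and no 3D scene generation; the
  simulator is a geometry benchmark, not an image-realism benchmark.
- Crossing neurites are not generated and, if present in supplied
  images, merge into one trace (synapse undercount).
- Clump cell-count estimation is an area ratio and is approximate by
  construction; it is exercised, not certified, by the tests.
- The headline effect sizes of vitamin-combination studies (e.g.
  +97.32 % viability, 4-fold synapsing) derive from unpublished raw
  data; this package reproduces the *conventions* (the same planted
  ratio yields the same printed line) and the machinery, not those
  numbers.
- The DE rule's raw-p threshold is reproduced faithfully; users wanting
  FDR control should consult the BH-adjusted ORA output or apply their
  own correction to the reported p-values.
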