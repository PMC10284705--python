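# Methods

## Scope and data model

The package analyses longitudinal multi-channel image stacks of arrayed
dermal microtumours (tumour reporter, T-cell reporter, optionally a
GCaMP6 calcium channel) and the per-tumour tables derived from them.
Time is a uniform grid of integer days; irregular sampling is handled by
masking days, never by changing the grid. Phenotypes are coded
1 desert / 2 excluded / 3 inflamed plus two absorbing codes: 5 from the
first day a tumour is durably undetectable (rejection) and 0 from mouse
death/euthanasia; once a timeline enters 5 or 0 it stays there.

## Synthetic cohorts

The generator is first-class: it defines the conditions under which the
analysis is validated.

**Phenotype dynamics.** Each tumour's daily phenotype is a realisation of
a Markov chain over the five codes. A cohort is a mixture of three
archetype classes mirroring the canonical trajectory classes: class I
(persistently excluded, rising T-cell abundance, rare rejection), class
II (excluded until an inflammation switch at day 8 opens a fast
excluded→inflamed conversion), class III (early inflamed, high
infiltration, rejection hazard 0.12/day). Mixture weights
(0.40/0.32/0.28) and per-class rates were fixed once, by simulating the
scenario during design, so that ~30% of tumours resolve by day 14 — the
spontaneous rejection fraction of immunocompetent hosts that the default
scenario is meant to emulate. A shared mouse-loss hazard of 0.005/day
produces occasional death-censored timelines.

**Growth.** Area follows logistic growth `a(t) = K a₀ e^{rt} / (K + a₀(e^{rt}−1))`
with K = 0.5 mm², a₀ = 0.05 mm² and per-tumour lognormal r (mean
0.35/day, CV 0.2). On entry into the resolved state the area decays
exponentially (1.2/day) and the tumour leaves the detectability set
below 0.01 mm².

**Emissions.** Per day each live tumour emits a (T-cell abundance, core
infiltration ratio) pair drawn from per-phenotype Gaussians (abundance
is in arbitrary units — the T-cell channel is only defined up to scale),
multiplied by a per-class linear abundance trend. The resolved state
emits near-inflamed values because rejection leaves a dense residual
T-cell cluster. These emissions are deliberately separable: they encode
the assumption that phenotype and trajectory class express themselves in
the imaging features. Passing recovery tests on these cohorts therefore
demonstrates correctness of the machinery, not that real cohorts are
this clean.

**Rendering.** Tumours are flat-top radial blobs (`exp(−ln2·(r/r_eq)^8)`)
whose half-maximum radius equals the equivalent radius of the true area,
so segmented areas match ground truth by construction. The T-cell
channel renders the phenotype's spatial signature: nothing for desert; a
rim annulus (width 20% of r_eq) plus an 8% diffuse in-mask level for
excluded — excluded lesions confine T cells, they are not T-cell-free,
and the diffuse term is what gives them a higher in-mask median than
deserts, as in real arrays; a filled disc for inflamed; a residual
cluster for resolved. The GCaMP channel adds single-frame flash discs,
Poisson-distributed with per-phenotype rates. Gaussian/Poisson noise is
applied last and defaults to off; validation criteria are stated for the
noise-free default. Randomness uses one root `SeedSequence` split into
per-tumour substreams, so enlarging a cohort reproduces the smaller
cohort's tumours exactly.

**What the generator does not emulate.** Real point-spread functions,
vasculature, autofluorescence, skin deformation between days, per-mouse
correlation of outcomes, or intensity units tied to physical MFIs.
Per-phenotype intensity magnitudes are not published; defaults were
chosen only to make the classifier's decision regions realisable.

## Image analysis

**Segmentation** replaces the original learned model with a classical
pluggable pipeline (Gaussian σ = 1 px, Otsu threshold with fixed-value
fallback, ≥ 20 px area floor, 8-connected labelling): the downstream
mathematics, not the CNN, is the contribution, and a learned segmenter
can be dropped in behind the same interface. Native resolution is kept.

**Tracking** links frames greedily by mutual nearest centroids under a
maximum displacement (default 300 µm); unmatched tumours stay active as
"not detected" and may re-link, which protects complete-response calls
from single-frame dropouts (CR requires ≥ 2 terminal undetected days).

**Geometry.** Area = pixel count × (pixel size/1000)²; Feret diameter =
maximum pairwise distance between boundary-pixel centres (boundary =
mask minus 4-connected erosion, maximised over convex-hull vertices).

**Radial coordinate.** The profile normalises distance-to-centroid by the
equivalent radius √(A/π); "central 50% of the isosurface" is read as 50%
of mask *area* (radius ≤ √0.5) and the "inner 25%" of the ratiometric
rules as the inner 25% of normalised *radius* (r ≤ 0.25). Both readings
are configurable; the sources leave the radial convention undefined.
MFIs are arithmetic means within a region per day; medians are taken
across days, and across pixels only where a median is explicitly part of
the statistic.

**Classification.** "Consistently" above/below a ratiometric cut-off is
read strictly — all inner-radius bins must satisfy it (a relaxed
fraction is configurable). Rule precedence is inflamed → reclassified →
excluded → desert → propagate. The desert threshold is frozen on the
first imaging day; the inflamed core reference is recomputed daily from
that day's inflamed calls in a two-pass sweep, and reclassification is
disabled on days with no inflamed tumour. First-day tumours that are
indeterminate and not desert default to excluded, the modal early state.
Every emitted code carries a provenance tag. On a same-day conflict
between death and resolution, death wins.

## Phenotype dynamics

Transition counting stops after the first entry into an absorbing state:
timelines are padded with 0/5 for bookkeeping, and counting those
self-loops would let padding dominate the probabilities (a flag restores
them). Probabilities are row-normalised; absorbing rows get a unit
self-loop by convention; zero-count live rows are reported missing.
Significance uses a within-tumour shuffle null (default 10 permutations,
matching the original analysis; configurable upward) with add-one
two-sided empirical p-values; each permutation preserves every tumour's
pre-absorbing state multiset. Whether the shuffle should instead permute
across the cohort is not documented in the original description;
within-tumour is the implemented reading.

Trajectory clustering uses Ward linkage on per-day z-scored
(abundance, ratio) vectors, with interior missing days linearly
interpolated and edges held. The class count is selected by the
Calinski–Harabasz variance-ratio criterion over k = 2..6. Average
silhouette — the more common default — was evaluated first and rejected:
for trajectory classes that share their early time course (class II is
excluded, like class I, until its switch day; that nesting is the
phenomenon, not an artefact) the silhouette curve is flat or decreasing
in k and systematically merges the nested pair, while the
variance-ratio criterion recovers the generative count on every seed
tested. Silhouette is retained as an absolute-scale degeneracy guard: if
the selected partition scores below 0.2 (or all trajectories are
identical) the cohort is reported as one effective class. Heat-map
ordering of timelines uses average-linkage clustering of Hamming
distances.

## Calcium and PI influx indices

All four indices follow the respective acquisition geometry:
epifluorescence normalises the mean absolute frame-to-frame change of
summed in-mask intensity by the channel's across-frame mean pixel
intensity and takes the GCaMP/reference ratio; two-photon multiplies
that ratio by the ratio of mean per-pixel temporal SDs (population SD);
confocal and PI divide the mean absolute change of the per-frame median
of per-cell MFIs by its across-frame mean. "Averaged … and normalized"
is implemented as normalising the averaged delta; the operations commute
for the formula as written. Masks are held fixed across a movie;
photobleaching is not corrected (a linear detrend exists behind a flag
conceptually but is deliberately not default — the original quantities
are uncorrected). Degenerate denominators (constant reference, zero
mean) yield NaN, reported as missing rather than raising.

## Survival

The survival unit is the tumour, not the mouse; intra-mouse correlation
is ignored, matching per-lesion survival reporting. Event time is the
first resolved day; death censors at the last observed pre-death day;
ties between events and censorings follow the standard
events-before-censorings convention. Estimation uses the product-limit
estimator with Greenwood variance and a log-log (exponential Greenwood)
95% band; group comparisons use pairwise log-rank tests against a
designated reference. Grouping by phenotype uses a landmark day
(default 8) with later phenotype changes ignored, the day being
configurable.

## Validation sizes and determinism

The test suite validates against independent brute-force oracles on
small fixtures (exact to 1e-10), and at scale uses: 2 000+ observed
transitions per row for Markov parameter recovery (max error < 0.05),
500-tumour cohorts for the day-14 calibration, 300 tumours for class
recovery, a 64-tumour × 15-day array for segmentation fidelity, and 500
null replicates (n = 200/arm, exponential event times, fixed horizon)
for log-rank type-I calibration. These sizes were chosen to keep
sampling error well inside the stated bounds while remaining quick on a
single CPU. Every stochastic stage is reproducible bit-for-bit from its
seed.

## Known limitations

The automated mutual-nearest tracker stands in for manual track
curation and is not validated against human tracks; the SD/PD split
(±20% of initial area) is an explicit convention the original reporting
leaves merged; the desert threshold degenerates if ≥ 25% of first-day
tumours are true deserts with zero background (threshold 0); and the
infiltration index is undefined (reported missing) when the periphery
median is zero.
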