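# Methods

## Scope and data model

`csmorph` operates on single-neuron reconstructions in which every sampled
point carries a tree link (`sampleNumber`/`parentNumber`), a structure class
(1 soma, 2 axon, 3 dendrite), an Allen CCF structure id (`allenId`, 0 when
unannotated) and x/y/z coordinates in µm (x medial-lateral, y dorsal-ventral,
z anterior-posterior). The reader merges the dialect's axon and dendrite
arrays into one sample list; the structure class is taken from the array of
origin, which is authoritative over any per-sample code, so downstream code
sees a single uniform tree. Real exports number axon and dendrite samples in
separate id spaces; colliding dendrite ids are shifted by a constant offset
to keep sample ids unique. Parent id −1 marks a root; a sample parented to
the soma is not a root. Coordinates are kept exactly as stored — no
resampling, registration or deduplication (duplicate coordinates count as
distinct end-points, because end-points are samples, not locations). SWC
input is supported through an external region assigner, since SWC carries no
atlas annotation.

## Region policy

Striatal membership is an **exact id set** — Striatum (477), its dorsal (485)
and ventral (493) regions, caudoputamen (672), nucleus accumbens (56),
olfactory tubercle (754) and fundus of striatum (998), plus the Islands of
Calleja (481, 489) and olfactory-tubercle sublayers (144, 458, 465, 473)
whose inclusion was verified to add no further end-point — never ontology
descent. This makes end-point identification bit-reproducible regardless of
ontology revisions. Pons (root 771), telencephalon (cerebrum, 567) and
cerebral cortex (688) membership are by descent, matching the hierarchical
annotation of the database. Pass-through structures — by default all
descendants of the fiber-tract (1009) and ventricular-system (73) roots —
are treated as evidence neither for nor against an intratelencephalic
projection pattern: parts of tracts such as the corticospinal tract can
belong to IT axons in transit. The published analysis names only examples of
this exclusion set, so it is configurable; the default is our best
reconstruction of it.

The medial-lateral midline defaults to x = 5700 µm and is configurable;
5500 µm is an equivalent historical choice for these data (no end-point of
the analysed cohort lies between the two), and the synthetic atlas keeps a
clear margin around both so the equivalence is testable. A point exactly on
the midline is assigned ipsilateral with a logged warning (deterministic and
visible); a soma exactly on the midline is an error.

## Classification

A neuron with soma in the cerebral cortex and ≥ 1 intra-striatal axonal
end-point is **PT** when its soma layer is 5 and ≥ 1 axon sample lies in the
pons; **IT** when no axon sample lies in the pons and its non-telencephalic
axon fraction is ≤ the exclusion threshold; **EXCLUDED_NON_IT** when that
fraction exceeds the threshold (layer-6a thalamus-projecting cells —
corticothalamic neurons — fall here without any layer rule); otherwise
**NOT_CORTICOSTRIATAL** (this includes pons-projecting cells with non-layer-5
somata, which are deliberately not called PT). The exclusion threshold
defaults to 0 — any non-telencephalic axon sample excludes a candidate IT
neuron — because that is the analysed cohort's final selection; neurons with
small (< 2.2%) contamination arguably could be retained, so the threshold is
exposed. The non-telencephalic fraction counts **all** axon samples in its
denominator (annotated or not) and only non-telencephalic-class samples in
its numerator.

Soma area (MOp/MOs/other) is resolved by walking the soma structure's
ancestor chain for a configured motor-area name; the layer is parsed from a
"layer …" token in the soma structure's own name (longest token first, so
"layer 6a" is never read as "layer 1"/"layer 6"). Layer annotations are taken
at face value; near a curved cortical surface some layer-2/3 annotations may
in reality be upper layer 5, which this package cannot detect.

## End-points and metrics

An axonal end-point is an axon-class sample whose id appears as the parent of
no axon-class sample. Leaf status is judged against axon children only: a
sample whose only children are dendritic is still an end-point. A striatal
sample with an axon child outside the striatum is therefore not an end-point.

Per-neuron metrics use (n−1)-normalised standard deviations, **defined as 0
for a single point** so that one-end-point neurons appear in dispersion
histograms and correlations (analyses are reported with and without them).
The normalisation convention is inferred from that single-point behaviour;
both conventions differ only at small n and the metrics module is the single
place where the choice lives. ln n_ipsi uses the natural log; Welch p, d,
r and regression p-values on logged counts are invariant to the base (a pure
rescaling), so only plot axes would depend on it. Neurons with n_ipsi = 0
are excluded from every logarithmic and dispersion analysis ("log 0"), and
every comparison records its inclusion rule and the resulting group sizes so
excluded + included always equals the group total.

## Statistics

* Welch's t (unequal variances, Satterthwaite df, two-sided), computed by
  `scipy.stats.ttest_ind(equal_var=False)`. Cohen's d uses the classical
  pooled SD and absolute value, d = |μ₁−μ₂|/√(((N₁−1)s₁²+(N₂−1)s₂²)/(N₁+N₂−2));
  it is deliberately not Welch-adjusted.
* χ² is the uncorrected Pearson statistic (`scipy.stats.chi2_contingency`,
  `correction=False`), df = 1, with φ = √(χ²/(N₁+N₂)). The no-continuity-
  correction choice is pinned empirically: the published pair (p = 0.042,
  φ = 0.15) is recovered from the printed table 48/97 vs 5/28 only without
  Yates correction. The ">50 end-points" dichotomy threshold is
  configuration, not a constant — small changes make the IT/PT difference
  non-significant, so sensitivity analyses need it exposed.
* Pearson r with the t-transform p (n−2 df); simple OLS (statsmodels) with
  standard-error-based two-sided p-values for intercept and slope.
* All tests are two-sided; no multiple-testing correction is applied,
  matching the analysis this package reproduces.
* Degenerate inputs: two zero-variance samples with equal means give t = 0,
  p = 1; with unequal means they raise; a zero column gives χ² = 0, φ = 0;
  constant variables make correlation/regression raise (or, for a flat
  response with varying x, r = 0).

## Synthetic data

The generator emulates the features the analysis depends on and nothing
more. A fixed toy atlas reuses real Allen ids over axis-aligned boxes,
mirror-symmetric about x = 5700 µm, with caudoputamen boxes on both sides
and cortical-layer boxes stacked in depth; every box stops ≥ 10 µm short of
the midline (and the soma/striatum boxes stop short of 5500 µm), so the
5500-vs-5700 midline equivalence holds by construction. Every generated
sample's `allenId` is assigned from the containing box, exactly as the
database annotates reconstructions.

Ipsilateral end-point counts follow a zero-truncated geometric law on
{1, 2, …} (mean 1/p), giving the roughly monotonically decreasing count
distributions seen in real cohorts, with a separate zero-inflation
probability for neurons lacking ipsilateral end-points. End-point
coordinates are Gaussian per axis around a per-neuron centre drawn inside
the striatum box and rejection-resampled into the box. Rejection truncation
biases the realised SD downward; the bias is accepted and measured, not
corrected — it stays under 10% for generating SDs ≤ 200 µm at n ≥ 200 points
and reaches ~20% at 400 µm in the default box. Tests that assert SD recovery
therefore use moderate spreads; tests of group *differences* are unaffected
since the ordering of spreads is preserved.

Default cohort parameters are the package's standing model of the study
conditions: IT neurons with zero-ipsi inflation 0.10 and contra-targeting
probability 0.74 (the observed 16/161 and 119/161), ipsilateral count mean
30 vs 20 for PT, and per-axis spreads (400, 300, 300) µm for IT vs 200 µm
isotropic for PT. PT-like neurons get a two-sample pons branch;
corticothalamic-like contamination places a chain of thalamic axon samples
sized to hit a requested non-telencephalic fraction. Trees are built so that
ground truth is exact: the striatal hub node always parents the drawn
end-points (hence is never a leaf), and the generator records the label its
construction implies.

What passing synthetic tests does **not** show: real reconstructions have
biologically realistic branching statistics, curved region boundaries,
annotation noise and unannotated samples in places the toy atlas never
produces; recovering generated labels and spreads validates the pipeline's
logic, not the anatomy.

## Problem sizes and determinism

All stochastic tests fix their seeds. The default test run uses cohorts of
10–200 neurons, 100-seed power replications (spread 400 vs 200 µm, n = 40
per group, detection at p < 0.01), 1000-tree brute-force cross-checks and
1000-replicate null calibrations — sizes chosen so the whole suite completes
in well under a minute per heavy test while keeping Monte-Carlo error small
relative to the asserted bands. Reproducing the published cohort counts
end-to-end requires downloading the 220 DOI-versioned entity files (see
`data/manifests/cohort.tsv` and the `fetch` subcommand) plus the full Allen
structure graph; that path is deterministic once the files are present.

## Known limitations

* No volumetric atlas lookup: region ids come from the reconstruction files
  (or, for SWC, from a user-supplied assigner).
* No bouton/synapse inference and no axonal path-length computation; the
  end-point count is a proxy whose relation to synapse counts is itself an
  open question.
* The pass-through exclusion set is a reconstruction of an under-specified
  list and is configurable rather than canonical.
* Plots are not produced; the comparison report is tabular/textual.
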