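# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic-fixture tests do and do not
demonstrate about real neuroimaging data.

## Coordinate and ordering conventions

All geometry lives in millimetre "world" space through the parcellation's
4×4 affine; voxel indices are 0-based, and a millimetre point is mapped
to a voxel by applying the inverse affine and flooring the continuous
index. This single rule is used both by the streamline-assignment code
and by the fixture generator, so planted endpoint memberships are exact
by construction.

The canonical ROI ordering — subcortical regions with left/right
interleaved, then left cortical, then right cortical, alphabetical by
name within each block — is a pure function of the ROI table
(hemisphere, tissue class, name), never of file order. It fixes the
block structure of the matrix view (intra-subcortical, intra-left,
intra-right, and the mixed blocks) and makes every matrix, report and
figure deterministic.

## Anatomical connectivity

The a-CM relates two ROIs by the ratio of a morphometric measure. The
orientation of a raw ratio mᵢ/mⱼ is arbitrary, so the default is the
symmetric min/max ratio, which is bounded in (0, 1], equals 1 exactly for
identical measures, and is invariant to global rescaling of the measure.
A directional mode (`symmetric=False`) retains the raw ratio for users
who want the asymmetric variant. Measures defined for only one tissue
class (CT/SA/GMV cortical, volume subcortical) yield a matrix over that
class only, avoiding undefined entries.

## Structural connectivity

Streamlines are assigned to ROI pairs by their two *endpoints* (not by
pass-through traversal): each endpoint takes the label of its containing
voxel; background or out-of-volume endpoints leave the streamline
unassigned. Endpoint semantics match deterministic streamline
tractography output, are order-reversal invariant, and admit an exact
brute-force oracle. Same-ROI loops are excluded from the matrices (the
diagonal is identically zero) and counted in a QC report. No endpoint
dilation or nearest-label search is applied — determinism first.

Fiber length is polyline arc length in mm. "Mean fiber orientation" has
no unique definition; here it is the normalized mean of sign-aligned
end-to-end unit vectors per pair (sign-aligned so that antiparallel
end-to-end vectors of the same bundle do not cancel). This is one of
several defensible definitions and is documented as a package choice.

## Functional, effective and PET connectivity

Pearson correlations carry two-sided p-values from the exact t transform
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom; a permutation oracle
in the tests confirms the transform at small n. The Bonferroni family
for undirected matrices is the R(R−1)/2 unique pairs (the matrix is
symmetric, so each pair is one test); for the directed effective matrix
it is R(R−1) ordered pairs, because each direction is a separate
hypothesis.

Granger causality is pairwise and time-domain: at order p the restricted
model regresses the target on its own p lags plus intercept, the full
model adds the driver's p lags, and

    GC = ln(RSS_r / RSS_f),
    F  = ((RSS_r − RSS_f)/p) / (RSS_f/(T_eff − 2p − 1)),  T_eff = T − p.

The GC scalar is the log variance ratio (zero-floored against negative
rounding); F and p are kept alongside. Order defaults to 1 and is
user-set; no automatic order selection is attempted. OLS uses
`numpy.linalg.lstsq`; the tests verify equivalence against an
independent normal-equations solver. A noiseless deterministic
lag-relation drives RSS_f to 0; that limit is reported as infinite
strength with p = 0 rather than raised as an error.

PET connectivity correlates per-ROI time–activity curves across dynamic
frames within subject (default, matching the dynamic-series reading of
the acquisition); with few frames (8 by default in the fixture,
mirroring a short dynamic scan) the t test has tiny degrees of freedom
and the code warns accordingly. A cross-subject SUV-correlation mode
(`suv_group_cm`) is provided as the alternative reading. SUV is the ROI
mean of the frame-summed volume with optional body-weight/dose scaling;
rSUV divides by a reference region (cerebellum in typical use).

## Group algebra

Mean-CM averages weighted matrices elementwise; robustness-CM averages
binarized matrices, so an entry is the fraction of subjects showing the
connection (0.1 → 10% of subjects, 0.9 → 90%). The combined matrix is
`mean × (robustness > τ)` with τ = 0.8 and a *strict* inequality — an
edge present in exactly 80% of subjects is dropped. The hybrid sf-CM is
the elementwise (Hadamard) product of s-CM and f-CM: a true matrix
product would mix entries across ROI pairs and destroy the
per-connection meaning, so it is not offered.

Direct/mediated decomposition of binary matrices: direct = s AND f,
mediated = f AND NOT s; the two classes partition the functional edge
set exactly, and a structural-only edge belongs to neither. The
mediated-path search runs breadth-first on the binary structural graph,
returning the path with the fewest intermediate regions; ties are broken
deterministically by expanding neighbors in canonical ROI order, and an
optional mode enumerates all minimum-length paths. Weighted shortest
paths are deliberately out of scope.

## Graph metrics and null models

Degree, clustering (binary triangle formula C = 2t/(k(k−1))),
characteristic path length and modularity are delegated to networkx;
the tests check them against hand-rolled exhaustive oracles (triangle
enumeration, Floyd–Warshall, exhaustive partition search on ≤8 nodes).
Characteristic path length averages over reachable ordered pairs only
and always reports the unreachable fraction, so the exclusion is
auditable. Modularity uses seeded Louvain optimization with Q evaluated
exactly for the returned partition.

Null graphs preserve node count, symmetry and edge count (hence mean
degree) by uniformly re-drawing the edge set over the upper triangle;
this is the literal reading of "maintaining symmetry and mean degree."
A degree-sequence-preserving Maslov–Sneppen rewiring mode is available
behind `preserve_degree_sequence=True` for users who want the stricter
null. Normalized indexes divide each metric by its mean over 10 nulls
(configurable); small-worldness is σ = (C/⟨C⟩_null)/(L/⟨L⟩_null). Both σ
and the separate normalized C and L ratios are emitted.

## Group statistics

Between-group tests are Welch (unequal-variance) two-sample t-tests per
target; the pooled-variance variant sits behind `equal_var=True`.
Covariates of no interest are removed by OLS residualization of the
pooled subject vector before testing. The reported direction is the
sign of mean(group 2) − mean(group 1), feeding the red/blue
increase/decrease edge coloring of the connectogram. Multiplicity
correction defaults to none, with Bonferroni and Benjamini–Hochberg
available per target family.

## Synthetic fixtures

The generator plants every quantity the analysis is supposed to recover:
exact per-pair fiber counts (streamlines constructed endpoint-inside-ROI
by the same voxel rule the assigner uses), a lag-1 VAR coupling matrix
(stationarity enforced; burn-in of 100 samples discarded), additive
group effects on morphometry, and shared/distinct PET kinetic profiles.
Noise is Gaussian everywhere, with scalar noise levels interpreted
relative to each measure's baseline magnitude (a dict gives absolute
units). The toy parcellation is mirrored axis-aligned boxes, so
left/right symmetry behaviour is exercisable; hemispheres follow the
sign of the x coordinate.

Defaults: a two-group morphometry study of 15 vs 20 subjects (the
young/old regime of a typical ageing comparison, split at 40 years),
8 PET frames, BOLD repetition time 2 s. The bundled demo study uses 10
subjects and 8 ROIs so it runs in seconds.

What the fixtures do **not** emulate: hemodynamic convolution and
autocorrelated physiological noise in BOLD, kinetic compartment models
in PET, curving fiber geometry and partial-volume effects in
tractography, and spatially correlated morphometric noise. Passing
tests therefore demonstrate the correctness of the matrix constructions,
the algebra, and the statistical calibration under their stated
assumptions — not robustness to the artefacts of real acquisitions.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] before the t transform; the
  transform guards 1 − r² against zero.
* Zero-variance series, non-stationary VAR couplings, rank-deficient
  covariate designs, odd ROI counts, and frame/grid mismatches raise
  errors naming the offending ROI or input.
* Matrix files store values at full double precision (`%.17g`), so
  write/read round-trips are bit-exact and repeated pipeline runs under
  one seed are byte-identical.
* All stochastic components (fixtures, null graphs, Louvain) take
  explicit seeds; the pipeline threads one seed from its config.

## Problem sizes in the test suite

The suites run at desk scale: calibration checks use 500 simulated
null studies (R = 10, T = 100), Granger recovery uses 200 seeds at
T = 300 plus 1000 null seeds at T = 400, oracle equivalences use 100–200
random instances at ≤ 16 nodes, and the end-to-end determinism check
runs a 5-subject, 8-ROI study twice. These sizes make the full suite
complete in well under a minute while keeping binomial/Monte-Carlo error
bars far tighter than the tolerances asserted.

## Known limitations

* Only NIfTI, TrackVis `.trk`, TSV and the text matrix container are
  read; DICOM/Analyze/ECAT ingestion belongs to upstream converters.
* Assignment is endpoint-based; a traversal-counting mode is a
  documented extension point, not implemented.
* Conditional or spectral Granger causality, network-based statistics,
  and weighted path metrics are out of scope.
* Renderers are static (SVG/PNG); interactive hover behaviour is
  replaced by a per-ROI adjacency report.
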