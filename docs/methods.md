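# Methods

## Model and scope

The package quantifies geometric aggregation of rod-like dye molecules in
a periodic orthorhombic cell. Three reductions underlie everything:

* **Center of mass**: mass-weighted mean of atom positions. Molecules are
  required to be whole (no atom pair farther apart than half the smallest
  box edge); input violating this is rejected rather than silently
  rewrapped, because unwrapping policy belongs to the producer of the
  trajectory.
* **Longest molecular axis**: the largest-variance eigenvector of the
  mass-weighted gyration tensor. For rod-like molecules this coincides
  with the smallest-moment-of-inertia direction and is numerically
  simpler. The eigenvector sign is physically meaningless, so a head→tail
  atom convention orients it when available; otherwise the sign is merely
  canonicalized and all angular quantities are folded to [0°, 90°]. A
  relative gap below 1e−6 between the two largest eigenvalues (square,
  sphere-like or planar-symmetric shapes) raises an explicit degeneracy
  error instead of returning an arbitrary axis.
* **Minimum image displacement**: component-wise nearest image, each
  component in (−L/2, L/2]. Only orthorhombic cells are supported;
  triclinic input errors out.

### Pairwise orientational order O(r)

O(r) is the mean second Legendre polynomial P₂(cos θ) of the inter-axis
angle, binned by COM separation. P₂ is even in cos θ, so O(r) is
insensitive to axis sign conventions; it is the unique quadratic in cos θ
taking the anchor values 1 (parallel or anti-parallel), 0 (mutually
random) and −0.5 (perpendicular). Two averaging modes exist: the default
pools every pair observation over all frames with equal weight (the most
literal ensemble-and-time average); the alternative averages per-frame bin
means, which weights frames equally when pair counts fluctuate. For equal
per-frame counts the two coincide (unit-tested). Empty bins are reported
as NaN, never 0, since 0 is a meaningful order-parameter value.

### Angle distributions and RDF

The close-pair angle distribution histograms inter-axis angles for pairs
within `r_max` (default 10 Å, the first-neighbor range), normalized to a
per-degree density integrating to 1. For independent isotropic axes the
oriented angle follows the solid-angle sine law, density sin θ / 2 on
[0°, 180°] — used as a distributional test of the isotropic control.

g(r) uses the standard homogeneous-fluid normalization with exact shell
volumes (4π/3)(r₂³ − r₁³) rather than the thin-shell approximation
4πr²Δr; for one pair in one bin the value is therefore exactly
V_box / (N(N−1)/2 · V_shell). The normalization assumes 3D homogeneity;
slab-confined (bilayer-adsorbed) systems violate it, which is recorded in
the profile's metadata rather than corrected — relative peak positions,
which are what the neighbor-cutoff logic uses, are unaffected.

`first_neighbor_cutoff` locates the first local maximum of g(r) and
returns the bin edge at which its basin ends (the start of the first
local-minimum bin). A moving-average smoothing window is available for
noisy profiles but is off by default; constructed or well-sampled
profiles do not need it. Monotone or flat profiles raise.

### Cluster analysis

Single-linkage connectivity under a COM–COM minimum-image cutoff
(default 17 Å — wide enough to span first and second neighbor shells when
first neighbors sit within ~10 Å), minimum cluster size 2. COM distance is
chosen over minimum atom–atom distance for consistency with O(r), which
is COM-resolved. Components are found with a union-find structure;
neighbor pairs come from an all-pairs scan for ≤ 200 molecules and a
periodic k-d tree (`scipy.spatial.cKDTree` with `boxsize`) above that —
the two paths are asserted identical in the tests. Cluster labels are
deterministic (numbered by smallest member position) and molecules outside
any qualifying cluster carry the sentinel −1. Membership percentage is
100 × (clustered molecules) / (all molecules), averaged unweighted over
frames.

### J/H classification

The stacking angle of a pair is the angle between the bisector of the two
sign-aligned axes and the unit inter-COM vector, folded to [0°, 90°]. The
bisector is robust for the near-parallel pairs the exciton picture
assumes; when the (folded) inter-axis angle exceeds 30° a warning flags
that the J/H dichotomy is being stretched. The classification threshold is
the magic angle: J strictly below 54.7°, H at and above it (the boundary
is assigned to H). `jh_boundary_angle` re-derives the threshold at run
time by bisecting the two-rod pair order parameter for its zero on
[0°, 90°], which lands on arccos(1/√3) = 54.7356…°; this ties the
classification boundary to the order-parameter formalism instead of a
hard-coded constant. Clusters are labelled J if all linked pairs are J,
H if all are H, otherwise mixed.

### Formulation metrics

`ija_icg_ratio` is A₈₉₂/A₇₉₂ read from a spectrum table: the nearest grid
point is used when within 0.5 nm (1 nm plate-reader grids hit both
wavelengths exactly), linear interpolation otherwise. No baseline
correction is applied by default, since the ratio as reported in practice
uses raw absorbances. Encapsulation efficiencies are pure ratios
(× 100%); the doxorubicin variant warns on values above 100% (possible
only through measurement error) but returns them. Zero or negative
denominators raise.

## Synthetic generator

The generator emulates the simulated systems the analyses target: ~15 rod
molecules (3 equally spaced equal-mass atoms, 10 Å long by default) in a
periodic box of order 100 Å, optionally confined to a slab standing in
for a bilayer surface, with bilayer templating reduced to a nematic
director plus a target order parameter S.

* **Axis law**: mixture S·δ(director) + (1−S)·isotropic. ⟨P₂(a·n)⟩ = S
  exactly in expectation, and for independent molecules
  ⟨P₂(aᵢ·aⱼ)⟩ = S² (Legendre addition theorem with uniform azimuths) —
  both moments are closed-form, so testers can derive expectations
  without simulation. The law is deliberately not a realistic
  Maier–Saupe distribution; only its first two even moments matter to the
  statistics under test.
* **Placement**: COMs uniform in the box (or slab), rejection-sampled to a
  minimum separation with a budget of 1e5 attempts per molecule;
  exceeding the budget raises a density-naming error rather than packing
  silently.
* **Planted clusters**: members uniform in a ball of radius
  (intra-separation)/2 around well-separated centers; centers (and
  isolated molecules) are kept more than cutoff + cluster diameter + 1 Å
  apart, so the single-linkage decomposition at the planting cutoff
  equals the planted labels by construction. Intra-cluster separations
  above the cutoff are rejected up front.
* **Frames** are i.i.d. redraws — a stand-in for the ensemble-and-time
  average of a real trajectory. Real MD frames are time-correlated; the
  generator makes no attempt to model that, so error bars estimated from
  synthetic frames say nothing about autocorrelation-inflated errors in
  real data. Likewise the generator has no excluded volume beyond the
  minimum separation, no solvent or lipid atoms, and no coupling between
  position and orientation; passing tests demonstrate the correctness of
  the estimators, not the realism of the ensemble.

All randomness flows from one `numpy.random.default_rng(seed)`; identical
spec + seed is bit-reproducible.

## Problem sizes and numerical choices

Statistical tests run at sizes where closed-form standard errors make the
assertions sharp: 2000 molecules for isotropic/ideal-gas checks (RDF mean
within 0.01 of 1), 8 × 2000-molecule frames for the S² = 0.64 recovery
(pooled pairwise order has molecule-level correlation, so a single frame
carries SD ≈ 0.02; pooling i.i.d. frames brings the sampling error under
the 0.01 assertion), 100 000 axis pairs for the random-orientation anchor
(SE ≈ 0.003, asserted within 0.01), and 200 random configurations of up
to 50 molecules for exact oracle equivalence of the cluster labels.
Angle-distribution agreement with the sine law uses a Kolmogorov–Smirnov
test at p > 0.01.

Defaults: O(r) and RDF bin width 0.5 Å, angle bins 5°, angle range cutoff
10 Å, cluster cutoff 17 Å / min size 2. All are overridable per call and
through the pipeline configuration.

## Pipeline and I/O

The pipeline (`run_pipeline` / `jaggr run-all`) chains load → O(r) →
angle distribution → RDF → clusters → J/H classification, writing tidy
CSV tables and a `summary.json`; every output embeds the SHA-256 hash of
the configuration, and a fixed config + seed reproduces byte-identical
output. Stage failures propagate with the stage name; the CLI exits
nonzero with that name on stderr.

Structure/trajectory input goes through MDAnalysis (PDB, GRO, DCD, XTC),
which reports coordinates in Å regardless of on-disk units (GRO stores
nm); dye molecules are selected by an MDAnalysis selection string with an
optional expected-count assertion to catch topology mistakes. Missing
periodic cells and triclinic cells are hard errors. When masses are
absent and unguessable, the reader warns and falls back to equal masses
(centers of mass degrade to centroids). The native tabular format (atom
CSV + JSON sidecar with box, head/tail convention and provenance)
round-trips generator output exactly.

## Known limitations

* Only orthorhombic cells; no unwrapping of molecules split across
  images.
* RDF normalization is wrong in absolute scale for slab-confined systems
  (flagged, not corrected).
* The stacking-angle construction (axis bisector) is one of several
  conventions in use; alternatives (per-molecule angle to the inter-COM
  axis) differ for strongly non-parallel pairs, exactly where the J/H
  dichotomy is dubious anyway — hence the non-coplanarity warning.
* Cluster analysis is per-frame; no cluster lifetimes or cross-frame
  identity tracking.
* The headline observables of bilayer-templating studies (membership
  percentages near 61%, O(r < 10 Å) > 0.5 in rigid bilayers) emerge from
  long atomistic simulations; this package reproduces the analysis
  machinery and its analytic anchors, and demonstrates the pipeline on
  synthetic surrogates with planted structure.
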