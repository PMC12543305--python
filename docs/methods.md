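# Methods

## The exponential distance rule and its measurement

The package treats a neuron's *main cable* as the tree path between its
closest postsynaptic point (dendritic side) and its closest presynaptic point
(axonal side), "closest" meaning minimal soma-path distance.  Fly neurons
place the soma on the brain surface with a primary neurite diving inward
before branching, so the soma and primary neurite are excluded automatically:
the path between two non-root nodes runs through their common branch point,
not the root.  The *Euclidean cable length* is the straight-line distance
between the same two points; it is the quantity that connects neuron-level
geometry to the region-level model, which only knows centroid-to-centroid
Euclidean distances.

Neurons whose closest synaptic point is far from the rest of its arbor
(mean-minus-min soma-path distance above 0.15 mm for either synapse role) are
filtered out before fitting; these are the signatures of synapse-prediction
errors or nontraditional (dendro-dendritic, axo-axonic) contacts.

**Decay-rate estimator.**  λ is read off the length histogram: log
probability density regressed on bin centers by least squares, repeated over
bin sizes {0.01, 0.02, 0.05} mm, the spread of per-bin-size estimates giving
the reported interval.  Two range rules apply:

- the fit starts at the modal bin — the left edge of empirical length
  histograms is depleted by geometry, and only the tail is exponential;
- bins with fewer than 5 entries are excluded (`min_count=5`).  Conditioning
  on a nonzero count inflates the apparent density of bins whose expectation
  is far below one entry, lifting the far tail and biasing the slope toward
  zero; at n = 10,000 this bias reaches −17% at λ = 20 mm⁻¹ while the
  five-count rule removes it (recovery within ±3% at λ ∈ {20, 33, 50}).
  `min_count=1` restores the plain nonzero-bin rule.  A maximum-likelihood
  cross-check (λ = 1/mean for an exponential sample) is available as
  `ExponentialDecayModel.mle_lambda`.

The tortuosity (scaling) factor *a* relating cable to Euclidean length is the
through-origin least-squares slope: zero Euclidean separation must imply zero
cable length.

## Projectome construction

A neuron's incoming (postsynaptic) and outgoing (presynaptic) synapse counts
per region are normalized to fraction vectors; their outer product is the
neuron's flow matrix (total mass 1), and the raw projectome W is the sum over
intrinsic neurons — afferent/efferent neurons are excluded because their
structure reflects traffic across the brain boundary.  Column normalization
yields w with every nonzero column summing to 1, so w[i, j] is the
probability of information from region i flowing to region j, the analogue of
the fraction-of-labeled-neurons convention in tracing studies.  Within-region
flow (the diagonal) is retained in column sums but excluded from the link
count M, the binary adjacency and all network statistics; both choices are
visible in `Projectome`.

## The EDR / CDR generator

Given D and M, each multi-edge is placed by (a) drawing a distance bin with
probability ∝ exp(−λ·bin center) among *nonempty* bins, (b) drawing an
unordered region pair uniformly within the bin, (c) drawing the direction
uniformly; placement repeats until exactly M distinct directed links exist,
and the multi-edge counts are column-normalized into weights.  Notes:

- Restricting to nonempty bins is equivalent to rejection-resampling a
  continuous exponential draw and guarantees termination: every available bin
  keeps positive probability, so the bin-level placement law is
  exp(−λ·c) · 1{bin nonempty}, which the chi-square acceptance test checks.
- λ = 0 is the constant distance rule (CDR): placed-link lengths are uniform
  over available *bins*, not over pairs — the CDR is still distance-aware
  through bin availability, deliberately so.
- Pairs already linked keep accepting multi-edges (weights keep growing);
  stopping is on the *binary* link count.
- Bin width defaults to (max distance)/50.
- Ensembles use per-network seeds `base_seed + index`; every network is
  analyzed separately and only the derived properties are averaged — averaging
  the weighted networks themselves would change density and bias every
  statistic.

**Model selection.**  `EDRModel.fit` generates an ensemble per λ on a grid,
computes each network's properties, and takes the RMSD between the data's
property vector and each model network's, averaged over the ensemble.
Distribution-valued properties (log₁₀ weights, out-strengths, node distances)
are binned on shared edges computed from the data network; degree spectra are
compared as sorted vectors.  The pooled curve averages per-property RMSD
curves, each normalized by its own mean so that no property dominates by
scale; `lambda_opt_` is the pooled argmin and per-property argmins are also
reported.  Self-consistency: a network generated at λ = 33 mm⁻¹ on the
default atlas is recovered within one grid step (±5 mm⁻¹) with 100 networks
per λ.

## Network measures

Link lengths are l = −ln w; natural log, because shortest-path structure and
RMSD argmins are invariant to the base (a global rescaling), while display
histograms use log₁₀.  Node distances (resistances) are directed weighted
shortest paths on l; global efficiency is the mean conductance 1/r over
ordered pairs with unreachable pairs contributing 0 and exact-zero distances
excluded (and counted).  For the clustering coefficient and local efficiency
the neighborhood of a node is the union of its in- and out-neighbors while
connectivity among neighbors is read from the directed matrix; local
efficiency removes the center node before measuring neighbor-to-neighbor
distances.  The triad census classifies every node triple into the 16
directed three-node configurations via a 64-entry canonical-form lookup
(classes ordered by edge count, the fully reciprocal triangle last).  Cliques
are complete subgraphs of the undirected graph of *reciprocal* pairs; counts
include all complete subgraphs, with maximal-clique summaries separate.
Efficiency-vs-density curves remove links one at a time in weight order
(ties broken by weight, source, target for determinism) without
renormalization.  Backbones greedily delete the weakest link whose removal
preserves strong or weak connectivity; since connectivity only degrades as
links are removed, a link skipped as a bridge can never become removable, and
a single ascending pass is exact.

## Weight asymmetry and hierarchy

ASYM = |w_ij − w_ji|/(w_ij + w_ji) per connected pair; 1 for unidirectional
pairs.  Histograms cover bidirectional pairs by default (the unidirectional
mass at 1 is reported by the reciprocity counts).  The asymmetry network
orients one link per pair toward the predominant direction with weight ASYM;
unidirectional pairs enter with weight 1 and exact ties produce no link.
Regions are ranked by asymmetry out-strength (descending, label tie-break):
sensory-like regions at the bottom of the functional hierarchy export
asymmetry, integrative regions absorb it.

Pair classes follow the label convention: homotopic (same base name, opposite
`_L`/`_R`), ipsilateral (same hemisphere; center regions count as ipsilateral
with each other), contralateral (opposite hemispheres); a center–hemisphere
pair belongs to no class.

## Hierarchical clustering

Regions are clustered on the columns of the link-length matrix — their
incoming-flow profiles.  Absent links receive a finite fill of 1.05 × the
maximum observed length ("very weak" rather than infinite, which would break
Euclidean and correlation geometry).  Ward requires Euclidean distances;
average and complete linkage pair with correlation or cosine dissimilarity
(1 − similarity).  Ensemble co-clustering partitions each network
independently into k clusters and records P_ij, the fraction of networks
placing i and j together; P is then clustered with complete linkage on the
1 − P distances (Ward is not defined for precomputed non-Euclidean
distances).

## The synthetic-data generator

The generator emulates the statistical structure of the real data, not its
anatomy:

- **Atlas**: centroids uniform in an ellipsoid with semi-axes
  (0.28, 0.175, 0.123) mm — the real template-brain extent, with neuropil
  centroids spanning roughly half a millimeter — mirrored across x = 0 into
  37 bilateral pairs plus one midline region (N = 75).  The pairwise-distance
  histogram is unimodal with an interior mode, the truncated-Gaussian-like
  shape of the real atlas.
- **Skeletons**: soma on the ellipsoid surface, a primary neurite to an
  interior branch point, a straight dendritic trunk and a bent axonal trunk
  carrying the closest post-/pre-synaptic points, star arbors of 3–20
  synaptic points beyond each.  The main-cable length is drawn from
  Exp(λ_true); trunk geometry is solved so the realized Euclidean cable
  length equals cable/a·(1 + ε) with |ε| ≤ 5% (default 2%).
- **Projectomes**: the EDR generator at λ_true, optionally with directional
  bias exp(±β·Δh/2) multiplying the two raw weights of each non-homotopic
  reciprocal pair, flow toward the higher hierarchy score h up-weighted, then
  re-normalized.  Hierarchy scores should be hemisphere-symmetric (partners
  share their base score): hierarchy is a property of the functional region,
  and asymmetric scores would leak bias into homotopic pairs through the
  column sums.  β ≈ 24 produces data-like asymmetry distributions from which
  the out-strength ranking recovers the inverse hierarchy at Spearman ≈ 0.9.

What the generator does **not** emulate: realistic morphology (no branching
statistics, no polyadic synapses), neuron-level connectivity (the synthetic
synapse tables have no partner identity, so the five-synapse connection
threshold is exercised on separate connection tables), measurement noise in
synapse placement, and any true developmental mechanism of weight asymmetry —
the multiplicative bias is a testing device.  Passing tests therefore show
the pipeline's statistics and estimators are correct and self-consistent, not
that the biological conclusions transfer.

## Numerical choices and edge cases

- All lengths in mm internally; SWC and atlas files use µm (factor 1000).
- Zero columns stay zero under normalization (logged); zero-distance region
  pairs are excluded from the distance histogram (logged).
- Degenerate histogram fits (fewer than two usable bins) and all-equal length
  samples raise instead of returning nonsense.
- `sample_distance`/`generate` draw in vectorized chunks; a chunk that
  overshoots M is truncated at the exact draw where the M-th distinct link
  appears, so results are identical to one-at-a-time sampling.
- Hemisphere assignment of a 3D point uses the sign of x with a configurable
  midline half-width (default 0.01 mm) defining "center".

## Known limitations and honest disagreements

- At the full 85% density, homotopic pairs' distance profile gives them
  systematically different multi-edge counts and hence *lower* intrinsic ASYM
  than other pairs even without injected bias; the no-bias equivalence of the
  homotopic class is therefore a moderate-density property (tested at
  M = 1000, 18% density).
- Model modules are spatially localized, so homotopic partners — sitting in
  opposite hemispheres — co-cluster *less* often than average in ensemble
  contingency matrices.  Bilaterally symmetric clusters in real data reflect
  genuinely symmetric connectivity, which a per-network geometric null does
  not produce; the co-clustering test asserts spatial localization (near
  pairs ≫ far pairs), not bilateral symmetry.
- Greedy backbone extraction is exact for the greedy rule but not globally
  minimal: bridges locked early can keep the density above the target.
- Clique *counts* at large sizes on dense graphs are combinatorially huge;
  the package exposes exact counts for requested sizes and maximum-clique
  summaries, and leaves full clique-size distributions to small sizes.
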