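# edrnet

Exponential-distance-rule (EDR) null models for region-level connectomes,
built around the *Drosophila* neuropil network (projectome).

## The problem

Across species, the probability that a neuron projects over a cable length
*d* decays exponentially,

    p(d) = c · exp(−λ d),

with a decay rate λ set by brain size.  Feeding only this rule, the Euclidean
distance matrix *D* between brain regions, and the observed number of
region-to-region connections *M* into a one-parameter maximum-entropy random
network generator yields a geometric null model.  Properties of the real
region-level network that the null reproduces are attributable to geometry;
properties it cannot reproduce — most prominently the strong asymmetry of
reciprocal connection weights, which tracks the functional hierarchy of
regions — are candidates for functional explanation.

`edrnet` implements the full analysis pipeline for the fly projectome and, in
place of the proprietary-scale electron-microscopy inputs, ships a
first-class synthetic-data generator with known ground truth:

- **skeleton morphometry** — main-cable length (tree path between the closest
  postsynaptic and closest presynaptic point), Euclidean cable length, the
  arbor-consistency filter (0.15 mm), and the log-histogram fit of λ;
- **projectome construction** — per-neuron synapse-fraction outer products
  summed over intrinsic neurons, column-normalized so that w<sub>ij</sub> is
  the probability of information flowing from region *i* to region *j*;
- **the EDR/CDR generator** — multi-edges placed by distance bins drawn with
  probability ∝ exp(−λ·bin center) until exactly *M* distinct directed links
  exist (λ = 0 is the constant-distance-rule baseline);
- **network comparison** — sorted degree spectra, uni/bidirectional counts,
  average binary path length, clustering coefficient, the 16-class triad
  census, clique counts, link lengths l<sub>ij</sub> = −log w<sub>ij</sub>,
  weighted node distances, global/local communication efficiency under
  ordered link removal, strong/weak backbones, and RMSD-vs-λ curves;
- **asymmetry analysis** — ASYM<sub>ij</sub> = |w<sub>ij</sub> − w<sub>ji</sub>| /
  (w<sub>ij</sub> + w<sub>ji</sub>), pair classes (homotopic / ipsilateral /
  contralateral), the directed asymmetry network and its in/out-strength
  hierarchy ranking;
- **clustering** — Ward/average/complete hierarchical clustering of
  incoming-flow (link-length column) profiles and ensemble co-clustering
  contingency matrices.

## Worked example

Measure the decay rate from a synthetic cohort with known λ = 33 mm⁻¹ and
tortuosity a = 1.5, then scan the EDR model's λ grid against an
EDR-generated data network:

```python
from edrnet import AtlasSpec, SyntheticTruth, make_atlas, make_projectome, EDRModel
from edrnet.synthetic import make_skeletons
from edrnet.skeleton_metrics import measure_cohort, fit_edr, scaling_factor

atlas = make_atlas(AtlasSpec(n_pairs=37, n_central=1, seed=0))   # 75 regions
truth = SyntheticTruth(lambda_true_per_mm=33.0, tortuosity_a=1.5, seed=42)

skeletons, _ = make_skeletons(atlas, truth, 10_000)
records = measure_cohort(skeletons)
print(fit_edr(records["cable_mm"]).summary())
print(scaling_factor(records["cable_mm"].to_numpy(), records["euclid_mm"].to_numpy()))

data = make_projectome(atlas, truth, M=2000)
results = EDRModel(data, atlas=atlas).fit(
    lambda_grid=(0, 10, 20, 25, 30, 35, 40, 45, 50, 60), n_networks=25, seed=1
)
print(results.summary())
```

This prints

```
Exponential distance rule fit: p(d) = c exp(-lambda d)
======================================================
sample: n=10000 min-cable lengths (mm)
lambda = 31.4 mm^-1   c = 30
lambda interval over bin sizes: [31.4, 34.2] mm^-1
...
scaling factor a = 1.500, Pearson r = 1.000

EDR model fit (RMSD-vs-lambda grid scan)
================================================
regions: 75   binary links M: 2000
networks per lambda: 25
...
optimal lambda (pooled RMSD argmin): 35 mm^-1
per-property argmin:
      degree_spectra: 25 mm^-1
       log10_weights: 35 mm^-1
      node_distances: 35 mm^-1
```

The histogram fit recovers the generating decay rate inside its bin-size
interval ([31.4, 34.2] mm⁻¹ around the true 33), the through-origin
regression of cable on Euclidean length returns the tortuosity exactly
(a = 1.5), and the RMSD scan's pooled argmin lands at 35 mm⁻¹ — the grid
point nearest the generating rate.

A command-line interface wraps the same stages:

```sh
edrnet simulate --n-pairs 37 --n-central 1 --n-neurons 1000 --m 2000 --seed 0 --out run/
edrnet measure  --swc-dir run/ --out run/metrics/
edrnet build    --synapses run/synapses.tsv --classes run/classes.tsv \
                --atlas run/atlas.csv --out run/proj/
edrnet compare  --network run/proj/projectome_w.csv \
                --distances run/proj/distances_mm.csv --out run/cmp/
edrnet asym     --network run/proj/projectome_w.csv --out run/asym/
edrnet cluster  --network run/proj/projectome_w.csv --k 4 --out run/clu/
```

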