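# jaggr

Orientational-order and aggregation analysis of rod-like dye molecules in
periodic molecular configurations, built for the question of how lipid
bilayers template dye J-aggregation — for example indocyanine green (ICG),
whose J-aggregate (absorbing at 892 nm) forms readily in rigid,
gel-phase liposomes but not in fluid ones.

It is aimed at people analysing MD simulations (or surrogate
configurations) of a handful of dye molecules at or in a bilayer, who want
the standard battery of geometric aggregation diagnostics plus the
formulation arithmetic used to characterize the resulting liposomal
preparations in the lab.

## What it computes

**Distance-resolved pairwise orientational order.** For every molecule
pair at center-of-mass separation *r* (minimum image, orthorhombic box),

    O(r) = ⟨ P₂(cos θᵢⱼ) ⟩ = ⟨ (3 cos² θᵢⱼ − 1) / 2 ⟩,

where θᵢⱼ is the angle between the molecules' longest principal axes
(largest-variance eigenvector of the mass-weighted gyration tensor).
O = 1 for parallel or anti-parallel pairs, 0 for mutually random
orientation, −0.5 for perpendicular pairs. The average pools all pair
observations across frames.

**Close-pair angle distributions** (oriented 0–180° when a head→tail atom
convention is available) for pairs within a chosen separation, the
**center-of-mass radial distribution function** g(r) with ideal-gas
normalization, and a first-neighbor cutoff estimator from the first
minimum of g(r).

**Single-linkage cluster analysis**: molecules closer than a cutoff
(default 17 Å, covering first and second neighbor shells) are linked;
connected components with ≥ 2 members are clusters. Reported: per-frame
membership percentage, its time average, and the cluster-size histogram.

**J/H classification.** A close pair is a J-aggregate ("slipped" stack)
when its stacking angle — between the mean molecular axis and the
inter-center direction — is below the magic angle 54.7° (the zero of
P₂(cos θ)), and an H-aggregate ("card-pack") for 54.7°–90°. Detected
clusters are labelled J, H or mixed from their linked pairs.

**Formulation metrics**: the J-aggregate/monomer absorbance ratio
A₈₉₂/A₇₉₂ from a spectrum table, and encapsulation efficiencies
(dye: 100 × encapsulated/initial concentration; doxorubicin:
100 × fluorescence after/before purification).

**Synthetic generator.** Because every stage needs ground truth, the
package generates rigid-rod ensembles with a prescribed nematic order S
about a director (axis law: mixture S·δ(director) + (1−S)·isotropic, so
⟨P₂(a·n)⟩ = S exactly and independent pairs give ⟨P₂(aᵢ·aⱼ)⟩ = S²),
optional slab confinement standing in for a bilayer surface, and planted
clusters whose single-linkage decomposition at a chosen cutoff is known
exactly.

## Worked example

Generate a rigid-bilayer-like surrogate (15 rods, high nematic order
S = 0.9, a planted 5-cluster and a planted dimer, 8 isolated molecules,
25 independent frames) and run the full pipeline:

```python
from jaggr import GeneratorSpec, RunConfig, generate_clustered, run_pipeline
from jaggr.io import write_configuration_csv

spec = GeneratorSpec(n_molecules=15, order_target=0.9,
                     planted_clusters=((5, 12.0), (2, 9.0)), n_isolated=8,
                     box=(300, 300, 300), frames=25, seed=42)
traj, truth = generate_clustered(spec, cutoff=17.0)
write_configuration_csv(traj, "dspc_like.csv")
summary = run_pipeline(RunConfig(input_csv="dspc_like.csv", seed=42,
                                 output_dir="out"))
```

The summary (also written to `out/summary.json`) contains:

```
"membership_percent_mean": 46.6666666667,
"max_cluster_size": 5,
"order_plateau_close_range": 0.7847425251,
"j_pair_fraction": 0.4218181818,
"cluster_size_histogram": {"2": 25, "5": 25}
```

Reading: 7 of 15 molecules sit in clusters in every frame (46.7%); the
largest cluster has 5 members; the pooled order parameter for pairs
closer than 10 Å is 0.78 (strong mutual alignment — ensembles with
O(r < 10 Å) above 0.5 are the signature of a J-aggregation-prone,
rigid-bilayer-like system, versus ≈ 0 for an isotropic control); and 42%
of linked close pairs have J-type (slipped) stacking geometry. Stage
tables (`order_profile.csv`, `angle_distribution.csv`, `rdf.csv`,
`membership.csv`, `cluster_sizes.csv`, `cluster_classification.csv`) sit
alongside the summary.

The same pipeline runs from the shell:

```bash
jaggr generate --n 10 --clusters 2:10,2:10,2:10 --isolated 4 \
      --box 250 250 250 --seed 3 --out gen.csv
jaggr clusters --input gen.csv --cutoff 17 --out clusters.json
# -> "membership_percent_mean": 60.0
jaggr run-all --config run.yaml
```

MD output is ingested directly: `read_trajectory("system.gro",
"production.xtc", selection="resname ICG", expected_count=15)` selects the
dye molecules and converts units as needed.

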