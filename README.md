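# allopath

Ensemble analysis of multi-segment protein complexes: conformational
statistics, interface interactions, end-state binding energetics, and
correlation-network allostery — for trajectories stored as multi-model PDB
files, with a synthetic elastic-network generator that provides exact
ground truth for every stage.

## Who this is for

Structural/computational biologists studying long-range allosteric
communication in protein complexes — the motivating system is the ternary
assembly of a catalytic K-Ras4B, the SOS catalytic core, and a second
Ras–GTP bound at SOS's distal allosteric site, where activator binding
far from the catalytic site strengthens the catalytic Ras–SOS interface
and reshapes the communication pathways between them.

## What it computes

Given an ensemble of frames over a fixed topology (three segments:
catalytic Ras-like, SOS-like, allosteric Ras-like):

- **Conformation** — Kabsch superposition, per-frame/region RMSD,
  per-residue RMSF, residue-pair Cα distance distributions.
- **Essential dynamics** — PCA of the Cα covariance matrix, PC1–PC2
  conformational landscapes, k-means clustering with
  nearest-to-centroid representative structures.
- **Interface** — geometric hydrogen-bond and salt-bridge detection
  across a segment–segment interface with per-frame occupancies.
- **Energetics** — single-trajectory end-state binding energies,

      ΔG_binding = ΔE_MM + ΔG_solv            (−TΔS omitted)
      ΔE_MM      = ΔE_vdW + ΔE_ele + ΔE_int
      ΔG_solv    = ΔE_polar + ΔE_nonpolar,    ΔE_nonpolar = γ·SASA + b

  with a generalized-Born polar term (pairwise-descreening effective
  radii), Shrake–Rupley-style SASA, γ = 0.00542 kcal·mol⁻¹·Å⁻²,
  b = 0.92 kcal/mol, interior dielectric 4.0 — plus a per-residue
  decomposition whose columns sum exactly to the totals.
- **Allostery network** — dynamic cross-correlation matrix
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), a residue contact graph
  (edges: pairs within 4.5 Å in ≥ 75 % of frames) weighted by
  d_ij = −log|C_ij|, Girvan–Newman communities at maximal modularity,
  Floyd–Warshall optimal pathways, and exact bounded enumeration of
  suboptimal pathways within a tolerance of the optimum.

The `synthetic_complex` module generates three-segment bead complexes
whose frames are drawn from the exact Gaussian of an anisotropic elastic
network (Σ = kT·H⁺, rigid-body modes projected out), with planted
community structure and a planted allosteric pathway — so covariances,
correlations, spectra, partitions and pathways all have known answers.

## Worked example

```python
from allopath.synthetic_complex import SyntheticSpec, build_bead_complex, plant_pathway, sample_ensemble
from allopath.allostery_network import build_graph, compute_dccm, detect_communities, optimal_path
from allopath.conformation import rmsd_series

spec = SyntheticSpec(n_frames=2000, seed=42)
spec, chain = plant_pathway(spec, source=70, sink=5)
topology, reference, communities = build_bead_complex(spec)
ensemble, truth = sample_ensemble(topology, reference, spec, communities)

rmsd = rmsd_series(ensemble)
print(f"mean RMSD: {rmsd.mean:.2f} +/- {rmsd.sd:.2f} A")

graph = build_graph(ensemble, compute_dccm(ensemble))
partition = detect_communities(graph)
print(f"communities: {partition.n_communities} (modularity {partition.modularity:.3f})")

report = optimal_path(graph, 70, 5)
print(f"optimal pathway: {report.n_residues} residues, length {report.optimal_length:.2f}")
print(f"matches planted chain: {report.optimal_path == truth.path}")
```

prints

```
mean RMSD: 1.73 +/- 0.37 A
communities: 14 (modularity 0.786)
optimal pathway: 26 residues, length 9.65
matches planted chain: True
```

The mean RMSD is the average Cα deviation from the first frame after
superposition; the community partition groups residues that move as
units (the compact blocks of the synthetic complex, here split finer
than the 8 planted blocks by the modularity maximum); the optimal
pathway is the chain of contacts with the smallest total −log|C|
distance from the allosteric-site residue 70 to the catalytic-site
residue 5, and it recovers the planted chain exactly.

## Command line

```sh
allopath init-config cfg.yaml          # binary-vs-ternary synthetic template
allopath run-all --config cfg.yaml     # full comparative analysis
allopath verify-paper                  # published-table consistency check
```

`run-all` writes per-system CSVs (RMSD, RMSF, PCA, clusters, distances,
interface occupancies, energy tables, DCCM, network edges, communities,
pathways) plus GraphML/DOT graph exports and a comparative summary; every
CSV is stamped with the config hash and seed, and reruns at the same seed
are byte-identical.  `verify-paper` recomputes the derived rows of the
published Ras–SOS binding-energy table from its printed components and
reports the sign inconsistency in the binary column's polar term.

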