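# Methods

## Scope and data model

`allopath` analyzes conformational ensembles of multi-segment protein
complexes. An ensemble is an ordered set of frames (F × N × 3 Cartesian
coordinates, Å) over a fixed atom list with per-atom labels and nonbonded
parameters (partial charge, LJ ε and r_min/2, segment). Trajectories are
read and written as standard multi-model PDB; since PDB carries no
charges, a plain-text CSV sidecar supplies them. Residue numbering is
1-based and preserved from the input; energy operations refuse to run on
unparameterized topologies rather than silently using zeros.

The motivating biology is allosteric activation of the Ras–SOS nucleotide
exchange machine: a Ras–GTP molecule bound at the distal allosteric site
of the SOS catalytic core strengthens the catalytic Ras–SOS interface and
re-routes the communication pathways between the two sites. The package's
comparative pipeline therefore analyzes a weakly coupled ("binary") and a
strongly coupled ("ternary") system side by side.

## Synthetic complexes with planted truth

Real trajectories of this system are not redistributable, so the test
substrate is a synthetic three-segment bead complex (one bead per
residue) with exact, closed-form ground truth.

**Geometry.** Residues are grouped into compact cubic blocks (lattice
constant 3.8 Å, one bead per site); blocks are laid along a diagonal
staircase so consecutive blocks touch through exactly one bead pair at
3.8 Å. Segment boundaries coincide with block bridges, giving a
catalytic/SOS and a SOS/allosteric interface and no direct contact
between the two Ras-like segments. Defaults: segments of 24/32/24
residues in 3/2/3 blocks — eight planted communities.

**Ensemble.** An anisotropic elastic network is built on the reference
geometry: unit springs (1 kcal·mol⁻¹·Å⁻²) between all bead pairs within
7.5 Å, plus a weak all-pairs background spring (1 % of the main constant)
that keeps the network mechanically rigid across the single-contact
bridges — without it the Hessian has floppy hinge modes beyond the six
rigid-body ones and the Gaussian is ill-defined. Frames are drawn from
the exact multivariate normal with covariance Σ = kT·H⁺ (kT = 0.593
kcal/mol, i.e. 300 K), with the six rigid-body modes projected out, so
every frame is exactly orthogonal to net translation/rotation. Sampling
from the distribution directly (rather than integrating dynamics) is a
deliberate choice: RMSF, covariances, correlations and PCA spectra then
have closed forms in Σ, making the generator a strong oracle. 5,000
frames converge sample covariances to Σ within a few percent.

**Planted pathway.** `plant_pathway` finds the hop-minimal chain between
a source and sink residue in the 4.5 Å reference contact graph and
stiffens *all pairs along the chain* (a clique) by `coupling_scale`
(default 25×). A single stiffened bond constrains only the bond
direction and barely moves the correlation; the clique makes the chain
move quasi-rigidly, driving its pairwise correlations toward 1 so every
chain edge carries a small −log|C| distance. Under the exact Σ-derived
weights the chain is verified (by exhaustive path enumeration in the
tests) to be the unique optimal route.

**What the generator does not emulate.** No realistic force field or
solvent, no anharmonicity, no conformational transitions between basins
(frames are unimodal Gaussian unless explicitly mixed), no real Ras/SOS
geometry beyond the three-segment topology. Passing tests therefore
demonstrate correctness of the *estimators and algorithms* under known
statistics, not fidelity of any physical prediction for the real system.

## Conformational statistics

Superposition is the Kabsch least-squares rigid-body fit (SVD with
reflection correction; degenerate/collinear selections are rejected).
RMSD series fit each frame to frame 0 ("the initial structure") over a
fit mask and report over a possibly different mask, so region RMSDs
after a global fit are one call. Fluctuation statistics (RMSF, PCA,
DCCM) instead superpose onto the iteratively refined ensemble mean:
fitting to a single noisy frame leaks that frame's displacement into
every fit and measurably biases correlations (~0.12 worst-case DCCM
error vs ~0.03 with fit-to-mean at 5,000 frames). The mean-fit iterates
to convergence (tolerance 1e-9 Å, cap 50 iterations) and the result is
rotated to a canonical principal-axes orientation so downstream numbers
do not depend on frame order.

Pair-distance distributions use 0.1 Å bins by default — fine enough to
resolve sub-Å shifts between ensembles — and report mean and modal
distance; the histogram is a probability mass summing to 1.

## Essential dynamics

PCA diagonalizes the Cα positional covariance (unbiased 1/(F−1)
normalization) of the mean-superposed ensemble; eigenvalues are clipped
at zero beyond the ensemble rank. Landscapes are per-frame (PC1, PC2)
scores with a normalized 2D histogram. Clustering is seeded multi-start
k-means (10 restarts) in the PC1–PC2 plane with K supplied by config
(default 2); the representative of a cluster is the sampled frame
nearest its centroid, never a coordinate average (averages can be
unphysical). The pipeline pools all frames of a system; per-replicate
analysis is a matter of running the pipeline per input.

## Interface interactions

PDB-style bead models carry no hydrogens, so the default hydrogen-bond
criterion is the distance-only proxy (donor–acceptor ≤ 3.5 Å), flagged
per record; when hydrogen positions are supplied the full criterion
(distance ≤ 3.5 Å and donor–H–acceptor angle ≥ 120°) applies, and a
strict mode errors instead of falling back. Salt bridges are
opposite-charge groups (|q| ≥ 0.3 e) with minimum heavy-atom distance
≤ 4.0 Å. These cutoffs are package conventions, configurable in one
place. Occupancy is the fraction of frames a criterion holds;
"interface counts" are the distinct interactions present in a designated
representative frame (by default the first cluster representative,
mirroring the practice of tabulating interface contacts on cluster
representatives). Only cross-segment pairs are considered.

## Binding energetics

Single-trajectory end-state protocol: complex, receptor and ligand
conformations are taken from the same frame, so the internal term
vanishes identically and the gas-phase components reduce to cross-group
sums. No distance cutoffs anywhere — group sizes at this scale make
exact O(N²) sums cheap and brute-force checkable.

- **Electrostatics:** Coulomb sum with k_e = 332.0637 kcal·Å·mol⁻¹·e⁻²
  and interior dielectric 4.0 (default; the screened-interface
  convention). vdW is the 12-6 form with ε_ij = √(ε_i ε_j) and
  r_min,ij = r_min,i/2 + r_min,j/2.
- **Polar solvation:** generalized-Born model,
  E = −k_e/2 (1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB with
  f_GB = √(r² + R_i R_j e^(−r²/4R_iR_j)) and effective radii from the
  (unscaled) pairwise-descreening integral; a lone atom recovers the
  Born formula exactly. Exterior dielectric 80.0 (water). Atomic radii
  are the LJ r_min/2 values. Outputs label this term "GB (polar)": it
  occupies the polar-solvation slot that a finite-difference
  Poisson–Boltzmann solver would fill in production force-field work,
  with the same physical role and closed-form testability.
- **Nonpolar solvation:** E = γ·SASA + b per species with γ = 0.00542
  kcal·mol⁻¹·Å⁻², b = 0.92 kcal/mol, probe 1.4 Å; SASA is deterministic
  sphere-point sampling (960 Fibonacci points/atom, < 1 % error on a
  sphere). Because the intercept is per species, the complex − receptor
  − ligand difference retains exactly −b; at infinite separation every
  other component vanishes and ΔE_nonpolar → −b. The per-residue
  decomposition surfaces this as an explicit `(const)` row so column
  sums reproduce totals to machine precision.
- **Decomposition:** cross-group pair energies are split half/half
  between the partner residues; polar and nonpolar terms are assigned
  per atom (GB shares −k_e/2·τ·q_i Σ_j q_j/f_ij; per-atom ΔSASA) and
  summed per residue.
- **Entropy:** the conformational −TΔS term is omitted and marked
  "omitted" in every output, the standard economy when comparing
  closely related complexes.
- **Frame stride:** energy evaluation subsamples frames (pipeline
  default every 25th), the usual end-state practice; means and SDs are
  over evaluated frames.

The bookkeeping identities (ΔE_MM = ΔE_vdW + ΔE_ele + ΔE_int,
ΔG_solv = ΔE_polar + ΔE_nonpolar, ΔG_binding = ΔE_MM + ΔG_solv) hold
exactly per frame by construction and to 1e-6 on the means.

`verify_table2_consistency` treats a *published* component table as
input and recomputes the derived rows through the same identities. For
the packaged Ras–SOS values the ternary column is internally consistent
to printed precision, while the binary column's polar term (−163.28) is
compatible with the printed binding energy only with the opposite sign
(+163.28); the checker reports this, it never repairs data.

## Allostery network

DCCM entries are normalized displacement covariances of Cα beads about
the ensemble mean, after mean-superposition; zero-variance residues are
an error (the normalization is undefined), and the matrix is symmetrized
and clipped to [−1, 1] against float drift.

The contact network has one node per residue and an edge wherever the
minimum inter-residue atom distance stays within 4.5 Å in at least 75 %
of frames (threshold inclusive); edges are weighted d_ij = −log|C_ij|
in natural log (base-10 selectable; the metadata records the choice).
Edges with C_ij = 0 would be infinitely distant and are dropped. A
display-only convention of masking |C| < 0.3 in correlation *plots*
never feeds the graph.

**Communities:** Girvan–Newman — iteratively remove the edge of highest
distance-weighted betweenness, tracking partitions as components split,
and return the partition of maximal unweighted modularity on the
original graph (the initial components partition included, so K₅ stays
one community). Determinism: betweenness values are rounded to 9
decimals and ties break to the lexicographically smallest node pair;
modularity is rational with denominator (2m)², so a strict-improvement
threshold of 1e-12 resolves exact ties to the coarser partition. Note
that Girvan–Newman maximizes modularity only over its own dendrogram,
not over all partitions; the tests therefore check exact agreement with
an independently written naive implementation (brute-force betweenness
by simple-path enumeration, direct modularity sums) on random graphs,
and global-optimum agreement on structured cases (two cliques and a
bridge) where the dendrogram provably contains the optimum. On the
synthetic complexes the modularity maximum typically splits the eight
planted blocks a little finer (~14 communities) while agreeing with the
planted partition at adjusted Rand ≈ 0.95.

**Pathways:** all-pairs shortest paths by Floyd–Warshall with
predecessor reconstruction; a disconnected pair yields an explicit
no-path report. Suboptimal pathways are *all* simple paths within a
tolerance of the optimal length, enumerated by depth-first search pruned
with the exact remaining distance to the sink and capped at a configured
expansion budget (default 10⁶; hitting the cap flags the count as a
lower bound). The tolerance is unitless (edge distances are
−log-correlations); the function default of 20 follows the convention of
reporting suboptimal paths "within 20" of the optimum at face value, and
the synthetic pipeline config uses 1.0, which keeps enumeration exact at
these graph sizes.

**Intercommunity strength** sums distance-weighted edge betweenness (or,
configurably, edge counts) over community-crossing edges — the quantity
behind the stick widths of community-network diagrams.

## Pipeline and reproducibility

A single YAML config defines the systems (synthetic specs or PDB +
sidecar paths), named residue regions, and per-stage parameters. Stages
run in order (superposition → RMSD/RMSF → PCA/clusters → distances →
interface → energetics → DCCM/network/communities/pathways); a stage
failure aborts with the stage name and leaves a `FAILED` marker beside
the partial outputs. Every CSV begins with a comment line carrying the
config hash (SHA-256 of the analysis-defining fields; output location
excluded) and the global seed. Per-stage seeds derive deterministically
as SHA-256 of `"<seed>:<label>"` mod 2³¹. Fixed-format floats make
reruns at the same seed byte-identical.

The default comparative config plants the same allosteric pathway in
both systems and couples it at scale 5 ("binary") vs 25 ("ternary"):
stronger coupling rigidifies the chain, raising contact occupancies and
correlations along it, so the ternary system shows shorter optimal path
lengths and a tighter interface — the qualitative signature of
activator-enhanced allosteric communication. Default problem sizes (80
residues, 1,500 frames in the template config; 5,000 frames for the
planted-recovery checks; energy stride 25) are chosen so sample
statistics sit well inside their convergence bands while a full
comparative run completes in seconds on one core.

Plotting is intentionally out of scope; all outputs are CSV, GraphML,
DOT or PDB.

## Known limitations

- The GB polar term is a surrogate in the PB slot: absolute polar
  energies will differ from a grid PB solver; bookkeeping and
  decomposition are unaffected.
- The HCT descreening radii are unscaled (no per-element scaling
  factors), adequate for bead models; all-atom accuracy would want the
  scaled variant.
- Suboptimal-path counts are exact only below the expansion cap; dense
  graphs at large tolerance return flagged lower bounds.
- Multi-replicate trajectories are handled by pooling frames; per-replicate
  occupancy thresholds are a separate run, not a config flag.
- The multi-model PDB reader supports the ATOM/HETATM/MODEL/ENDMDL
  subset it writes; exotic records (insertion codes, altlocs) are out of
  scope.
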