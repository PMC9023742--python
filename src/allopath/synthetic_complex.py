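"""Synthetic three-segment bead complexes with planted ground truth.

The generator emulates the statistical structure of an MD ensemble of a
ternary GTPase–exchange-factor complex: a catalytic Ras-like segment, a
SOS-like segment and an allosteric Ras-like segment, arranged in a chain of
compact residue *blocks* (the planted communities) joined by single-contact
bridges, with the two inter-segment bridges playing the role of the
catalytic and allosteric interfaces.

Frames are drawn from the exact multivariate Gaussian of an anisotropic
elastic network built on the reference geometry: the 3N×3N Hessian ``H`` of
Hookean springs between all bead pairs within ``contact_cutoff_build`` is
pseudo-inverted on its non-rigid-body modes and the planted covariance is

    Σ = kT · H⁺           (six rigid-body modes carry zero variance).

Gaussian sampling (rather than integrating dynamics) is what makes the
generator a strong oracle: every downstream expectation — RMSF, covariance,
cross-correlations, PCA spectra, network edge weights — has a closed form
in Σ, recorded in :class:`PlantedTruth`.

A planted allosteric pathway is a residue chain whose springs are stiffened
by ``coupling_scale``; motion along the chain becomes highly correlated, so
the chain carries low ``−log|C|`` edge distances and becomes the optimal
source→sink communication route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from allopath.structure_io import EnsembleFrameSet, Topology

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "build_bead_complex",
    "sample_ensemble",
    "plant_pathway",
    "dccm_from_covariance",
    "inject_rigid_motions",
]

#: one bead per residue, roughly a Cα–Cα virtual bond length
BEAD_SPACING = 3.8


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic complex and its ensemble.

    Defaults are the package's standard study conditions: three segments
    with a total of eight residue blocks (communities), springs of
    1 kcal·mol⁻¹·Å⁻² between beads within 7.5 Å, kT at 300 K, and 5,000
    frames — large enough that sample covariances converge to Σ within a
    few percent.
    """

    residues_per_segment: tuple[int, int, int] = (24, 32, 24)
    blocks_per_segment: tuple[int, int, int] = (3, 2, 3)
    segment_names: tuple[str, str, str] = ("RASC", "SOS", "RASA")
    contact_cutoff_build: float = 7.5  # Å, elastic-network spring cutoff
    spring_constant: float = 1.0  # kcal/mol/Å^2
    coupling_edges: tuple[tuple[int, int], ...] = ()
    coupling_scale: float = 25.0
    #: weak all-pairs spring (fraction of spring_constant) that keeps the
    #: network rigid across single-contact block bridges
    background_spring_fraction: float = 0.01
    kT: float = 0.593  # kcal/mol (300 K)
    n_frames: int = 5000
    seed: int = 0
    # bead parameter rule: alternating +/- charge, uniform LJ
    bead_charge: float = 0.5  # e, sign alternates with atom index
    bead_epsilon: float = 0.1  # kcal/mol
    bead_rmin_half: float = 2.0  # Å
    bead_mass: float = 110.0  # amu
    pathway_chain: tuple[int, ...] | None = None  # set by plant_pathway

    def __post_init__(self) -> None:
        if len(self.residues_per_segment) != 3:
            raise ValueError("exactly three segments required")
        if any(n < 2 for n in self.residues_per_segment):
            raise ValueError("each segment needs at least 2 residues")
        if len(self.blocks_per_segment) != 3 or any(b < 1 for b in self.blocks_per_segment):
            raise ValueError("blocks_per_segment must be three positive integers")
        if any(n < b for n, b in zip(self.residues_per_segment, self.blocks_per_segment)):
            raise ValueError("more blocks than residues in a segment")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def n_residues(self) -> int:
        return int(sum(self.residues_per_segment))


@dataclass
class PlantedTruth:
    """Exact ground truth of a sampled ensemble.

    ``covariance`` is the exact 3N×3N sampling covariance Σ (Å²);
    ``community_of`` maps residue index -> planted block id; ``path`` is the
    planted allosteric residue chain (None when no couplings are planted).
    """

    covariance: np.ndarray
    community_of: dict[int, int]
    path: list[int] | None
    seed: int

    def exact_dccm(self) -> np.ndarray:
        """Closed-form residue–residue cross-correlations implied by Σ."""
        return dccm_from_covariance(self.covariance)


def dccm_from_covariance(sigma: np.ndarray) -> np.ndarray:
    """C_ij = tr Σ_ij / sqrt(tr Σ_ii · tr Σ_jj) over 3×3 residue blocks."""
    n3 = sigma.shape[0]
    if n3 % 3:
        raise ValueError("covariance dimension must be a multiple of 3")
    n = n3 // 3
    blocks = sigma.reshape(n, 3, n, 3)
    inner = np.einsum("idjd->ij", blocks)
    var = np.diag(inner)
    if np.any(var <= 0):
        raise ValueError("zero-variance residue in covariance")
    return inner / np.sqrt(np.outer(var, var))


def _block_sizes(n_res: int, n_blocks: int) -> list[int]:
    base = n_res // n_blocks
    sizes = [base] * n_blocks
    for i in range(n_res - base * n_blocks):
        sizes[i] += 1
    return sizes


def _grid_positions(m: int, spacing: float) -> np.ndarray:
    """First m sites of a compact cubic lattice, raster order, x fastest."""
    side = max(2, math.ceil(m ** (1.0 / 3.0)))
    sites = []
    for k in range(side):
        for j in range(side):
            for i in range(side):
                sites.append((i, j, k))
                if len(sites) == m:
                    return np.array(sites, dtype=float) * spacing
    return np.array(sites[:m], dtype=float) * spacing


def build_bead_complex(spec: SyntheticSpec) -> tuple[Topology, np.ndarray, dict[int, int]]:
    """Build the reference bead geometry of the three-segment complex.

    Returns ``(topology, reference_coords, community_of)`` where
    ``community_of`` maps residue index (1-based) -> planted block id.
    Blocks are compact cubic clusters placed on a diagonal staircase so
    that consecutive blocks touch through exactly one bead pair at
    :data:`BEAD_SPACING`; segment boundaries coincide with block bridges,
    giving a catalytic-segment/SOS interface and a SOS/allosteric-segment
    interface and no direct contact between the two Ras-like segments.
    """
    coords: list[np.ndarray] = []
    seg_of_block: list[int] = []
    sizes_all: list[int] = []
    for s in range(3):
        for size in _block_sizes(spec.residues_per_segment[s], spec.blocks_per_segment[s]):
            sizes_all.append(size)
            seg_of_block.append(s)

    origin = np.zeros(3)
    step = BEAD_SPACING / math.sqrt(3.0)
    community_of: dict[int, int] = {}
    res = 0
    for b, size in enumerate(sizes_all):
        block = _grid_positions(size, BEAD_SPACING) + origin
        coords.append(block)
        for _ in range(size):
            res += 1
            community_of[res] = b
        origin = block[-1] + step  # next block's first bead one spacing away

    ref = np.vstack(coords)
    n = ref.shape[0]

    # steric sanity: no two beads closer than 2 Å
    d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 2.0:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(f"steric overlap: beads {i + 1} and {j + 1} at {d.min():.2f} Å")

    seg_ids = []
    for s, n_s in enumerate(spec.residues_per_segment):
        seg_ids.extend([spec.segment_names[s]] * n_s)
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    topology = Topology(
        atom_names=np.array(["CA"] * n),
        res_indices=np.arange(1, n + 1),
        res_names=np.array(["BEA"] * n),
        segment_ids=np.array(seg_ids),
        masses=np.full(n, spec.bead_mass),
        charges=signs * spec.bead_charge,
        epsilons=np.full(n, spec.bead_epsilon),
        rmin_halves=np.full(n, spec.bead_rmin_half),
        parameterized=True,
    )
    return topology, ref, community_of


def _spring_list(spec: SyntheticSpec, reference: np.ndarray) -> list[tuple[int, int, float]]:
    """(i, j, k) springs: all pairs within the build cutoff, plus planted
    couplings at ``spring_constant * coupling_scale`` (0-based indices)."""
    n = reference.shape[0]
    d = np.linalg.norm(reference[:, None, :] - reference[None, :, :], axis=-1)
    coupled = {tuple(sorted((i - 1, j - 1))) for i, j in spec.coupling_edges}
    springs = []
    k_bg = spec.spring_constant * spec.background_spring_fraction
    for i in range(n):
        for j in range(i + 1, n):
            k = k_bg
            if d[i, j] <= spec.contact_cutoff_build:
                k = spec.spring_constant
            if (i, j) in coupled:
                k = spec.spring_constant * spec.coupling_scale
            if k > 0:
                springs.append((i, j, k))
    return springs


def _hessian(reference: np.ndarray, springs) -> np.ndarray:
    n = reference.shape[0]
    h = np.zeros((3 * n, 3 * n))
    for i, j, k in springs:
        e = reference[j] - reference[i]
        e = e / np.linalg.norm(e)
        kb = k * np.outer(e, e)
        h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += kb
        h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += kb
        h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= kb
        h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= kb
    return h


def sample_ensemble(
    topology: Topology,
    reference: np.ndarray,
    spec: SyntheticSpec,
    community_of: dict[int, int] | None = None,
) -> tuple[EnsembleFrameSet, PlantedTruth]:
    """Draw ``spec.n_frames`` frames from the elastic-network Gaussian.

    Frames come pre-superposed: the six rigid-body modes at the reference
    geometry are projected out of the Hessian spectrum, so each sampled
    displacement is exactly orthogonal to net translation and rotation.

    Raises
    ------
    ValueError
        If the spring network is disconnected (listing the components) or
        mechanically floppy (more than six near-zero modes).
    """
    n = reference.shape[0]
    if topology.n_atoms != n:
        raise ValueError("topology/reference size mismatch")
    springs = _spring_list(spec, reference)

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j, _ in springs)
    if not nx.is_connected(g):
        comps = [sorted(c)[:5] for c in nx.connected_components(g)]
        raise ValueError(f"elastic network disconnected; components start with {comps}")

    h = _hessian(reference, springs)
    w, v = np.linalg.eigh(h)
    tol = max(w.max(), 1.0) * 1e-9
    n_zero = int(np.sum(w < tol))
    if n_zero != 6:
        raise ValueError(
            f"expected 6 rigid-body zero modes, found {n_zero}; the network is "
            + ("floppy — increase contact_cutoff_build" if n_zero > 6 else "over-constrained")
        )
    w_int, v_int = w[6:], v[:, 6:]

    sigma = spec.kT * (v_int / w_int) @ v_int.T
    amp = v_int * np.sqrt(spec.kT / w_int)  # (3n, 3n-6)

    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, 3 * n - 6))
    disp = z @ amp.T
    frames = reference[None, :, :] + disp.reshape(spec.n_frames, n, 3)

    if community_of is None:
        community_of = {int(r): 0 for r in topology.residue_indices}
    path = list(spec.pathway_chain) if spec.pathway_chain else None
    truth = PlantedTruth(covariance=sigma, community_of=dict(community_of), path=path, seed=spec.seed)
    return EnsembleFrameSet(topology=topology, frames=frames), truth


def plant_pathway(spec: SyntheticSpec, source: int, sink: int) -> tuple[SyntheticSpec, list[int] | None]:
    """Plant an allosteric pathway between two residues.

    Computes the hop-minimal residue chain from ``source`` to ``sink`` in
    the reference-geometry contact graph (bead pairs within 4.5 Å) and
    returns a new spec whose ``coupling_edges`` stiffen every edge of that
    chain by ``coupling_scale``.  Under the planted covariance those edges
    carry near-unity correlations, so the chain is the optimal
    ``−log|C|`` path in the infinite-sampling limit.

    With ``coupling_scale <= 1`` no pathway is designed and ``(spec, None)``
    is returned.
    """
    if source == sink:
        raise ValueError("source and sink must differ")
    topology, ref, _ = build_bead_complex(spec)
    residues = set(int(r) for r in topology.residue_indices)
    if source not in residues or sink not in residues:
        raise ValueError(f"source/sink outside residue range 1..{len(residues)}")
    if spec.coupling_scale <= 1.0:
        return spec, None

    d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    g = nx.Graph()
    g.add_nodes_from(range(1, len(residues) + 1))
    ii, jj = np.nonzero(np.triu(d <= 4.5, k=1))
    g.add_edges_from(zip(ii + 1, jj + 1))
    try:
        chain = nx.shortest_path(g, source, sink)
    except nx.NetworkXNoPath as exc:
        raise ValueError(f"no contact-graph route between {source} and {sink}") from exc
    # Stiffen all pairs along the chain (not just consecutive ones): the
    # chain then moves as a quasi-rigid unit, so its members' displacements
    # become highly correlated and every chain edge carries a small
    # -log|C| distance.  A single stiffened bond would only constrain the
    # bond direction and barely move the correlation.
    edges = tuple(
        (int(chain[a]), int(chain[b]))
        for a in range(len(chain))
        for b in range(a + 1, len(chain))
    )
    chain = [int(r) for r in chain]
    return replace(spec, coupling_edges=edges, pathway_chain=tuple(chain)), chain


def inject_rigid_motions(
    ensemble: EnsembleFrameSet,
    seed: int = 0,
    max_rotation_deg: float = 180.0,
    max_translation: float = 20.0,
) -> EnsembleFrameSet:
    """Apply an independent random rigid motion to every frame.

    Used to exercise the superposition stage: statistics computed after
    Kabsch fitting must be unchanged by this transformation.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    frames = ensemble.frames.copy()
    for f in range(frames.shape[0]):
        rot = Rotation.from_rotvec(
            rng.uniform(-1, 1, 3) * np.deg2rad(max_rotation_deg)
        ).as_matrix()
        shift = rng.uniform(-max_translation, max_translation, 3)
        center = frames[f].mean(axis=0)
        frames[f] = (frames[f] - center) @ rot.T + center + shift
    return EnsembleFrameSet(topology=ensemble.topology, frames=frames, frame_times=ensemble.frame_times)
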