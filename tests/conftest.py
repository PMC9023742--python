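"""Shared fixtures: toy topologies and planted-covariance ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from allopath.structure_io import EnsembleFrameSet, Topology
from allopath.synthetic_complex import SyntheticSpec, build_bead_complex, plant_pathway, sample_ensemble


def make_topology(
    n_atoms: int,
    segments=None,
    charges=None,
    epsilons=None,
    rmin_halves=None,
    res_indices=None,
) -> Topology:
    """One-bead-per-residue topology with controllable parameters."""
    if segments is None:
        segments = ["A"] * n_atoms
    if res_indices is None:
        res_indices = np.arange(1, n_atoms + 1)
    return Topology(
        atom_names=np.array(["CA"] * n_atoms),
        res_indices=np.asarray(res_indices, int),
        res_names=np.array(["BEA"] * n_atoms),
        segment_ids=np.asarray(segments, dtype=object).astype(str),
        masses=np.full(n_atoms, 110.0),
        charges=np.zeros(n_atoms) if charges is None else np.asarray(charges, float),
        epsilons=np.full(n_atoms, 0.1) if epsilons is None else np.asarray(epsilons, float),
        rmin_halves=np.full(n_atoms, 2.0) if rmin_halves is None else np.asarray(rmin_halves, float),
        parameterized=True,
    )


def make_ensemble(frames: np.ndarray, topology: Topology | None = None, **kwargs) -> EnsembleFrameSet:
    frames = np.asarray(frames, float)
    if topology is None:
        topology = make_topology(frames.shape[1], **kwargs)
    return EnsembleFrameSet(topology=topology, frames=frames)


@pytest.fixture(scope="session")
def toy20():
    """20-bead three-segment complex, 5,000 frames from the exact planted Σ."""
    spec = SyntheticSpec(
        residues_per_segment=(6, 8, 6), blocks_per_segment=(1, 1, 1), n_frames=5000, seed=101
    )
    topology, reference, community_of = build_bead_complex(spec)
    ensemble, truth = sample_ensemble(topology, reference, spec, community_of)
    return {
        "spec": spec,
        "topology": topology,
        "reference": reference,
        "ensemble": ensemble,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def complex80():
    """80-bead complex with 8 planted communities and a planted pathway."""
    spec = SyntheticSpec(n_frames=5000, seed=202)
    topology, reference, community_of = build_bead_complex(spec)
    spec, chain = plant_pathway(spec, 70, 5)
    ensemble, truth = sample_ensemble(topology, reference, spec, community_of)
    return {
        "spec": spec,
        "topology": topology,
        "reference": reference,
        "ensemble": ensemble,
        "truth": truth,
        "chain": chain,
    }
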