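"""Multi-model PDB and topology-sidecar I/O.

The package consumes trajectories as standard multi-model PDB files (one
``MODEL``/``ENDMDL`` block per frame).  Because PDB carries no charges or
Lennard-Jones parameters, a plain-text *sidecar* (CSV, one row per atom, same
order as the coordinate file) supplies them together with segment labels:

    atom_name,res_index,res_name,segment,mass,charge,epsilon,rmin_half

``charge`` is in elementary-charge units, ``epsilon`` (LJ well depth) in
kcal/mol and ``rmin_half`` (half the LJ minimum-energy distance) in Å.
Without a sidecar, charges and LJ parameters default to zero and the
energetics operations refuse to run.

Residue numbering is 1-based and preserved exactly as found in the input;
internal arrays are 0-based with explicit maps on :class:`Topology`.

The reader/writer is deliberately self-contained: the error contract
(offending model index on atom-count mismatch, line numbers on unparsable
records, exact label preservation) is part of this module's interface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "EnsembleFrameSet",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_topology_sidecar",
    "write_topology_sidecar",
]

SIDECAR_COLUMNS = [
    "atom_name",
    "res_index",
    "res_name",
    "segment",
    "mass",
    "charge",
    "epsilon",
    "rmin_half",
]


@dataclass
class Topology:
    """Per-atom labels and nonbonded parameters for a fixed atom list.

    Parameters
    ----------
    atom_names, res_indices, res_names, segment_ids
        One entry per atom; ``res_indices`` are the (1-based) author residue
        numbers of the coordinate file.
    masses, charges, epsilons, rmin_halves
        amu, e, kcal/mol and Å respectively.
    parameterized
        True when charges/LJ came from a sidecar (energetics require this).
    """

    atom_names: np.ndarray
    res_indices: np.ndarray
    res_names: np.ndarray
    segment_ids: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    epsilons: np.ndarray
    rmin_halves: np.ndarray
    parameterized: bool = False

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for name in ("res_indices", "res_names", "segment_ids", "masses", "charges", "epsilons", "rmin_halves"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology field {name!r} length != atom count {n}")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("non-finite charge in topology")
        if np.any(self.epsilons < 0):
            raise ValueError("negative LJ epsilon in topology")
        if self.parameterized and np.any(self.rmin_halves <= 0):
            raise ValueError("non-positive rmin_half in parameterized topology")
        # residue indices strictly increasing within each segment
        for seg in self.segment_names:
            res = self.res_indices[self.segment_ids == seg]
            runs = res[np.concatenate(([True], np.diff(res) != 0))]
            if np.any(np.diff(runs) <= 0):
                raise ValueError(f"residue indices not strictly increasing in segment {seg!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def segment_names(self) -> list[str]:
        """Segment names in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.segment_ids:
            seen.setdefault(str(s), None)
        return list(seen)

    @property
    def segments(self) -> dict[str, np.ndarray]:
        """Map segment name -> sorted residue indices it contains."""
        return {
            seg: np.unique(self.res_indices[self.segment_ids == seg])
            for seg in self.segment_names
        }

    @property
    def residue_indices(self) -> np.ndarray:
        """All residue indices, in order of first appearance."""
        _, first = np.unique(self.res_indices, return_index=True)
        return self.res_indices[np.sort(first)]

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)

    @property
    def calpha_index(self) -> dict[int, int]:
        """Map residue index -> atom position of its Cα-equivalent bead.

        The Cα-equivalent atom is the one named ``CA``; every residue must
        have exactly one.
        """
        out: dict[int, int] = {}
        for pos, (name, res) in enumerate(zip(self.atom_names, self.res_indices)):
            if str(name).strip() == "CA":
                res = int(res)
                if res in out:
                    raise ValueError(f"residue {res} has more than one CA atom")
                out[res] = pos
        missing = set(int(r) for r in self.residue_indices) - set(out)
        if missing:
            raise ValueError(f"residues without a CA atom: {sorted(missing)}")
        return out

    def atom_indices_of_segment(self, segment: str) -> np.ndarray:
        idx = np.flatnonzero(self.segment_ids == segment)
        if idx.size == 0:
            raise KeyError(f"unknown segment {segment!r}")
        return idx

    def atom_indices_of_residues(self, residues) -> np.ndarray:
        mask = np.isin(self.res_indices, np.asarray(list(residues)))
        return np.flatnonzero(mask)


@dataclass
class EnsembleFrameSet:
    """Ordered coordinate frames (F, N, 3) in Å over a fixed :class:`Topology`."""

    topology: Topology
    frames: np.ndarray
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def calpha_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (residue indices, (F, n_res, 3) Cα coordinates)."""
        ca = self.topology.calpha_index
        residues = self.topology.residue_indices
        cols = np.array([ca[int(r)] for r in residues])
        return residues, self.frames[:, cols, :]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip()
        res_index = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        segid = line[72:76].strip() if len(line) >= 76 else ""
    except (ValueError, IndexError) as exc:
        raise ValueError(f"unparsable ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    return name, res_name, chain, res_index, (x, y, z), segid


def read_multimodel_pdb(path, topology_sidecar=None) -> EnsembleFrameSet:
    """Read a multi-model PDB file into an :class:`EnsembleFrameSet`.

    Frames are the ``MODEL``/``ENDMDL`` blocks in file order; a file with no
    ``MODEL`` records is treated as a single frame.  The segment label of an
    atom is the PDB segID field if present, else the chain ID; a sidecar
    (see module docstring) overrides labels and supplies charges/LJ.

    Raises
    ------
    ValueError
        If atom counts differ across models (naming the offending model) or
        an ATOM record cannot be parsed (naming the line number).
    """
    models: list[list] = []
    current: list | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                current = []
            elif rec.startswith("ENDMDL"):
                if current is not None:
                    models.append(current)
                current = None
            elif rec.startswith(("ATOM  ", "HETATM")):
                if current is None:
                    if saw_model:
                        raise ValueError(f"ATOM record outside MODEL block at line {lineno}")
                    current = []
                    models.append(current)
                current.append(_parse_atom_line(line, lineno))
    if current is not None and saw_model:
        models.append(current)  # unterminated final MODEL
    if not models or not models[0]:
        raise ValueError(f"no coordinates found in {path}")

    n0 = len(models[0])
    for m, atoms in enumerate(models, start=1):
        if len(atoms) != n0:
            raise ValueError(
                f"inconsistent atom count in model {m}: {len(atoms)} atoms, expected {n0}"
            )

    first = models[0]
    names = np.array([a[0] for a in first])
    res_names = np.array([a[1] for a in first])
    segs = np.array([(a[5] or a[2] or "A") for a in first])
    res_idx = np.array([a[3] for a in first], dtype=int)
    frames = np.array([[a[4] for a in atoms] for atoms in models], dtype=float)

    if topology_sidecar is not None:
        topology = read_topology_sidecar(topology_sidecar)
        if topology.n_atoms != n0:
            raise ValueError(
                f"sidecar atom count {topology.n_atoms} != PDB atom count {n0}"
            )
    else:
        n = n0
        topology = Topology(
            atom_names=names,
            res_indices=res_idx,
            res_names=res_names,
            segment_ids=segs,
            masses=np.zeros(n),
            charges=np.zeros(n),
            epsilons=np.zeros(n),
            rmin_halves=np.ones(n),
            parameterized=False,
        )
    return EnsembleFrameSet(topology=topology, frames=frames)


def write_multimodel_pdb(ensemble: EnsembleFrameSet, path) -> None:
    """Write an ensemble as a standard multi-model PDB file.

    Chain IDs are assigned A, B, C… per segment (in order of first
    appearance); the segment name is also written to the segID field
    (columns 73–76, truncated to 4 characters).
    """
    if np.any(np.abs(ensemble.frames) >= 1e4):
        raise ValueError("coordinate magnitude >= 10^4 Å cannot be represented in PDB fixed width")
    top = ensemble.topology
    chain_of = {seg: chr(ord("A") + i % 26) for i, seg in enumerate(top.segment_names)}
    buf = io.StringIO()
    for f in range(ensemble.n_frames):
        buf.write(f"MODEL     {f + 1:4d}\n")
        coords = ensemble.frames[f]
        for i in range(top.n_atoms):
            name = str(top.atom_names[i])
            # PDB convention: names of <4 chars start in column 14
            name_field = name if len(name) >= 4 else f" {name:<3s}"
            seg = str(top.segment_ids[i])
            x, y, z = coords[i]
            buf.write(
                f"ATOM  {(i + 1) % 100000:5d} {name_field:<4.4s} {str(top.res_names[i]):<3.3s} "
                f"{chain_of[seg]}{int(top.res_indices[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}      {seg:<4.4s}\n"
            )
        buf.write("ENDMDL\n")
    buf.write("END\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Sidecar
# ---------------------------------------------------------------------------

def write_topology_sidecar(topology: Topology, path) -> None:
    """Write the plain-text (CSV) per-atom parameter sidecar."""
    df = pd.DataFrame(
        {
            "atom_name": topology.atom_names,
            "res_index": topology.res_indices,
            "res_name": topology.res_names,
            "segment": topology.segment_ids,
            "mass": topology.masses,
            "charge": topology.charges,
            "epsilon": topology.epsilons,
            "rmin_half": topology.rmin_halves,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_topology_sidecar(path) -> Topology:
    """Read the sidecar written by :func:`write_topology_sidecar`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SIDECAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sidecar {path} missing columns {missing}")
    return Topology(
        atom_names=df["atom_name"].astype(str).to_numpy(),
        res_indices=df["res_index"].astype(int).to_numpy(),
        res_names=df["res_name"].astype(str).to_numpy(),
        segment_ids=df["segment"].astype(str).to_numpy(),
        masses=df["mass"].astype(float).to_numpy(),
        charges=df["charge"].astype(float).to_numpy(),
        epsilons=df["epsilon"].astype(float).to_numpy(),
        rmin_halves=df["rmin_half"].astype(float).to_numpy(),
        parameterized=True,
    )
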