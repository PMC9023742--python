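"""Superposition, RMSD, RMSF and residue-pair distance distributions.

All fits are least-squares rigid-body superpositions (Kabsch, via SVD) over
a selection mask; RMSD/RMSF follow the usual Cα conventions: RMSD against a
reference frame (frame 0 by default, "the initial structure"), RMSF about
the ensemble-mean structure after superposing every frame on all Cα atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from allopath.structure_io import EnsembleFrameSet, Topology

__all__ = [
    "SelectionMask",
    "DistanceSeries",
    "RMSDSeries",
    "calpha_mask",
    "mask_from_residues",
    "kabsch_superpose",
    "superpose_ensemble",
    "superpose_to_mean",
    "rmsd_series",
    "rmsf_per_residue",
    "pair_distance_distribution",
]


@dataclass(frozen=True)
class SelectionMask:
    """A named subset of atom positions (0-based indices into the frame)."""

    name: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=int)
        object.__setattr__(self, "atom_indices", idx)
        if idx.size == 0:
            raise ValueError(f"selection mask {self.name!r} is empty")
        if len(np.unique(idx)) != idx.size:
            raise ValueError(f"selection mask {self.name!r} has duplicate atoms")

    @property
    def size(self) -> int:
        return self.atom_indices.size


def calpha_mask(topology: Topology, name: str = "calpha") -> SelectionMask:
    """All Cα-equivalent atoms, in residue order."""
    ca = topology.calpha_index
    return SelectionMask(name, np.array([ca[int(r)] for r in topology.residue_indices]))


def mask_from_residues(topology: Topology, residues, name: str, calpha_only: bool = True) -> SelectionMask:
    """Mask of the given residue indices (Cα atoms only by default)."""
    residues = [int(r) for r in residues]
    missing = set(residues) - set(int(r) for r in topology.residue_indices)
    if missing:
        raise KeyError(f"residues not in topology: {sorted(missing)}")
    if calpha_only:
        ca = topology.calpha_index
        return SelectionMask(name, np.array([ca[r] for r in residues]))
    return SelectionMask(name, topology.atom_indices_of_residues(residues))


@dataclass
class RMSDSeries:
    """Per-frame RMSD (Å) with its mean and standard deviation."""

    values: np.ndarray
    mean: float
    sd: float
    fit_mask: str
    report_mask: str
    reference_frame: int


@dataclass
class DistanceSeries:
    """Per-frame Cα–Cα distance (Å) for one residue pair, with histogram."""

    pair: tuple[int, int]
    distances: np.ndarray
    bin_edges: np.ndarray
    probability: np.ndarray  # sums to 1
    mean: float
    mode: float  # midpoint of the most probable bin


def _kabsch_rotation(mobile_c: np.ndarray, ref_c: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered ``mobile_c`` to ``ref_c``."""
    h = mobile_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    # degenerate (collinear) selections leave the rotation under-determined
    if s[1] <= max(s[0], 1.0) * 1e-10:
        raise ValueError("degenerate (collinear or coincident) mask atoms; superposition ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, mask: SelectionMask
) -> tuple[np.ndarray, float]:
    """Rigid-body fit of one frame onto a reference over the mask atoms.

    Returns the transformed full frame and the mask-atom RMSD (Å), minimal
    over all proper rotations and translations.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    idx = mask.atom_indices
    if idx.max() >= mobile.shape[0]:
        raise ValueError(f"mask {mask.name!r} exceeds frame atom count")
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 mask atoms")
    mob_sel, ref_sel = mobile[idx], reference[idx]
    mob_cen, ref_cen = mob_sel.mean(axis=0), ref_sel.mean(axis=0)
    rot = _kabsch_rotation(mob_sel - mob_cen, ref_sel - ref_cen)
    moved = (mobile - mob_cen) @ rot.T + ref_cen
    rmsd = float(np.sqrt(np.mean(np.sum((moved[idx] - ref_sel) ** 2, axis=1))))
    return moved, rmsd


def _batch_superpose(frames: np.ndarray, ref: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Kabsch-fit every frame onto ``ref`` over atoms ``idx`` (batched SVD)."""
    sel = frames[:, idx, :]
    ref_sel = ref[idx]
    mob_cen = sel.mean(axis=1, keepdims=True)
    ref_cen = ref_sel.mean(axis=0)
    h = np.einsum("fni,nj->fij", sel - mob_cen, ref_sel - ref_cen)
    u, s, vt = np.linalg.svd(h)
    if np.any(s[:, 1] <= np.maximum(s[:, 0], 1.0) * 1e-10):
        raise ValueError("degenerate (collinear or coincident) mask atoms; superposition ill-defined")
    d = np.sign(np.linalg.det(np.einsum("fji,fkj->fik", vt, u)))
    vt[:, 2, :] *= d[:, None]
    rot = np.einsum("fji,fkj->fik", vt, u)  # (F, 3, 3) proper rotations
    return np.einsum("fni,fji->fnj", frames - mob_cen, rot) + ref_cen


def superpose_ensemble(
    ensemble: EnsembleFrameSet, fit_mask: SelectionMask | None = None, reference_frame: int = 0
) -> np.ndarray:
    """Superpose every frame on a reference frame; returns (F, N, 3) coordinates."""
    if fit_mask is None:
        fit_mask = calpha_mask(ensemble.topology)
    return _batch_superpose(ensemble.frames, ensemble.frames[reference_frame], fit_mask.atom_indices)


def superpose_to_mean(
    ensemble: EnsembleFrameSet,
    fit_mask: SelectionMask | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> np.ndarray:
    """Superpose every frame on the (iteratively refined) ensemble mean.

    Fluctuation statistics (RMSF, covariance, cross-correlations) are
    computed about the mean structure; fitting to the mean rather than to
    an arbitrary frame avoids leaking that frame's own displacement into
    every other frame's fit.  The mean structure is refined iteratively
    until the fit converges (mean displacement below ``tol`` Å), then
    rotated to a canonical principal-axes orientation so the result does
    not depend on frame order.
    """
    if fit_mask is None:
        fit_mask = calpha_mask(ensemble.topology)
    idx = fit_mask.atom_indices
    coords = superpose_ensemble(ensemble, fit_mask, reference_frame=0)
    ref = coords.mean(axis=0)
    for _ in range(max_iter):
        coords = _batch_superpose(coords, ref, idx)
        new_ref = coords.mean(axis=0)
        shift = float(np.abs(new_ref - ref).max())
        ref = new_ref
        if shift < tol:
            break
    # canonical orientation: principal axes of the mean structure
    sel = ref[fit_mask.atom_indices]
    centered = sel - sel.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    # fix axis signs deterministically and keep the frame right-handed
    for k in range(3):
        if (centered @ vt[k]).sum() < 0:
            vt[k] = -vt[k]
    if np.linalg.det(vt) < 0:
        vt[2] = -vt[2]
    center = sel.mean(axis=0)
    return (coords - center) @ vt.T


def rmsd_series(
    ensemble: EnsembleFrameSet,
    reference_frame: int = 0,
    fit_mask: SelectionMask | None = None,
    report_mask: SelectionMask | None = None,
) -> RMSDSeries:
    """Per-frame RMSD after fitting each frame on ``fit_mask``.

    The RMSD is reported over ``report_mask`` (default: the fit mask), so a
    region RMSD after a global fit is a single call.
    """
    if fit_mask is None:
        fit_mask = calpha_mask(ensemble.topology)
    if report_mask is None:
        report_mask = fit_mask
    if report_mask.size == 0:
        raise ValueError("empty report mask")
    ref = ensemble.frames[reference_frame]
    ridx = report_mask.atom_indices
    moved = _batch_superpose(ensemble.frames, ref, fit_mask.atom_indices)
    values = np.sqrt(np.mean(np.sum((moved[:, ridx, :] - ref[ridx]) ** 2, axis=2), axis=1))
    return RMSDSeries(
        values=values,
        mean=float(values.mean()),
        sd=float(values.std()),
        fit_mask=fit_mask.name,
        report_mask=report_mask.name,
        reference_frame=reference_frame,
    )


def rmsf_per_residue(
    ensemble: EnsembleFrameSet, fit_mask: SelectionMask | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue Cα RMSF (Å) about the ensemble mean after superposition.

    Returns ``(residue_indices, rmsf)``.  RMSF_i = sqrt(<|r_i - <r_i>|^2>).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    coords = superpose_to_mean(ensemble, fit_mask)
    residues = ensemble.topology.residue_indices
    ca = ensemble.topology.calpha_index
    cols = np.array([ca[int(r)] for r in residues])
    x = coords[:, cols, :]
    mean = x.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    return residues, rmsf


def pair_distance_distribution(
    ensemble: EnsembleFrameSet, pair: tuple[int, int], bin_width: float = 0.1
) -> DistanceSeries:
    """Distribution of the Cα–Cα distance between two residues.

    The default 0.1 Å bin width resolves shifts of a few tenths of an Å
    between ensembles.  The histogram is a probability mass (sums to 1).
    """
    i, j = int(pair[0]), int(pair[1])
    if i == j:
        raise ValueError("residue pair must be two distinct residues")
    ca = ensemble.topology.calpha_index
    if i not in ca or j not in ca:
        raise KeyError(f"residue pair {pair} not in topology")
    d = np.linalg.norm(ensemble.frames[:, ca[i], :] - ensemble.frames[:, ca[j], :], axis=1)
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(d, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    prob = counts / counts.sum()
    mode = float(0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))
    return DistanceSeries(
        pair=(i, j), distances=d, bin_edges=edges, probability=prob,
        mean=float(d.mean()), mode=mode,
    )
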