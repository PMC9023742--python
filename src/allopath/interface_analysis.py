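"""Geometric hydrogen-bond and salt-bridge detection across an interface.

Criteria are package conventions (configurable): a hydrogen bond is a
donor–acceptor heavy-atom distance ≤ 3.5 Å with a donor–H–acceptor angle
≥ 120°; a salt bridge is a minimum heavy-atom distance ≤ 4.0 Å between
oppositely charged groups.  Bead models carry no hydrogens, so a
distance-only proxy mode (flagged in the output) applies the hydrogen-bond
distance criterion alone.

Occupancy of an interaction is the fraction of ensemble frames in which
its criterion holds; interface counts at a representative frame mirror the
per-cluster interface tabulations common in the protein-complex
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from allopath.structure_io import EnsembleFrameSet

__all__ = [
    "InteractionCriteria",
    "InteractionRecord",
    "InterfaceReport",
    "detect_hbonds",
    "detect_salt_bridges",
    "interface_summary",
]


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs for interface interaction detection."""

    hbond_distance_max: float = 3.5  # Å, donor–acceptor
    hbond_angle_min: float = 120.0  # degrees, donor–H–acceptor
    salt_bridge_distance_max: float = 4.0  # Å, min heavy-atom
    min_abs_charge: float = 0.3  # e, to call a bead "charged"
    strict_hydrogens: bool = False  # error instead of proxy mode


@dataclass
class InteractionRecord:
    """One interface interaction with per-frame presence and occupancy."""

    kind: str  # "hydrogen_bond" | "salt_bridge"
    residue_i: int
    residue_j: int
    atom_i: int
    atom_j: int
    presence: np.ndarray  # (F,) bool
    occupancy: float
    proxy: bool = False  # distance-only hydrogen-bond criterion


@dataclass
class InterfaceReport:
    """All cross-segment interactions of an ensemble."""

    records: list[InteractionRecord]
    segment_a: str
    segment_b: str
    representative_frame: int
    count_at_representative: int
    criteria: InteractionCriteria

    def occupancy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [r.kind for r in self.records],
                "residue_i": [r.residue_i for r in self.records],
                "residue_j": [r.residue_j for r in self.records],
                "occupancy": [r.occupancy for r in self.records],
                "proxy": [r.proxy for r in self.records],
            }
        )

    def mean_occupancy(self) -> float:
        if not self.records:
            return 0.0
        return float(np.mean([r.occupancy for r in self.records]))


def detect_hbonds(
    coords: np.ndarray,
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    hydrogens: np.ndarray | None = None,
    strict: bool = False,
) -> list[tuple[int, int]]:
    """Hydrogen bonds present in one frame.

    ``hydrogens`` holds one H position per donor (shape ``(n_donors, 3)``);
    when absent the distance criterion alone is applied (proxy mode) unless
    ``strict`` is set, in which case the missing donors are reported in the
    raised error.
    """
    donors = np.asarray(donors, int)
    acceptors = np.asarray(acceptors, int)
    if hydrogens is None and strict:
        raise ValueError(f"missing hydrogen positions for donors {donors.tolist()}")
    out: list[tuple[int, int]] = []
    dpos = coords[donors]
    apos = coords[acceptors]
    dist = np.linalg.norm(dpos[:, None, :] - apos[None, :, :], axis=-1)
    for di, ai in zip(*np.nonzero(dist <= d_max)):
        d_atom, a_atom = int(donors[di]), int(acceptors[ai])
        if d_atom == a_atom:
            continue
        if hydrogens is not None:
            h = np.asarray(hydrogens[di], float)
            v1 = coords[d_atom] - h
            v2 = coords[a_atom] - h
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle < angle_min:
                continue
        out.append((d_atom, a_atom))
    return out


def detect_salt_bridges(
    coords: np.ndarray,
    cationic_groups: list,
    anionic_groups: list,
    d_max: float = 4.0,
) -> list[tuple[int, int]]:
    """Salt bridges present in one frame, as (cationic, anionic) group indices.

    A bridge exists when the minimum heavy-atom distance between the two
    groups is ≤ ``d_max``.
    """
    if not cationic_groups or not anionic_groups:
        raise ValueError("empty charged-group definitions")
    out = []
    for gi, cat in enumerate(cationic_groups):
        for gj, ani in enumerate(anionic_groups):
            d = np.linalg.norm(coords[np.asarray(cat)][:, None, :] - coords[np.asarray(ani)][None, :, :], axis=-1)
            if d.min() <= d_max:
                out.append((gi, gj))
    return out


def interface_summary(
    ensemble: EnsembleFrameSet,
    segment_a: str,
    segment_b: str,
    criteria: InteractionCriteria | None = None,
    representative_frame: int = 0,
) -> InterfaceReport:
    """Cross-segment interaction records with occupancies.

    Candidate pairs are all cross-segment atom pairs that satisfy their
    criterion in at least one frame; pairs of opposite charges (at least
    ``min_abs_charge``) are classified as salt bridges, all others as
    (proxy-mode) hydrogen bonds.  Intra-segment contacts never enter.
    """
    criteria = criteria or InteractionCriteria()
    top = ensemble.topology
    ia = top.atom_indices_of_segment(segment_a)
    ib = top.atom_indices_of_segment(segment_b)
    if np.intersect1d(ia, ib).size:
        raise ValueError(f"segments {segment_a!r} and {segment_b!r} overlap")
    if criteria.strict_hydrogens:
        raise ValueError(
            f"missing hydrogen positions for donors {ia.tolist()}; "
            "bead topologies support only the distance-only proxy criterion"
        )

    # (F, |A|, |B|) cross distances
    da = ensemble.frames[:, ia, :]
    db = ensemble.frames[:, ib, :]
    dist = np.linalg.norm(da[:, :, None, :] - db[:, None, :, :], axis=-1)

    qa = top.charges[ia][:, None]
    qb = top.charges[ib][None, :]
    salt_pair = (qa * qb < 0) & (np.abs(qa) >= criteria.min_abs_charge) & (np.abs(qb) >= criteria.min_abs_charge)
    cutoff = np.where(salt_pair, criteria.salt_bridge_distance_max, criteria.hbond_distance_max)
    present = dist <= cutoff  # (F, |A|, |B|)

    records: list[InteractionRecord] = []
    ever = present.any(axis=0)
    for i, j in zip(*np.nonzero(ever)):
        is_salt = bool(salt_pair[i, j])
        pres = present[:, i, j]
        records.append(
            InteractionRecord(
                kind="salt_bridge" if is_salt else "hydrogen_bond",
                residue_i=int(top.res_indices[ia[i]]),
                residue_j=int(top.res_indices[ib[j]]),
                atom_i=int(ia[i]),
                atom_j=int(ib[j]),
                presence=pres,
                occupancy=float(pres.mean()),
                proxy=not is_salt,
            )
        )
    count_rep = int(sum(r.presence[representative_frame] for r in records))
    return InterfaceReport(
        records=records,
        segment_a=segment_a,
        segment_b=segment_b,
        representative_frame=representative_frame,
        count_at_representative=count_rep,
        criteria=criteria,
    )
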