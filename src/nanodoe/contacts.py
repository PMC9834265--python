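"""Interface contact analysis and key-residue selection.

Given a docked nanobody–antigen pose, the mutable ("key") positions are the
nanobody residues that sit closest to the antigen. Contact distance between
two residues is the minimum over all atom pairs, under one of two metrics:

``min-atom``
    plain Euclidean distance between atom centres (Å, non-negative);
``vdw-gap``
    centre distance minus the two atoms' van der Waals radii — the surface
    gap, which is negative for interpenetrating spheres. Docking engines
    that report sub-Å "contact distances" are reporting something of this
    flavour.

Key residues are those whose per-residue minimum contact distance falls
*strictly below* a cutoff (default 2.2 Å).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import ResidueId, Structure

__all__ = [
    "ContactRecord",
    "ContactTable",
    "residue_contact_table",
    "select_key_residues",
    "vdw_radius",
    "DEFAULT_CUTOFF",
    "DEFAULT_RADIUS",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 2.2  # Å, strict upper bound for key residues
DEFAULT_RADIUS = 4.0  # Å, reporting radius — table-size control only

_FALLBACK_VDW = 1.70

with resources.files("nanodoe.data").joinpath("vdw_radii.json").open() as _fh:
    _VDW: dict[str, float] = {k: v for k, v in json.load(_fh).items() if not k.startswith("_")}


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius (Å); unknown elements fall back to 1.70."""
    r = _VDW.get(element.capitalize())
    if r is None:
        logger.warning("no van der Waals radius for element %r; using %.2f", element, _FALLBACK_VDW)
        return _FALLBACK_VDW
    return r


@dataclass(frozen=True)
class ContactRecord:
    nb_residue: ResidueId
    antigen_residue: ResidueId
    distance: float  # Å; minimum over all atom pairs under the table's metric


@dataclass
class ContactTable:
    metric: str
    records: list[ContactRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def minima(self) -> dict[ResidueId, float]:
        """Per nanobody-residue minimum contact distance."""
        out: dict[ResidueId, float] = {}
        for rec in self.records:
            cur = out.get(rec.nb_residue)
            if cur is None or rec.distance < cur:
                out[rec.nb_residue] = rec.distance
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "nb_chain": r.nb_residue.chain_id,
                "nb_resname": r.nb_residue.residue_name,
                "nb_resnum": r.nb_residue.residue_number,
                "icode": r.nb_residue.insertion_code,
                "ag_chain": r.antigen_residue.chain_id,
                "ag_resname": r.antigen_residue.residue_name,
                "ag_resnum": r.antigen_residue.residue_number,
                "ag_icode": r.antigen_residue.insertion_code,
                "distance_A": r.distance,
            }
            for r in self.records
        ]
        cols = [
            "nb_chain", "nb_resname", "nb_resnum", "icode",
            "ag_chain", "ag_resname", "ag_resnum", "ag_icode", "distance_A",
        ]
        return pd.DataFrame(rows, columns=cols)


def _group_arrays(structure: Structure, chains: set[str]):
    """Coordinates, per-atom vdW radius and residue index for one chain group."""
    sub = structure.select_chains(chains)
    residues: list[ResidueId] = []
    index: dict[ResidueId, int] = {}
    coords = np.empty((len(sub), 3))
    radii = np.empty(len(sub))
    res_idx = np.empty(len(sub), dtype=np.intp)
    for k, atom in enumerate(sub):
        rid = atom.residue_id
        if rid not in index:
            index[rid] = len(residues)
            residues.append(rid)
        coords[k] = (atom.x, atom.y, atom.z)
        radii[k] = vdw_radius(atom.element)
        res_idx[k] = index[rid]
    return residues, coords, radii, res_idx


def residue_contact_table(
    structure: Structure,
    group_a: set[str],
    group_b: set[str],
    *,
    metric: str = "min-atom",
    radius: float = DEFAULT_RADIUS,
) -> ContactTable:
    """Per-residue contact distances between two chain groups.

    For every residue of ``group_a`` (the nanobody side) with any atom within
    ``radius`` of ``group_b`` (the antigen side) under the chosen metric,
    lists each group_b residue within that radius together with the minimum
    atom-pair distance. The reporting radius only truncates the table; it
    never alters a reported minimum.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("chain selections must be non-empty")
    if group_a & group_b:
        raise ValueError(f"chain selections overlap: {sorted(group_a & group_b)}")
    if metric not in ("min-atom", "vdw-gap"):
        raise ValueError(f"unknown metric {metric!r}")

    res_a, xyz_a, rad_a, idx_a = _group_arrays(structure, group_a)
    res_b, xyz_b, rad_b, idx_b = _group_arrays(structure, group_b)
    if not res_a or not res_b:
        raise ValueError("a chain selection matched no atoms")

    d = cdist(xyz_a, xyz_b)
    if metric == "vdw-gap":
        d = d - rad_a[:, None] - rad_b[None, :]

    # residue-pair minima via a dense (n_res_a, n_res_b) reduction
    mins = np.full((len(res_a), len(res_b)), np.inf)
    np.minimum.at(mins, (idx_a[:, None], idx_b[None, :]), d)

    records = []
    for ia in range(len(res_a)):
        hits = np.where(mins[ia] <= radius)[0]
        for ib in hits[np.argsort(mins[ia, hits], kind="stable")]:
            records.append(ContactRecord(res_a[ia], res_b[ib], float(mins[ia, ib])))
    # sort by nb residue (chain, number, icode) keeping per-residue ascending distance
    records.sort(key=lambda r: (r.nb_residue.chain_id, r.nb_residue.residue_number,
                                r.nb_residue.insertion_code, r.distance))
    return ContactTable(metric=metric, records=records)


def select_key_residues(table: ContactTable, cutoff: float = DEFAULT_CUTOFF) -> list[ResidueId]:
    """Nanobody residues whose minimum contact distance is strictly below ``cutoff``.

    Sorted by residue number (then chain, insertion code). An empty result is
    a valid outcome: no residue is close enough to mutate.
    """
    if cutoff <= 0 and table.metric == "min-atom":
        raise ValueError("cutoff must be positive for the min-atom metric")
    selected = [rid for rid, dmin in table.minima().items() if dmin < cutoff]
    selected.sort(key=lambda r: (r.residue_number, r.chain_id, r.insertion_code))
    return selected
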