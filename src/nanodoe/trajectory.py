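"""RMSD / RMSF analysis of multi-frame coordinates.

The stability comparison between an engineered nanobody and its parent
rests on two standard trajectory statistics: the RMSD of each frame from a
reference after optimal rigid superposition (Kabsch), and the per-residue
RMSF about the time-average position. Input is multi-model PDB
(MODEL/ENDMDL blocks sharing one atom roster); the optimal rotation comes
from scipy's reflection-corrected ``Rotation.align_vectors``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structures import parse_structure

__all__ = ["Frame", "read_frames", "kabsch_rmsd", "rmsd_series", "rmsf"]

#: (chain_id, residue_number, insertion_code, atom_name)
AtomLabel = tuple[str, int, str, str]


@dataclass
class Frame:
    """One snapshot: an ordered atom roster with coordinates in Å."""

    labels: list[AtomLabel]
    coords: np.ndarray  # (n_atoms, 3)
    index: int = 0
    time_ns: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), 3):
            raise ValueError("coords must be (n_atoms, 3) matching the label roster")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def subset(self, mask: np.ndarray) -> "Frame":
        return Frame(
            labels=[l for l, m in zip(self.labels, mask) if m],
            coords=self.coords[mask],
            index=self.index,
            time_ns=self.time_ns,
        )


Selection = Callable[[AtomLabel], bool]


def select_atom_names(*names: str) -> Selection:
    allowed = set(names)
    return lambda label: label[3] in allowed


DEFAULT_SELECTION: Selection = select_atom_names("CA")


def read_frames(pdb_text: str, *, dt_ns: float | None = None) -> list[Frame]:
    """Parse a multi-model PDB into frames sharing one atom roster."""
    import gemmi

    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in trajectory")
    frames: list[Frame] = []
    roster: list[AtomLabel] | None = None
    for k in range(len(st)):
        structure = parse_structure(pdb_text, model_index=k)
        labels = [(a.chain_id, a.residue_number, a.insertion_code, a.atom_name) for a in structure]
        coords = np.array([(a.x, a.y, a.z) for a in structure])
        if roster is None:
            roster = labels
        elif labels != roster:
            raise ValueError(f"frame {k} atom roster differs from frame 0")
        frames.append(Frame(labels=labels, coords=coords, index=k,
                            time_ns=None if dt_ns is None else k * dt_ns))
    return frames


def _matched_selection(reference: Frame, frame: Frame, selection: Selection) -> tuple[np.ndarray, np.ndarray]:
    if reference.labels != frame.labels:
        raise ValueError("atom rosters differ between frames")
    mask = np.array([selection(l) for l in reference.labels], dtype=bool)
    if not mask.any():
        raise ValueError("selection matches no atoms")
    return reference.coords[mask], frame.coords[mask]


def _superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares fit of ``mobile`` onto ``target``; returns moved coordinates."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return (mobile - mc) @ rot.as_matrix().T + tc


def kabsch_rmsd(reference: Frame, frame: Frame, selection: Selection = DEFAULT_SELECTION) -> float:
    """RMSD (Å) between two frames after optimal rigid superposition."""
    ref, mob = _matched_selection(reference, frame, selection)
    moved = _superpose(mob, ref)
    return float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))


def rmsd_series(
    frames: Sequence[Frame],
    reference: Frame | None = None,
    selection: Selection = DEFAULT_SELECTION,
) -> pd.DataFrame:
    """Per-frame RMSD from a reference (default: the first frame)."""
    if not frames:
        raise ValueError("empty trajectory")
    ref = frames[0] if reference is None else reference
    rows = [
        {"frame": f.index, "time_ns": f.time_ns, "rmsd_A": kabsch_rmsd(ref, f, selection)}
        for f in frames
    ]
    return pd.DataFrame(rows, columns=["frame", "time_ns", "rmsd_A"])


def rmsf(
    frames: Sequence[Frame],
    selection: Selection = DEFAULT_SELECTION,
    *,
    n_align_passes: int = 2,
) -> pd.DataFrame:
    """Per-residue RMSF (Å) of the selected representative atoms.

    Frames are aligned to the mean structure iteratively (``n_align_passes``
    rounds: align to the running mean, recompute the mean), then RMSF_i is
    the root-mean-square distance of atom i from its time-average position.
    """
    if len(frames) < 2:
        raise ValueError("RMSF needs at least two frames")
    roster = frames[0].labels
    for f in frames[1:]:
        if f.labels != roster:
            raise ValueError("atom rosters differ between frames")
    mask = np.array([selection(l) for l in roster], dtype=bool)
    if not mask.any():
        raise ValueError("selection matches no atoms")
    labels = [l for l, m in zip(roster, mask) if m]
    stack = np.stack([f.coords[mask] for f in frames])  # (n_frames, n_sel, 3)

    mean = stack.mean(axis=0)  # order-invariant initial reference
    for _ in range(n_align_passes):
        aligned = np.stack([_superpose(x, mean) for x in stack])
        mean = aligned.mean(axis=0)
    dev = aligned - mean[None]
    per_atom = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return pd.DataFrame(
        {
            "chain": [l[0] for l in labels],
            "resnum": [l[1] for l in labels],
            "icode": [l[2] for l in labels],
            "rmsf_A": per_atom,
        }
    )
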