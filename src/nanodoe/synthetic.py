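"""Synthetic inputs for every pipeline stage — no downloads required.

The docking engine behind the published protocol is proprietary, so this
module supplies its statistical stand-ins:

* a surrogate **additive energy model** over position/amino-acid
  assignments, E(v) = beta0 + sum_f beta_f(level) (+ optional sparse
  pairwise interaction terms) + Gaussian noise, calibrated so every
  design-reachable energy stays strictly negative like a docked binding
  energy;
* **recovery experiments** that quantify how often the 25-run orthogonal
  screen finds the per-factor optimum of the full 15,625-variant space
  under noise;
* **toy complexes** in PDB text with planted nanobody–antigen contact
  distances (exact at the format's 3-decimal coordinate precision);
* a **stand-in nanobody sequence** carrying the documented wild-type
  residues at the six key positions (the real sequence lives behind a
  patent accession and is not shipped);
* **synthetic trajectories** with planted per-residue fluctuation scales
  for the RMSD/RMSF machinery.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mutagenesis import AminoAcidSequence
from .taguchi import (
    PAPER_LEVELS,
    PAPER_POSITIONS,
    DesignTable,
    FactorSpec,
    attach_levels,
    build_orthogonal_array,
    sn_larger_is_better,
)

__all__ = [
    "EnergyModel",
    "RecoveryResult",
    "make_energy_model",
    "score_variant",
    "score_design",
    "true_best_levels",
    "brute_force_minimum",
    "recovery_experiment",
    "make_toy_complex",
    "make_base_sequence",
    "make_trajectory",
    "DEFAULT_BETA0",
]

DEFAULT_BETA0 = -700.0  # kcal/mol; desk-scale mimic of the published energy range
DEFAULT_EFFECT_SCALE = 30.0


@dataclass
class EnergyModel:
    """Additive (optionally pairwise-coupled) surrogate binding-energy model."""

    beta0: float
    positions: tuple[int, ...]
    levels: tuple[str, ...]
    effects: dict[int, dict[str, float]]  # position -> level -> kcal/mol offset
    interactions: dict[tuple[tuple[int, int], tuple[str, str]], float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta0 >= 0:
            raise ValueError("beta0 must be negative (a binding energy)")
        self._noise_rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0x5E1F]))
        worst = self.beta0 + sum(max(e.values()) for e in self.effects.values())
        worst += sum(v for v in self.interactions.values() if v > 0)
        if worst >= 0:
            raise ValueError(
                f"noiseless energies must stay strictly negative; worst case {worst:+.2f} kcal/mol"
            )

    def factors(self) -> list[FactorSpec]:
        return [FactorSpec(p, self.levels) for p in self.positions]

    def noiseless(self, assignment: Mapping[int, str]) -> float:
        e = self.beta0
        for p in self.positions:
            aa = assignment[p]
            if aa not in self.effects[p]:
                raise ValueError(f"unknown level {aa!r} at position {p}")
            e += self.effects[p][aa]
        for ((p1, p2), (a1, a2)), v in self.interactions.items():
            if assignment[p1] == a1 and assignment[p2] == a2:
                e += v
        return e


def make_energy_model(
    seed: int,
    *,
    effect_scale: float = DEFAULT_EFFECT_SCALE,
    interaction_scale: float = 0.0,
    noise_sigma: float = 0.0,
    beta0: float = DEFAULT_BETA0,
    positions: Sequence[int] = PAPER_POSITIONS,
    levels: Sequence[str] = PAPER_LEVELS,
    n_interactions: int = 3,
) -> EnergyModel:
    """Draw a seeded surrogate model.

    Per-position, per-level effects are uniform on [-effect_scale,
    +effect_scale]. With ``interaction_scale > 0``, ``n_interactions``
    position pairs get one uniform pairwise term each. Identical seeds give
    identical models.
    """
    if effect_scale < 0 or interaction_scale < 0 or noise_sigma < 0:
        raise ValueError("scales must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE44E]))
    positions = tuple(int(p) for p in positions)
    levels = tuple(levels)
    effects = {
        p: {aa: float(rng.uniform(-effect_scale, effect_scale)) for aa in levels}
        for p in positions
    }
    interactions: dict[tuple[tuple[int, int], tuple[str, str]], float] = {}
    if interaction_scale > 0 and len(positions) >= 2:
        pairs = list(itertools.combinations(positions, 2))
        chosen = rng.choice(len(pairs), size=min(n_interactions, len(pairs)), replace=False)
        for k in chosen:
            p1, p2 = pairs[int(k)]
            a1, a2 = rng.choice(levels), rng.choice(levels)
            interactions[((p1, p2), (str(a1), str(a2)))] = float(
                rng.uniform(-interaction_scale, interaction_scale)
            )
    return EnergyModel(
        beta0=beta0, positions=positions, levels=levels, effects=effects,
        interactions=interactions, noise_sigma=noise_sigma, seed=int(seed),
    )


def score_variant(model: EnergyModel, assignment: Mapping[int, str]) -> float:
    """Surrogate binding energy of one variant (noise drawn from the model's stream)."""
    e = model.noiseless(assignment)
    if model.noise_sigma > 0:
        e += float(model._noise_rng.normal(0.0, model.noise_sigma))
    return e


def score_design(model: EnergyModel, design: DesignTable) -> np.ndarray:
    """Surrogate energies for every run of a design, in run order."""
    return np.array([score_variant(model, row) for row in design.rows])


def _effects_matrix(model: EnergyModel) -> np.ndarray:
    return np.array([[model.effects[p][aa] for aa in model.levels] for p in model.positions])


def brute_force_minimum(model: EnergyModel) -> tuple[dict[int, str], float]:
    """Noiseless global minimum by enumerating all |levels|**|positions| variants."""
    n_pos, n_lev = len(model.positions), len(model.levels)
    eff = _effects_matrix(model)
    grids = np.meshgrid(*[np.arange(n_lev)] * n_pos, indexing="ij")
    total = np.full(grids[0].shape, model.beta0)
    for k in range(n_pos):
        total += eff[k][grids[k]]
    for ((p1, p2), (a1, a2)), v in model.interactions.items():
        i1, i2 = model.positions.index(p1), model.positions.index(p2)
        l1, l2 = model.levels.index(a1), model.levels.index(a2)
        total += v * ((grids[i1] == l1) & (grids[i2] == l2))
    flat = int(np.argmin(total))
    idx = np.unravel_index(flat, total.shape)
    assignment = {p: model.levels[idx[k]] for k, p in enumerate(model.positions)}
    return assignment, float(total[idx])


def true_best_levels(model: EnergyModel) -> dict[int, str]:
    """Per-position level of the brute-force noiseless global minimum."""
    assignment, _ = brute_force_minimum(model)
    return assignment


@dataclass
class RecoveryResult:
    per_factor: dict[int, float]  # position -> fraction of replicates recovering truth
    overall: float  # mean over (replicate, factor) pairs
    n_reps: int
    truth: dict[int, str]


def _design_argmax_levels(design: DesignTable, energies: np.ndarray) -> dict[int, str]:
    """Top level per factor by mean S/N of |E| (first level wins exact ties)."""
    sn = sn_larger_is_better(np.abs(energies))
    out: dict[int, str] = {}
    for f in design.factors:
        col = np.array([row[f.position] for row in design.rows])
        means = [sn[col == l].mean() for l in f.levels]
        out[f.position] = f.levels[int(np.argmax(means))]
    return out


def recovery_experiment(model: EnergyModel, n_reps: int, seed: int) -> RecoveryResult:
    """How often does the orthogonal screen recover the true best levels?

    Per replicate: draw i.i.d. Gaussian noise (``model.noise_sigma``) on the
    design's run energies, take the top level per factor by mean S/N of
    |E|, and compare with the brute-force optimum of the noiseless model.
    At zero noise and zero interactions recovery is exact by column balance.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    design = attach_levels(
        build_orthogonal_array(len(model.levels), len(model.positions)), model.factors()
    )
    base = np.array([model.noiseless(row) for row in design.rows])
    truth = true_best_levels(model)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4EC0]))
    hits = {p: 0 for p in model.positions}
    for _ in range(n_reps):
        noisy = base + rng.normal(0.0, model.noise_sigma, size=base.shape) \
            if model.noise_sigma > 0 else base
        picked = _design_argmax_levels(design, noisy)
        for p in model.positions:
            hits[p] += picked[p] == truth[p]
    per_factor = {p: hits[p] / n_reps for p in model.positions}
    overall = float(np.mean(list(per_factor.values())))
    return RecoveryResult(per_factor=per_factor, overall=overall, n_reps=n_reps, truth=truth)


# --- toy complexes -----------------------------------------------------------

_PDB_ATOM = (
    "{rec:<6s}{serial:>5d} {name:^4s}{alt:1s}{res:<3s} {chain:1s}{resnum:>4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def _atom_line(serial, name, res, chain, resnum, x, y, z, elem="C") -> str:
    return _PDB_ATOM.format(
        rec="ATOM", serial=serial, name=name, alt=" ", res=res, chain=chain,
        resnum=resnum, icode=" ", x=x, y=y, z=z, occ=1.0, b=0.0, elem=elem,
    )


def make_toy_complex(
    planted_contacts: Sequence[float],
    seed: int = 0,
    *,
    decoys_per_chain: int = 2,
    pair_spacing: float = 25.0,
    with_records: bool = False,
):
    """Two-chain PDB text with one residue pair per planted contact distance.

    Pair k sits at y = k * ``pair_spacing``: chain A residue k+1 has its
    contact atom at the origin of that row and chain B residue 101+k has
    its contact atom ``planted_contacts[k]`` along +x, so the minimum
    atom-pair distance equals the planted value exactly (at the PDB
    format's 3-decimal precision — plant values with <= 3 decimals for
    1e-6 round-trips). Each residue also gets a second, farther atom, and
    seeded decoy residues are placed well outside the 4 Å reporting radius.
    With ``with_records=True`` also returns the generator's own atom list
    as (chain, resname, resnum, atom_name, x, y, z) tuples.
    """
    if any(d <= 0 for d in planted_contacts):
        raise ValueError("planted contact distances must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x70Ca]))
    records: list[tuple[str, str, int, str, float, float, float]] = []

    def add(name, res, chain, resnum, x, y, z):
        records.append((chain, res, resnum, name, round(float(x), 3), round(float(y), 3), round(float(z), 3)))

    for k, d in enumerate(planted_contacts):
        y = k * pair_spacing
        add("CA", "ALA", "A", k + 1, 0.0, y, 0.0)
        add("CB", "ALA", "A", k + 1, -2.0, y, 0.5)
        add("CA", "GLY", "B", 101 + k, round(float(d), 3), y, 0.0)
        add("C", "GLY", "B", 101 + k, round(float(d), 3) + 2.0, y, -0.5)
    for k in range(decoys_per_chain):
        jz = float(rng.uniform(-1, 1))
        add("CA", "SER", "A", 50 + k, -40.0 - 10 * k, float(rng.uniform(0, 5)), jz)
        add("CA", "THR", "B", 150 + k, 60.0 + 10 * k, float(rng.uniform(0, 5)), -jz)
    lines = [
        _atom_line(serial, name, res, chain, resnum, x, y, z)
        for serial, (chain, res, resnum, name, x, y, z) in enumerate(records, start=1)
    ]
    lines.append("END\n")
    text = "".join(lines)
    return (text, records) if with_records else text


# --- stand-in nanobody sequence ---------------------------------------------

_STANDIN = (
    "QVQLVESGGGLVQPGGSLRLSCAAS"  # 1-25    framework 1
    "GSTFSINA"                   # 26-33   CDR1 (S27, T28, F29, I31)
    "MGWYRQAPGKQRELVAA"          # 34-50   framework 2
    "ITSGGST"                    # 51-57   CDR2
    "NYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYC"  # 58-95 framework 3
    "AARDNSYGYDYDY"              # 96-108  CDR3 (D99, N100)
    "WGQGTQVTVSS"                # 109-119 framework 4
)


def make_base_sequence() -> AminoAcidSequence:
    """Synthetic VHH-like stand-in for the patent-accession nanobody.

    Not the study's sequence: a generic single-domain antibody scaffold
    carrying the documented wild-type residues at the six key positions
    (Ser27, Thr28, Phe29, Ile31, Asp99, Asn100) under sequential 1-based
    numbering, with CDRs at 26-33 / 51-57 / 96-108.
    """
    return AminoAcidSequence(id="synthetic-nb-standin", residues=_STANDIN)


# --- synthetic trajectories ---------------------------------------------------

def make_trajectory(
    planted_sigmas: Sequence[float],
    n_frames: int,
    seed: int = 0,
    *,
    spacing: float = 8.0,
) -> str:
    """Multi-model PDB text with planted per-residue fluctuation scales.

    One CA atom per residue on a coarse helix (rise ``spacing`` Å, radius
    4 Å — a non-collinear scaffold keeps the superposition well
    conditioned), displaced each frame by i.i.d. Gaussian noise with
    per-axis standard deviation ``planted_sigmas[i]``; a residue's expected
    RMSF about its mean is sigma_i * sqrt(3), less the small fraction the
    rigid fit absorbs. Residues with sigma 0 anchor the superposition.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    sig = np.asarray(planted_sigmas, dtype=float)
    if np.any(sig < 0):
        raise ValueError("sigmas must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7Fa3]))
    idx = np.arange(len(sig))
    base = np.column_stack(
        [idx * spacing, 4.0 * np.sin(1.7 * idx), 4.0 * np.cos(1.7 * idx)]
    )
    lines = []
    for f in range(n_frames):
        lines.append(f"MODEL     {f + 1:>4d}\n")
        disp = rng.normal(0.0, 1.0, size=base.shape) * sig[:, None]
        coords = base + disp
        for i, (x, y, z) in enumerate(coords):
            lines.append(_atom_line(i + 1, "CA", "ALA", "A", i + 1,
                                    float(x), float(y), float(z)))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    return "".join(lines)
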