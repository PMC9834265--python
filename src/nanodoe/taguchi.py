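"""Taguchi orthogonal-array design and signal-to-noise main-effects analysis.

The affinity-maturation problem is a fractional-factorial screen: six
nanobody positions (factors), five candidate amino acids each (levels),
hence 5**6 = 15,625 possible variants. An L25(5^6) orthogonal array screens
this space with 25 runs: every column contains each level five times, and
every ordered pair of columns contains every ordered level pair exactly
once, so per-factor main effects are estimated without confounding.

Responses are docking binding energies in kcal/mol — negative, lower is
better. The analysis uses the Taguchi larger-the-better statistic on the
energy magnitude y = |E|:

    S/N = -10 * log10( mean(1 / y**2) )   [dB]

which for a single replicate reduces to 20*log10(y). For each factor, the
mean S/N of the runs at each level is the main effect; the level with the
highest mean wins, with near-ties (within ``tie_tol`` dB) all retained and
carried into the variant proposal as a Cartesian product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "OrthogonalArray",
    "DesignTable",
    "MainEffectsTable",
    "OrthogonalityReport",
    "DesignSummary",
    "build_orthogonal_array",
    "verify_orthogonality",
    "attach_levels",
    "sn_larger_is_better",
    "main_effects",
    "propose_variants",
    "count_variant_space",
    "summarize_design",
    "paper_factors",
    "load_reference_design",
    "PAPER_POSITIONS",
    "PAPER_LEVELS",
    "ORIGINAL_RESIDUES",
    "ORIGINAL_ENERGY",
    "DEFAULT_TIE_TOL",
]

#: Key positions and candidate loop residues of the anti-CD20 study design.
PAPER_POSITIONS: tuple[int, ...] = (27, 28, 29, 31, 99, 100)
PAPER_LEVELS: tuple[str, ...] = ("Trp", "Phe", "His", "Asp", "Tyr")
#: Wild-type residues at the key positions (one-letter: S, T, F, I, D, N).
ORIGINAL_RESIDUES: dict[int, str] = {27: "Ser", 28: "Thr", 29: "Phe", 31: "Ile", 99: "Asp", 100: "Asn"}
#: Docked binding energy of the unmutated nanobody, kcal/mol.
ORIGINAL_ENERGY: float = -745.6

DEFAULT_TIE_TOL = 0.02  # dB; resolves genuine near-ties (~0.003 dB) without merging distinct effects (>= 0.04 dB)
DEFAULT_PROPOSAL_CAP = 64


@dataclass(frozen=True)
class FactorSpec:
    """One mutable position and its ordered amino-acid level list."""

    position: int
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"position must be positive, got {self.position}")
        if len(self.levels) < 2:
            raise ValueError("a factor needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"levels must be distinct: {self.levels}")
        object.__setattr__(self, "levels", tuple(self.levels))


def paper_factors() -> list[FactorSpec]:
    """The six-position, five-residue factor set of the reference study."""
    return [FactorSpec(pos, PAPER_LEVELS) for pos in PAPER_POSITIONS]


@dataclass(frozen=True)
class OrthogonalArray:
    n_runs: int
    n_factors: int
    n_levels: int
    entries: np.ndarray  # (n_runs, n_factors), level indices 1..n_levels

    def row(self, run: int) -> tuple[int, ...]:
        """Level indices of one run (1-based run number)."""
        return tuple(int(v) for v in self.entries[run - 1])


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % k for k in range(2, int(n**0.5) + 1))


def build_orthogonal_array(n_levels: int = 5, n_factors: int = 6) -> OrthogonalArray:
    """Cyclic Latin-square construction of an L(n^2) array for prime ``n_levels``.

    Runs are indexed by (i, j), i,j in 1..n; run = (i-1)*n + j. Column 1
    carries i, column 2 carries j, and column m >= 3 carries
    ``((m-2)*(i-1) + (j-1)) mod n + 1``. Primality of n makes the m >= 3
    columns mutually orthogonal Latin squares, so up to n+1 factors fit.
    """
    if not _is_prime(n_levels):
        raise ValueError(f"n_levels must be prime for this construction, got {n_levels}")
    if not 2 <= n_factors <= n_levels + 1:
        raise ValueError(f"n_factors must be in [2, {n_levels + 1}], got {n_factors}")
    n = n_levels
    entries = np.empty((n * n, n_factors), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            r = (i - 1) * n + j - 1
            entries[r, 0] = i
            entries[r, 1] = j
            for m in range(3, n_factors + 1):
                entries[r, m - 1] = ((m - 2) * (i - 1) + (j - 1)) % n + 1
    return OrthogonalArray(n_runs=n * n, n_factors=n_factors, n_levels=n, entries=entries)


@dataclass
class OrthogonalityReport:
    passed: bool
    expected_count: float
    #: (col_a, col_b) -> {(level_a, level_b): count}
    pair_counts: dict[tuple[int, int], dict[tuple[int, int], int]]
    failures: list[tuple[int, int]]


def verify_orthogonality(array: OrthogonalArray) -> OrthogonalityReport:
    """Count ordered level pairs for every column pair; pass iff all equal n_runs/n_levels**2."""
    expected = array.n_runs / array.n_levels**2
    pair_counts: dict[tuple[int, int], dict[tuple[int, int], int]] = {}
    failures: list[tuple[int, int]] = []
    levels = range(1, array.n_levels + 1)
    for a, b in itertools.combinations(range(array.n_factors), 2):
        counts = {(la, lb): 0 for la in levels for lb in levels}
        for r in range(array.n_runs):
            counts[(int(array.entries[r, a]), int(array.entries[r, b]))] += 1
        pair_counts[(a, b)] = counts
        if any(c != expected for c in counts.values()):
            failures.append((a, b))
    return OrthogonalityReport(
        passed=not failures, expected_count=expected, pair_counts=pair_counts, failures=failures
    )


@dataclass
class DesignTable:
    """An orthogonal array with amino-acid levels bound and optional responses."""

    factors: list[FactorSpec]
    rows: list[dict[int, str]]  # per run: position -> amino acid
    responses: np.ndarray | None = None  # kcal/mol, uniformly signed

    @property
    def n_runs(self) -> int:
        return len(self.rows)

    @property
    def positions(self) -> list[int]:
        return [f.position for f in self.factors]

    def require_responses(self) -> np.ndarray:
        if self.responses is None:
            raise ValueError("design has no responses; attach binding energies first")
        return self.responses

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [[row[p] for p in self.positions] for row in self.rows],
            columns=[f"pos{p}" for p in self.positions],
        )
        df.insert(0, "run", np.arange(1, self.n_runs + 1))
        if self.responses is not None:
            df["energy_kcal_mol"] = self.responses
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, factors: list[FactorSpec] | None = None) -> "DesignTable":
        pos_cols = [c for c in df.columns if c.startswith("pos")]
        positions = [int(c[3:]) for c in pos_cols]
        rows = [
            {p: str(df.iloc[r][c]) for p, c in zip(positions, pos_cols)}
            for r in range(len(df))
        ]
        if factors is None:
            factors = []
            for p, c in zip(positions, pos_cols):
                seen: dict[str, None] = {}
                for aa in df[c]:
                    seen.setdefault(str(aa), None)
                factors.append(FactorSpec(p, tuple(seen)))
        responses = None
        if "energy_kcal_mol" in df.columns:
            responses = _validate_responses(df["energy_kcal_mol"].to_numpy(dtype=float), len(df))
        return cls(factors=factors, rows=rows, responses=responses)


def _validate_responses(responses: Sequence[float], n_runs: int) -> np.ndarray:
    arr = np.asarray(responses, dtype=float)
    if arr.shape != (n_runs,):
        raise ValueError(f"expected {n_runs} responses, got shape {arr.shape}")
    if np.any(arr == 0) or not (np.all(arr > 0) or np.all(arr < 0)):
        raise ValueError("binding energies must be nonzero and uniformly signed")
    return arr


def attach_levels(
    array: OrthogonalArray,
    factors: Sequence[FactorSpec],
    responses: Sequence[float] | None = None,
) -> DesignTable:
    """Bind amino-acid levels (and optional energies) to an orthogonal array."""
    factors = list(factors)
    if len(factors) != array.n_factors:
        raise ValueError(f"array has {array.n_factors} factors, got {len(factors)} specs")
    for f in factors:
        if len(f.levels) != array.n_levels:
            raise ValueError(
                f"factor at position {f.position} has {len(f.levels)} levels, array needs {array.n_levels}"
            )
    rows = [
        {f.position: f.levels[array.entries[r, k] - 1] for k, f in enumerate(factors)}
        for r in range(array.n_runs)
    ]
    resp = None if responses is None else _validate_responses(responses, array.n_runs)
    return DesignTable(factors=factors, rows=rows, responses=resp)


def load_reference_design() -> DesignTable:
    """The packaged 25-run anti-CD20 design with its docked binding energies."""
    with resources.files("nanodoe.data").joinpath("table1_design.csv").open() as fh:
        df = pd.read_csv(fh)
    return DesignTable.from_frame(df, factors=paper_factors())


def sn_larger_is_better(values) -> np.ndarray:
    """Per-run larger-the-better S/N in dB: -10*log10(mean(1/y**2)).

    ``values`` is one magnitude per run, or a (n_runs, n_replicates) array /
    list of per-run replicate lists. Single replicates reduce to 20*log10(y).
    """
    rows = [np.atleast_1d(np.asarray(v, dtype=float)) for v in values]
    out = np.empty(len(rows))
    for k, y in enumerate(rows):
        if np.any(y <= 0):
            raise ValueError("S/N requires strictly positive magnitudes")
        out[k] = -10.0 * np.log10(np.mean(1.0 / y**2))
    return out


@dataclass
class MainEffectsTable:
    """Per-factor, per-level mean S/N with deltas, ranks and selected levels."""

    factors: list[FactorSpec]
    means: pd.DataFrame  # index: position, columns: level names (union), dB
    deltas: pd.Series  # per position, max - min of level means
    ranks: pd.Series  # 1 = largest delta
    tie_tol: float
    selected: dict[int, list[str]]  # position -> levels within tie_tol of the best

    def to_dict(self) -> dict:
        return {
            "tie_tol_db": self.tie_tol,
            "means_db": {str(p): {l: float(self.means.loc[p, l]) for l in self.means.columns
                                  if not pd.isna(self.means.loc[p, l])}
                         for p in self.means.index},
            "delta_db": {str(p): float(self.deltas[p]) for p in self.deltas.index},
            "rank": {str(p): int(self.ranks[p]) for p in self.ranks.index},
            "selected": {str(p): list(v) for p, v in self.selected.items()},
        }


def main_effects(design: DesignTable, tie_tol: float = DEFAULT_TIE_TOL) -> MainEffectsTable:
    """Mean S/N per factor level, with near-ties within ``tie_tol`` dB retained.

    Requires a balanced design: every level of every factor must occupy the
    same number of runs (guaranteed by any orthogonal array).
    """
    responses = design.require_responses()
    if tie_tol < 0:
        raise ValueError("tie_tol must be non-negative")
    sn = sn_larger_is_better(np.abs(responses))
    level_union: list[str] = []
    for f in design.factors:
        for l in f.levels:
            if l not in level_union:
                level_union.append(l)
    means = pd.DataFrame(np.nan, index=design.positions, columns=level_union, dtype=float)
    selected: dict[int, list[str]] = {}
    expected = design.n_runs / len(design.factors[0].levels) if design.factors else 0
    for f in design.factors:
        col = np.array([row[f.position] for row in design.rows])
        for l in f.levels:
            mask = col == l
            if mask.sum() == 0:
                raise ValueError(f"unbalanced design: level {l} absent at position {f.position}")
            means.loc[f.position, l] = sn[mask].mean()
        counts = {l: int((col == l).sum()) for l in f.levels}
        if len(set(counts.values())) != 1:
            raise ValueError(f"unbalanced design at position {f.position}: {counts}")
        row = means.loc[f.position, list(f.levels)]
        best = row.max()
        selected[f.position] = [l for l in f.levels if row[l] >= best - tie_tol]
    deltas = pd.Series(
        {f.position: means.loc[f.position, list(f.levels)].max() - means.loc[f.position, list(f.levels)].min()
         for f in design.factors}
    )
    ranks = deltas.rank(ascending=False, method="min").astype(int)
    return MainEffectsTable(
        factors=design.factors, means=means, deltas=deltas, ranks=ranks,
        tie_tol=tie_tol, selected=selected,
    )


def propose_variants(
    effects: MainEffectsTable,
    base_sequence=None,
    *,
    cap: int = DEFAULT_PROPOSAL_CAP,
) -> list[dict[int, str]] | list:
    """Cartesian product of the selected levels across factors.

    Variants are ordered deterministically: factors in design order, levels
    in each factor's declared level order. With a base
    :class:`~nanodoe.mutagenesis.AminoAcidSequence`, returns mutated
    sequences instead of bare position->amino-acid assignments.
    """
    sizes = [len(effects.selected[f.position]) for f in effects.factors]
    total = int(np.prod(sizes)) if sizes else 0
    if total == 0:
        raise ValueError("no selected levels to combine")
    if total > cap:
        raise ValueError(
            f"{total} candidate variants exceed the cap of {cap}; tighten tie_tol"
        )
    assignments = [
        dict(zip([f.position for f in effects.factors], combo))
        for combo in itertools.product(*(effects.selected[f.position] for f in effects.factors))
    ]
    if base_sequence is None:
        return assignments
    from .mutagenesis import mutate_to_assignment  # local import: avoids a cycle

    return [mutate_to_assignment(base_sequence, a) for a in assignments]


def count_variant_space(factors: Sequence[FactorSpec]) -> int:
    """Size of the full combinatorial variant space, prod of level counts."""
    if not factors:
        raise ValueError("need at least one factor")
    return int(np.prod([len(f.levels) for f in factors]))


@dataclass
class DesignSummary:
    best_run: int  # 1-based; argmin of signed energy, ties -> lowest index
    best_energy: float
    worst_run: int
    worst_energy: float
    sn_db: np.ndarray  # per run
    reference_energy: float | None = None
    n_below_reference: int | None = None


def summarize_design(design: DesignTable, reference_energy: float | None = None) -> DesignSummary:
    """Best/worst run by signed energy plus per-run S/N.

    With a ``reference_energy`` (e.g. the unmutated nanobody's docking
    score), also counts the runs strictly below it.
    """
    responses = design.require_responses()
    sn = sn_larger_is_better(np.abs(responses))
    best = int(np.argmin(responses))  # np.argmin takes the first minimum: lowest run index on ties
    worst = int(np.argmax(responses))
    n_below = None
    if reference_energy is not None:
        n_below = int(np.sum(responses < reference_energy))
    return DesignSummary(
        best_run=best + 1,
        best_energy=float(responses[best]),
        worst_run=worst + 1,
        worst_energy=float(responses[worst]),
        sn_db=sn,
        reference_energy=reference_energy,
        n_below_reference=n_below,
    )
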