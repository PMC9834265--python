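"""ProtParam-style physicochemical panel for candidate nanobody sequences.

Computes the quality-control numbers a developability screen looks at:
average-mass molecular weight, theoretical pI, instability index (dipeptide
DIWV statistic, < 40 classified stable), aliphatic index, GRAVY
(Kyte–Doolittle mean hydropathy), charged-residue tallies and the
N-end-rule half-life estimate in three expression contexts.

MW, GRAVY and the instability index delegate to Biopython's ProtParam
implementation, which uses the same published tables as the ExPASy service.
The theoretical pI is computed here: the net-charge function

    Q(pH) = sum_pos 1/(1 + 10**(pH - pKa)) - sum_neg 1/(1 + 10**(pKa - pH))

over the N-terminus, C-terminus and the D,E,C,Y,H,K,R side chains with the
Bjellqvist pKa set is strictly decreasing in pH, so the isoelectric point
is the unique root, found by bisection on [0, 14]. Cysteines are treated as
reduced (titratable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .mutagenesis import AminoAcidSequence

__all__ = ["PropertyReport", "compute_properties", "isoelectric_point", "net_charge",
           "aliphatic_index", "half_life"]

with resources.files("nanodoe.data").joinpath("pka_bjellqvist.json").open() as _fh:
    _PKA = json.load(_fh)
POSITIVE_PKS: dict[str, float] = dict(_PKA["positive"])
NEGATIVE_PKS: dict[str, float] = dict(_PKA["negative"])
NTERM_PKS: dict[str, float] = dict(_PKA["nterm_overrides"])  # residue-specific alpha-amino pKa
CTERM_PKS: dict[str, float] = dict(_PKA["cterm_overrides"])  # residue-specific alpha-carboxyl pKa

with resources.files("nanodoe.data").joinpath("half_life.json").open() as _fh:
    _HALF_LIFE = {k: v for k, v in json.load(_fh).items() if not k.startswith("_")}

STABILITY_THRESHOLD = 40.0  # instability index below this -> "stable"


def _as_string(seq) -> str:
    return seq.residues if isinstance(seq, AminoAcidSequence) else str(seq)


def net_charge(seq, pH: float) -> float:
    """Modeled net charge of the sequence at a given pH (Bjellqvist pKa)."""
    s = _as_string(seq)
    counts = {aa: s.count(aa) for aa in "DECYHKR"}
    pk_n = NTERM_PKS.get(s[0], POSITIVE_PKS["Nterm"])
    pk_c = CTERM_PKS.get(s[-1], NEGATIVE_PKS["Cterm"])
    q = 1.0 / (1.0 + 10 ** (pH - pk_n))
    q -= 1.0 / (1.0 + 10 ** (pk_c - pH))
    for aa in "HKR":
        q += counts[aa] / (1.0 + 10 ** (pH - POSITIVE_PKS[aa]))
    for aa in "DECY":
        q -= counts[aa] / (1.0 + 10 ** (NEGATIVE_PKS[aa] - pH))
    return q


def isoelectric_point(seq, tol: float = 0.001) -> float:
    """pH at which the modeled net charge vanishes, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def aliphatic_index(seq) -> float:
    """Relative volume of aliphatic side chains: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu)."""
    s = _as_string(seq)
    n = len(s)
    mol_pct = {aa: 100.0 * s.count(aa) / n for aa in "AVIL"}
    return mol_pct["A"] + 2.9 * mol_pct["V"] + 3.9 * (mol_pct["I"] + mol_pct["L"])


def half_life(seq) -> dict[str, str]:
    """N-end-rule half-life estimates keyed by expression context."""
    nterm = _as_string(seq)[0]
    mam, yeast, ecoli = _HALF_LIFE[nterm]
    return {
        "mammalian_reticulocytes_in_vitro": mam,
        "yeast_in_vivo": yeast,
        "escherichia_coli_in_vivo": ecoli,
    }


@dataclass(frozen=True)
class PropertyReport:
    sequence_id: str
    length: int
    mw_da: float
    pI: float
    instability_index: float
    stability_class: str  # "stable" iff instability_index < 40
    aliphatic_index: float
    gravy: float
    n_negative: int  # Asp + Glu
    n_positive: int  # Arg + Lys
    half_life: dict[str, str]

    @property
    def mw_kda(self) -> float:
        return self.mw_da / 1000.0

    def to_dict(self) -> dict:
        return {
            "sequence_id": self.sequence_id,
            "length": self.length,
            "mw_da": round(self.mw_da, 2),
            "mw_kda": round(self.mw_kda, 3),
            "pI": round(self.pI, 2),
            "instability_index": round(self.instability_index, 2),
            "stability_class": self.stability_class,
            "aliphatic_index": round(self.aliphatic_index, 2),
            "gravy": round(self.gravy, 3),
            "n_negative_asp_glu": self.n_negative,
            "n_positive_arg_lys": self.n_positive,
            "half_life": self.half_life,
        }


def compute_properties(seq) -> PropertyReport:
    """Full physicochemical panel for one sequence.

    Accepts an :class:`AminoAcidSequence` or a plain string; the alphabet is
    validated either way.
    """
    if not isinstance(seq, AminoAcidSequence):
        seq = AminoAcidSequence(id="seq", residues=str(seq))
    s = seq.residues
    pa = ProteinAnalysis(s)
    ii = pa.instability_index()
    return PropertyReport(
        sequence_id=seq.id,
        length=len(s),
        mw_da=pa.molecular_weight(),
        pI=isoelectric_point(s),
        instability_index=ii,
        stability_class="stable" if ii < STABILITY_THRESHOLD else "unstable",
        aliphatic_index=aliphatic_index(s),
        gravy=pa.gravy(),
        n_negative=s.count("D") + s.count("E"),
        n_positive=s.count("R") + s.count("K"),
        half_life=half_life(s),
    )
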