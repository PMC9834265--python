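"""End-to-end orchestration of the affinity-maturation protocol.

One config drives the whole chain: interface contacts -> key residues (or
an explicit factor list) -> orthogonal design -> binding-energy responses
(packaged/user run table, or the synthetic surrogate model) -> S/N main
effects -> proposed optimized variants -> per-variant physicochemical QC.
Every stage logs its parameters; outputs are deterministic given the
config and seed, and ``report.md`` records input hashes and versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .contacts import DEFAULT_CUTOFF, DEFAULT_RADIUS, residue_contact_table, select_key_residues
from .mutagenesis import write_fasta
from .seqprops import compute_properties
from .structures import parse_structure
from .synthetic import make_base_sequence, make_energy_model, score_design
from .taguchi import (
    DEFAULT_TIE_TOL,
    DesignTable,
    FactorSpec,
    attach_levels,
    build_orthogonal_array,
    load_reference_design,
    main_effects,
    paper_factors,
    propose_variants,
    summarize_design,
)

__all__ = ["PipelineConfig", "SyntheticSpec", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


class FactorConfig(BaseModel):
    position: int = Field(gt=0)
    levels: list[str] = Field(min_length=2)


class SyntheticSpec(BaseModel):
    effect_scale: float = Field(default=30.0, ge=0)
    interaction_scale: float = Field(default=0.0, ge=0)
    noise_sigma: float = Field(default=0.0, ge=0)
    beta0: float = Field(default=-700.0, lt=0)


class PipelineConfig(BaseModel):
    """Single source of truth for one pipeline run."""

    pdb: Path | None = None
    group_a: list[str] = Field(default_factory=lambda: ["A"])
    group_b: list[str] = Field(default_factory=lambda: ["B"])
    metric: Literal["min-atom", "vdw-gap"] = "min-atom"
    cutoff: float = DEFAULT_CUTOFF
    radius: float = DEFAULT_RADIUS

    fasta: Path | None = None  # base nanobody sequence; stand-in when omitted
    design_csv: Path | None = None  # run table with responses (scoring="table")
    scoring: Literal["table", "synthetic"] = "table"
    synthetic: SyntheticSpec = SyntheticSpec()

    factors: list[FactorConfig] | None = None  # explicit factor list bypasses contacts
    tie_tol: float = Field(default=DEFAULT_TIE_TOL, ge=0)
    reference_energy: float | None = None
    proposal_cap: int = 64
    seed: int = 0
    outdir: Path = Path("nanodoe_out")

    @field_validator("cutoff", "radius")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.model_validate(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("contacts")
def _contacts_stage(cfg: PipelineConfig, outdir: Path, hashes: dict):
    text = cfg.pdb.read_text()
    hashes[str(cfg.pdb)] = _sha256(cfg.pdb)
    structure = parse_structure(text)
    table = residue_contact_table(
        structure, set(cfg.group_a), set(cfg.group_b), metric=cfg.metric, radius=cfg.radius
    )
    key = select_key_residues(table, cfg.cutoff)
    table.to_frame().to_csv(outdir / "contacts.csv", index=False, float_format="%.6f")
    logger.info("contacts: %d records, %d key residues under %.2f Å (%s)",
                len(table), len(key), cfg.cutoff, cfg.metric)
    return table, key


@_stage("design")
def _design_stage(cfg: PipelineConfig, factors: list[FactorSpec], hashes: dict) -> DesignTable:
    if cfg.scoring == "table":
        if cfg.design_csv is not None:
            import pandas as pd

            hashes[str(cfg.design_csv)] = _sha256(cfg.design_csv)
            design = DesignTable.from_frame(pd.read_csv(cfg.design_csv), factors=factors)
            design.require_responses()
            return design
        logger.info("design: no design_csv given; using the packaged reference run table")
        return load_reference_design()
    n_levels = len(factors[0].levels)
    array = build_orthogonal_array(n_levels=n_levels, n_factors=len(factors))
    design = attach_levels(array, factors)
    model = make_energy_model(
        cfg.seed,
        effect_scale=cfg.synthetic.effect_scale,
        interaction_scale=cfg.synthetic.interaction_scale,
        noise_sigma=cfg.synthetic.noise_sigma,
        beta0=cfg.synthetic.beta0,
        positions=[f.position for f in factors],
        levels=factors[0].levels,
    )
    design.responses = score_design(model, design)
    logger.info("design: scored %d runs with the synthetic surrogate (seed %d)",
                design.n_runs, cfg.seed)
    return design


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full protocol; returns the report bundle as a dict.

    Writes design.csv, effects.json, variants.fasta, properties.json and
    report.md (plus contacts.csv when a PDB is configured) to
    ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashes: dict[str, str] = {}

    key_residues = None
    if cfg.pdb is not None:
        _, key_residues = _contacts_stage(cfg, outdir, hashes)
    elif cfg.factors is None:
        logger.info("contacts: skipped (no PDB); using the reference factor set")

    if cfg.factors is not None:
        factors = [FactorSpec(f.position, tuple(f.levels)) for f in cfg.factors]
    else:
        factors = paper_factors()

    design = _design_stage(cfg, factors, hashes)
    design.to_frame().to_csv(outdir / "design.csv", index=False, float_format="%.4f")

    try:
        effects = main_effects(design, tie_tol=cfg.tie_tol)
        summary = summarize_design(design, reference_energy=cfg.reference_energy)
        assignments = propose_variants(effects, cap=cfg.proposal_cap)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'analysis' failed: {exc}") from exc

    effects_doc = effects.to_dict()
    effects_doc["best_run"] = summary.best_run
    effects_doc["best_energy_kcal_mol"] = summary.best_energy
    if summary.n_below_reference is not None:
        effects_doc["n_runs_below_reference"] = summary.n_below_reference
    (outdir / "effects.json").write_text(json.dumps(effects_doc, indent=2, sort_keys=True) + "\n")

    if cfg.fasta is not None:
        from .mutagenesis import read_fasta

        hashes[str(cfg.fasta)] = _sha256(Path(cfg.fasta))
        base = read_fasta(cfg.fasta)[0]
    else:
        base = make_base_sequence()
        logger.info("variants: no FASTA given; using the synthetic stand-in sequence")

    try:
        variants = propose_variants(effects, base, cap=cfg.proposal_cap)
        write_fasta(variants, outdir / "variants.fasta")
        reports = [compute_properties(v) for v in variants]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'variants' failed: {exc}") from exc
    (outdir / "properties.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=2, sort_keys=True) + "\n"
    )

    bundle = {
        "version": __version__,
        "seed": cfg.seed,
        "input_hashes": hashes,
        "key_residues": [str(r) for r in key_residues] if key_residues is not None else None,
        "factors": {f.position: list(f.levels) for f in factors},
        "effects": effects_doc,
        "proposed_assignments": [{str(k): v for k, v in a.items()} for a in assignments],
        "variant_ids": [v.id for v in variants],
        "properties": [r.to_dict() for r in reports],
    }
    _write_report(outdir / "report.md", cfg, bundle)
    return bundle


def _write_report(path: Path, cfg: PipelineConfig, bundle: dict) -> None:
    lines = [
        "# nanodoe pipeline report",
        "",
        f"- package version: {bundle['version']}",
        f"- seed: {cfg.seed}",
        f"- scoring: {cfg.scoring}  |  metric: {cfg.metric}  |  cutoff: {cfg.cutoff} Å"
        f"  |  tie_tol: {cfg.tie_tol} dB",
        "",
        "## Inputs",
    ]
    if bundle["input_hashes"]:
        lines += [f"- `{p}` sha256 `{h}`" for p, h in sorted(bundle["input_hashes"].items())]
    else:
        lines.append("- no external inputs (synthetic/packaged data only)")
    if bundle["key_residues"] is not None:
        lines += ["", "## Key residues (contact analysis)",
                  ", ".join(bundle["key_residues"]) or "(none under cutoff)"]
    eff = bundle["effects"]
    lines += ["", "## Main effects", f"- best run: {eff['best_run']} "
              f"({eff['best_energy_kcal_mol']:+.1f} kcal/mol)"]
    if "n_runs_below_reference" in eff:
        lines.append(f"- runs beating the reference energy: {eff['n_runs_below_reference']}")
    for pos, levels in eff["selected"].items():
        lines.append(f"- position {pos}: selected {', '.join(levels)}")
    lines += ["", "## Proposed variants"]
    for a, vid in zip(bundle["proposed_assignments"], bundle["variant_ids"]):
        combo = ", ".join(f"{p}:{aa}" for p, aa in a.items())
        lines.append(f"- `{vid}` — {combo}")
    lines += ["", "## Variant properties"]
    for rep in bundle["properties"]:
        lines.append(
            f"- `{rep['sequence_id']}`: MW {rep['mw_kda']:.3f} kDa, pI {rep['pI']:.2f}, "
            f"II {rep['instability_index']:.2f} ({rep['stability_class']}), "
            f"GRAVY {rep['gravy']:+.3f}, charges +{rep['n_positive_arg_lys']}/-{rep['n_negative_asp_glu']}"
        )
    path.write_text("\n".join(lines) + "\n")
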