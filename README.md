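# nanodoe

In-silico affinity maturation of nanobodies by design of experiments.

Engineering a single-domain antibody (nanobody, VHH) for tighter antigen
binding means choosing better amino acids at the handful of positions that
actually touch the antigen. With 6 candidate positions and 5 candidate
residues each, the mutational space holds 5⁶ = 15,625 variants — far more
than any docking campaign wants to score. `nanodoe` implements the
DOE-guided alternative for that screen, developed around an anti-CD20
nanobody design study:

1. **Interface contacts** — parse a docked nanobody–antigen pose (PDB) and
   compute per-residue contact distances (minimum atom-pair distance, or a
   van-der-Waals surface gap). Residues with a contact distance strictly
   below 2.2 Å are the *key residues* eligible for mutation.
2. **Taguchi orthogonal design** — build the L25(5⁶) orthogonal array by
   the cyclic Latin-square construction: every column carries each level 5
   times and every ordered pair of columns carries every ordered level
   pair exactly once, so 25 runs estimate all six main effects without
   confounding.
3. **Signal-to-noise main effects** — score each run (docked binding
   energy *E*, kcal/mol, supplied as a table or by the built-in synthetic
   surrogate) and analyse with the larger-the-better Taguchi statistic on
   y = |E|:  S/N = −10·log₁₀(mean(1/y²)) dB.  Per factor, the level with
   the highest mean S/N wins; near-ties within a dB tolerance are all
   retained.
4. **Variant proposal** — the Cartesian product of selected levels gives
   the optimized variant(s); point mutations are applied to the nanobody
   sequence with wild-type validation and CDR annotation.
5. **Physicochemical QC** — ProtParam-style panel per variant: MW,
   theoretical pI (Bjellqvist pKa, bisection), instability index,
   aliphatic index, GRAVY, charge tallies, N-end-rule half-life.
6. **Trajectory metrics** — Kabsch-superposed RMSD and per-residue RMSF
   over multi-model PDB coordinates, for stability comparison of variants
   after simulation.

A synthetic-data module generates every input the pipeline needs — an
additive per-position energy model with optional pairwise interactions and
Gaussian noise, toy complexes with planted interface distances, a stand-in
VHH sequence, and trajectories with planted per-residue fluctuations — so
the whole protocol is testable offline. The packaged 25-run table of the
anti-CD20 study (with its published binding energies) ships as a fixture.

## Worked example

```python
import nanodoe as nd

design = nd.load_reference_design()          # the packaged 25-run table
effects = nd.main_effects(design)            # S/N main effects
for pos, levels in effects.selected.items():
    print(f"position {pos}: best {'/'.join(levels)}"
          f"  (delta {effects.deltas[pos]:.3f} dB, rank {effects.ranks[pos]})")
summary = nd.summarize_design(design, reference_energy=-745.6)
print(f"best run: {summary.best_run} at {summary.best_energy:+.0f} kcal/mol; "
      f"{summary.n_below_reference} run(s) beat the original")
for variant in nd.propose_variants(effects, nd.make_base_sequence()):
    report = nd.compute_properties(variant)
    print(f"{variant.id}: MW {report.mw_kda:.2f} kDa, pI {report.pI:.2f}, "
          f"II {report.instability_index:.2f} ({report.stability_class}), "
          f"GRAVY {report.gravy:+.3f}")
```

prints

```
position 27: best Phe  (delta 0.233 dB, rank 6)
position 28: best Trp/Tyr  (delta 0.234 dB, rank 5)
position 29: best Tyr  (delta 0.486 dB, rank 3)
position 31: best Trp  (delta 0.592 dB, rank 2)
position 99: best Phe  (delta 0.380 dB, rank 4)
position 100: best His  (delta 0.729 dB, rank 1)
best run: 9 at -791 kcal/mol; 2 run(s) beat the original
synthetic-nb-standin|S27F+T28W+F29Y+I31W+D99F+N100H: MW 13.07 kDa, pI 8.59, II 30.48 (stable), GRAVY -0.430
synthetic-nb-standin|S27F+T28Y+F29Y+I31W+D99F+N100H: MW 13.05 kDa, pI 8.57, II 34.26 (stable), GRAVY -0.434
```

Five positions get a unique best residue; position 28 is a genuine
near-tie (0.003 dB) between Trp and Tyr, so two optimized variants are
proposed — Phe27/Trp28/Tyr29/Trp31/Phe99/His100 and its Tyr28 sibling.
The property panel shows both variants are nanobody-sized (~13 kDa),
mildly basic, predicted stable (instability index < 40) and hydrophilic
(negative GRAVY). The sequences here use the synthetic stand-in scaffold;
supply your own FASTA to mutate a real nanobody.

The same analysis is available from a shell:

```sh
nanodoe analyze --design design.csv --reference-energy -745.6 --out effects.json
nanodoe propose --effects effects.json --fasta nb.fasta --out variants.fasta
nanodoe run --config config.json          # the full pipeline from one config
```

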