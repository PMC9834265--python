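# Methods

## The screening problem and the orthogonal design

The package addresses in-silico affinity maturation of a nanobody against
its antigen (the reference application is an anti-CD20 VHH). Six interface
positions (27, 28, 29, 31, 99, 100 in sequential author numbering) are
each allowed one of five loop-favourable residues (Trp, Phe, His, Asp,
Tyr), a space of 5⁶ = 15,625 variants. Instead of scoring all of them, an
L25(5⁶) Taguchi orthogonal array selects 25 variants such that each
factor's five levels each appear in exactly five runs, and every ordered
pair of levels appears exactly once for every pair of factors.

The array is built by the cyclic Latin-square construction for prime level
counts n: runs are indexed by (i, j) ∈ {1..n}², column 1 = i, column 2 =
j, and column m ≥ 3 = ((m−2)(i−1) + (j−1)) mod n + 1. Primality makes the
m ≥ 3 columns mutually orthogonal Latin squares, so up to n+1 factors fit.
Many other valid L25 arrays exist; this construction with this column
order is the one that reproduces the packaged reference design row for
row, and it is the only array the package emits. `verify_orthogonality`
checks the defining pair-count property exhaustively rather than trusting
the construction.

## Response statistic and selection

Responses are binding energies E in kcal/mol — negative, lower is better,
one docking evaluation per run (replicates are supported in the S/N but
the reference table has none). Because "lower energy" means "larger
magnitude", the analysis applies the Taguchi larger-the-better statistic
to y = |E|:

    S/N = −10 log₁₀( (1/k) Σ 1/y² )  [dB],

which for a single replicate is 20 log₁₀ y. Responses must be nonzero and
uniformly signed for |E| to be order-faithful; `attach_levels` enforces
this. The main effect m_{f,l} is the mean S/N over the runs where factor f
carries level l; column balance makes these means unconfounded, and for a
noiseless additive response the per-factor argmax of m_{f,l} is exactly
the per-factor optimum of the full variant space (asserted, not sampled,
in the tests).

Selection keeps every level within `tie_tol` of the factor's best mean.
On the packaged reference energies the closest near-tie is 0.0026 dB (at
position 28, a genuine two-way recommendation) while the next-smallest gap
anywhere is 0.0444 dB (position 27); the default `tie_tol` = 0.02 dB sits
between the two, so real ties survive and distinct effects are never
merged. Proposals are the Cartesian product of selected levels, capped
(default 64) to keep a sloppy tolerance from exploding the candidate list;
ordering is deterministic (factor order, then declared level order).
Best-run ties break to the lowest run index.

## Contact analysis

Key residues are found from a docked pose: for every nanobody residue, the
minimum over all atom pairs of the distance to each antigen residue.
Two metrics are offered. `min-atom` is the Euclidean centre-centre
minimum (non-negative, rigid-motion invariant). `vdw-gap` subtracts the
two atoms' Bondi van der Waals radii and may be negative for
interpenetrating atoms — docking engines that print sub-Ångström "contact
distances" are reporting a quantity of this kind, which a centre distance
cannot produce; offering both reproduces the procedure without guessing
any engine's internal definition. The default is `min-atom`. Unknown
elements fall back to a 1.70 Å radius with a logged warning.

The key-residue rule is strict: minimum distance < cutoff (default
2.2 Å), under whichever metric built the table. A reporting radius
(default 4.0 Å) truncates the table for readability only; it never alters
a reported minimum. Hydrogens are used if present in the file and never
added, so results are deterministic on the input. Author residue
numbering with insertion codes is preserved exactly; waters are dropped,
alternate locations keep the first occurrence, and non-standard residues
(e.g. an NMA C-terminal cap) are kept as contact partners.

## Mutagenesis and sequence QC

Mutations are substitutions only, in plain sequential 1-based numbering
(configurable offset); no Kabat/IMGT renumbering, no indels. Each
mutation's stated wild type is validated against the sequence, making
mutation lists self-checking. CDR annotation uses the study's sequential
ranges (CDR1 26–33, CDR2 51–57, CDR3 96–108).

The property panel follows the ProtParam conventions: average (not
monoisotopic) masses; GRAVY as mean Kyte–Doolittle hydropathy; the
Guruprasad dipeptide instability index with < 40 classified stable (MW,
GRAVY and the instability index delegate to Biopython's ProtParam, which
implements the same published tables); the aliphatic index
X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu)) in mole percent; and the
N-end-rule half-life lookup on the N-terminal residue, reported verbatim
for the three standard contexts. The theoretical pI solves Q(pH) = 0 by
bisection on [0, 14], where Q sums Henderson–Hasselbalch group fractions
over the termini and the D, E, C, Y, H, K, R side chains with the
Bjellqvist pKa set, including its residue-specific terminal adjustments
(e.g. an N-terminal Pro titrates at 8.36, not 7.5). Q is strictly
decreasing in pH, so the root is unique; the tests cross-check the
bisection against a 10⁻⁴-step grid scan of Q and against Biopython's
independent implementation. Cysteines are treated as reduced and
titratable; disulfides are not modelled.

Note on half-life lookups: the published N-end-rule table gives 1.1 h
(mammalian reticulocytes, in vitro) for an N-terminal Asp; reports exist
that quote 11.1 h for an Asp-initial nanobody. The package implements the
published table as-is.

## Synthetic data: what it emulates and what it does not

The surrogate energy model is E(v) = β₀ + Σ_f β_f(level) + sparse pairwise
terms + Gaussian noise, with β₀ = −700 kcal/mol and per-level effects
uniform on ±30 kcal/mol by default, chosen to mimic the reference table's
range (−650 to −791). Construction enforces that every noiseless
design-reachable energy stays strictly negative. All generators are pure
functions of their seeds (NumPy `SeedSequence` streams; replicate
sub-streams derived deterministically).

`recovery_experiment` is the package's validation of the DOE logic
itself: per replicate it perturbs the 25 design responses with noise,
takes each factor's top level by mean S/N, and compares with the
brute-force enumeration of the noiseless model over all variants. With
zero noise and no interactions, recovery is exact — the core correctness
theorem of the balanced design. Under gross noise (σ ≫ effect scale)
per-factor recovery approaches the chance rate 1/5. The harness computes
S/N from |E| directly rather than through the design table's sign gate,
because in the gross-noise regime a Gaussian excursion can push a
simulated energy across zero and that regime is exactly what is being
measured. The surrogate is statistical only: it does not model force
fields, rotamers, or pose geometry, so passing recovery tests validates
the screening arithmetic, not docking accuracy.

Toy complexes plant exact nearest-atom distances by axis-aligned
placement; PDB coordinates carry three decimals, so planted values with
≤ 3 decimals round-trip to 10⁻⁶ Å. Decoy residues sit far outside the
reporting radius. Synthetic trajectories put one Cα per residue on a
coarse helix (a collinear scaffold would leave the superposition's
rotation degenerate) and displace each residue i.i.d. per frame with a
planted per-axis σ; the expected RMSF is σ√3 less the small fraction a
rigid fit absorbs (a few percent at 40 residues).

The stand-in nanobody sequence is synthetic: a generic VHH-like scaffold
carrying the documented wild types (Ser27, Thr28, Phe29, Ile31, Asp99,
Asn100). The study's actual sequence is deposited under a patent
accession and is not redistributed, so the published property panel
values (MW ≈ 13.4 kDa, pI 9.26, II 24.69, GRAVY −0.395, 8/12 charges) are
not assertable here; the property operations are instead validated by
construction-independent oracles (grid-scan pI, MW additivity, tallies).

## Trajectory metrics

RMSD uses centroid removal plus the optimal rotation from scipy's
reflection-corrected SVD solver; RMSF aligns all frames to the mean
structure iteratively (two passes, order-invariant initialisation from the
plain coordinate mean) and reports each selected atom's RMS deviation
from its time-average position. Default selection is Cα for both. Input
is multi-model PDB only; binary trajectory formats are out of scope and
can be converted upstream. Exact closed forms used in testing: an
alignment-neutral antipodal ±d displacement gives RMSD = √(Σd²/N), and a
single displaced atom gives d·√(N−1)/N — strictly below the naive d/√N
because optimal superposition re-centres. Published plateau values from
any particular simulation are not reproduction targets; the trajectories
behind them are not distributed.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated or
packaged data: 25-run designs, ≤ 500-atom toy complexes, 15,625-variant
enumerations (vectorised, < 1 s), 500-replicate recovery experiments, and
1,000-frame synthetic trajectories. Pipeline runs are bit-reproducible
given a config and seed; reports record input hashes and the package
version.
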