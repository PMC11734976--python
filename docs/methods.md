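# Methods

This note records the models, conventions, parameter choices and known
limitations behind each stage of the funnel.

## Descriptors and drug-likeness rules

All descriptors are computed with RDKit on the canonicalized structure, so
canonical-SMILES-equal inputs yield bit-identical descriptor vectors. Molecular
weight is the average (isotope-abundance-weighted) mass; TPSA is the
Ertl topological polar surface area (Å²); rotatable bonds use RDKit's default
(amide C–N excluded); H-bond donors/acceptors are the strict
`CalcNumHBD`/`CalcNumHBA` counts. Both the `clogp` and `wlogp` fields are
backed by the Wildman–Crippen atomic-contribution estimator — the single logP
model RDKit provides — so rule sets written against different logP estimators
see the same number here. That mainly affects Ghose's lower logP bound, which
in practice triggers on genuinely hydrophilic structures either way.

Rule thresholds (all configurable only by editing the rule table; they are the
rules' published forms):

| rule    | conditions |
|---------|------------|
| Lipinski | MW ≤ 500, cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10 — **passes with ≤ 1 violation** (classical allowance; strict mode available) |
| Veber   | RotB ≤ 10 and TPSA ≤ 140 |
| Egan    | WLOGP ≤ 5.88 and TPSA ≤ 131.6 |
| Muegge  | 200 ≤ MW ≤ 600, −2 ≤ cLogP ≤ 5, TPSA ≤ 150, rings ≤ 7, C > 4, heteroatoms > 1, RotB ≤ 15, HBD ≤ 5, HBA ≤ 10 |
| Ghose   | 160 ≤ MW ≤ 480, −0.4 ≤ WLOGP ≤ 5.6, 40 ≤ MR ≤ 130, 20 ≤ atoms ≤ 70 |
| Varma   | MW ≤ 500, TPSA ≤ 125, RotB ≤ 12, HBD+HBA ≤ 9 |
| GSK 4/400 | MW ≤ 400 and cLogP ≤ 4 |
| Pfizer 3/75 | fails iff cLogP > 3 **and** TPSA < 75 (toxicity-risk rule) |

The Varma oral-bioavailability criteria circulate with slightly different
cutoffs; the set above is the one used here and is stated rather than assumed.
PAINS screening runs RDKit's FilterCatalog families A+B+C and reports every
matching pattern name. The cascade's survivor set is an intersection and hence
independent of rule order; only the per-stage counts depend on it. Duplicate
removal is canonical-SMILES identity, first id wins.

## ADME and toxicity gates

The package consumes prediction tables, it does not predict. A record passes
ADME iff all three solubility classes (ESOL, Ali, Silicos-IT) are at least
"Soluble" ("Highly soluble" — emitted by some SwissADME versions above "Very
soluble" — also passes, the criterion being a lower bound), GI absorption is
High, BBB permeant No, P-gp substrate No, and all five CYP inhibition flags
(1A2, 2C19, 2C9, 2D6, 3A4) No. A record passes toxicity iff mutagenic,
tumorigenic and reproductive risks are "none" and irritant risk is at most
"low" — the irritant criterion is deliberately laxer because the screening
demand is *low* irritant potential versus *non*-mutagenicity. Boolean-only
toxicity dialects map True→high, False→none. Headers are matched
case-insensitively through an alias table; out-of-vocabulary cells reject the
row (logged), never coerce.

## Consensus ranking

Within each program's column, competition ("1224") ranking: rank = 1 + number
of strictly better scores; tied scores share the minimal rank of their block.
This is the convention the published rank table uses (two compounds tied at
the 24th-best AutoDockTools score both carry 24 and no 25 appears). All seven
bundled program columns are lower-is-better, including the PLANTS and rDock
native scores; an orientation flag per program handles the general case.
Mean-rank ties in the final ordering are broken by best single-program rank,
then compound id, purely for determinism — and top-N selection never splits an
exact tie block, so a request for n may return more than n (it does for the
bundled campaign at n = 5, not at n = 6). The score-threshold filter uses
inclusive ≤; its cutoff is a campaign decision and is a required config value,
not a default.

## Trajectory metrics

Coordinates are Å throughout; SASA totals are reported in nm² (1 nm² =
100 Å²). Superposition is the Kabsch algorithm: SVD of the weighted
covariance, reflection branch corrected to det = +1; collinear selections are
rejected as degenerate. RMSD fits each frame to the reference on the fit
selection, then evaluates on the calc selection (defaults: all atoms; Cα-fit /
backbone-calc is a caller choice — which atom set published campaigns use is
rarely stated). RMSF superposes all frames to the mean structure with one
re-fit iteration; residue aggregation averages member atoms.

Shrake–Rupley SASA uses a 960-point golden-spiral sphere per atom at radius
r_vdw + probe (probe 1.4 Å, Bondi radii keyed by element; an untabulated
element is an error, never a silent default). Coordinates are first rotated
into a deterministically-signed principal-axes frame, which makes the
quadrature exactly invariant under rigid motion of the input — without it the
fixed point sphere leaves an orientation-dependent quadrature wobble of a few
tenths of a percent. Isolated-sphere error at 960 points is < 1 %.

Hydrogen bonds are D–H···A triples with D···A ≤ 3.5 Å and deviation from
linearity ≤ 30°; a heavy-atom-only mode counts D···A distances for
hydrogen-stripped trajectories. Donor (D, H) pairs are auto-detected as
hydrogens within 1.25 Å of an N/O in the first frame; every N/O is a potential
acceptor. Residue contacts are any-heavy-atom distance ≤ 4.5 Å to the ligand;
occupancy = 100 × fraction of frames; ionic contacts use charged-group
centroids at ≤ 5.0 Å. These cutoffs are the community-standard geometric
criteria; all are parameters.

PCA superposes frames to the mean structure, then takes the SVD of the
centered F × 3N coordinate matrix (equivalent to eigendecomposing the 3N × 3N
covariance without forming it); eigenvalues are Å² and their sum equals the
total variance to machine precision. The free-energy landscape is the inverse
Boltzmann transform ΔG = −k_B T ln(P / P_max) of the 2-D (PC1, PC2) histogram
(default 50 × 50 bins, T = 300 K, in k_BT or kJ/mol); the modal bin is exactly
0, empty bins are masked and exported at the maximum finite ΔG. Water-mediated
and π-stacking interaction channels are out of scope; the implementable
channels are distance contact, hydrogen bond, and ionic.

## Synthetic data: what it emulates and what it does not

The generators exist to make every stage testable against planted truth; they
are study-condition definitions, not tuning knobs.

**Molecules** come from a curated template pool — real drug-like scaffolds
with small substituent variations — rather than random graph generation, so
every structure is valid chemistry. "Benign" templates pass all eight rules
and PAINS; each violator class is built to fail its target rule when
descriptors are recomputed, and every candidate is verified against its class
predicate at generation time (a substituent that flips a verdict is
discarded; an exhausted pool raises an unsatisfiable-plan error, as do bad
fractions or planted counts exceeding n). Because the rule sets share
descriptor bounds, a violator can incidentally fail overlapping rules — any
double Lipinski breach necessarily breaks Muegge's matching bounds, and any
TPSA-driven Egan breach (> 131.6 Å²) also exceeds Varma's 125 Å² — so the
truth table records the *computed* verdict of every rule, and the planted
guarantee is one-directional: flagged molecules genuinely violate their target
rule. The library is small-pool (≈ 100 benign variants); it emulates rule
logic, not the chemical diversity of a real 9,497-compound library.

**Score tables** plant a true ranking: `score = base − (n − rank + 1) +
Normal(0, sd_p)`, lower-is-better with adjacent true ranks one score unit
apart. Zero noise makes every program's competition ranking equal the truth;
per-program noise lets consensus demonstrably beat single programs (Spearman ρ
of the mean-rank ordering exceeds any individual program's, on average). Real
docking scores have neither uniform spacing nor independent Gaussian errors.

**ADME/tox tables** plant exact pass counts: round(n·f) records satisfy every
criterion in both tables; each failing record breaks ≥ 1 named criterion in
*each* table, so the ADME gate and the tox gate independently retain exactly
round(n·f) — this is what lets a 50 → 25 toxicity step be reproduced exactly.
Real prediction tables have correlated failures.

**Trajectories** are harmonic: frame t = R_t(x_ref + ε_t) + d_t with ε
isotropic per-coordinate Normal(0, σ_i²). Analytic consequences used in tests:
RMSF_i → σ_i√3 (at 10⁴ frames, sampling error ≈ 0.3 % and the 6 rigid degrees
of freedom absorbed by superposition bias the mean by ≈ 3/(3N) — ≈ 1 % on a
100-atom selection, within the 2 % recovery band); rigid motion must be
invisible after superposition; σ = 0 reproduces the reference. The toy
receptor is a Cα-trace ideal helix with the CDK4/6 active-site residue
numbering (ILE19, TYR24, ALA41, GLU99, GLN103, ASP104, ALA162) plus a 5-atom
heteroatom ligand parked at a chosen offset; it has no force-field realism, no
secondary-structure transitions, no waters. Passing tests therefore establish
the *metrics*' correctness, not any claim about real MD behaviour; published
trajectory summaries (e.g. a mean RMSD of a specific complex) require the
original 500 ns trajectories, which are not distributable, and are replaced by
the analytic property checks above.

PDB round-trips are exact to 5 × 10⁻⁴ Å (the format's 3-decimal precision);
coordinates are pre-rounded before the float32 cast so the cast can never push
a value across a rounding boundary.

## Problem sizes

Defaults were chosen so the whole suite runs in well under a minute on one
CPU: cascade libraries of 10–40 molecules, 25 × 7 score tables with 200
Monte-Carlo replicates, 10⁴-frame / 100-atom trajectories for RMSF recovery,
960-point SASA spheres with a 5 × 10⁵-point Monte-Carlo surface oracle,
150 000-sample free-energy wells. All generator randomness flows from one
explicit seed per call; there is no global RNG state.

## Known limitations

- No 3D conformer descriptors, pKa/charge-state enumeration, or docking/MD
  execution — the package consumes scores and trajectories, it does not create
  them.
- Single logP estimator (see above).
- Contact channels omit water-mediated bridges and π-stacking.
- mm-PBSA binding free energies are out of scope.
- The synthetic molecule pool cannot serve plans needing more than ~100 benign
  or ~15 per-rule violator structures; it fails loudly when exhausted.
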