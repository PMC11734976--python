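# mnp-funnel

A reusable, tested implementation of a marine-natural-product virtual-screening
funnel against CDK4/6 (cyclin-dependent kinases 4/6, cell-cycle regulators and
breast-cancer drug targets). Screening campaigns of this kind thread a compound
library through a cascade of cheap filters before anything expensive runs:

1. **Docking-score threshold** — keep initial hits with binding energy ≤ a
   stated cutoff (kcal/mol, lower = stronger).
2. **Drug-likeness cascade + PAINS** — eight descriptor rule sets (Lipinski,
   Veber, Egan, Muegge, Ghose, Varma, GSK 4/400, Pfizer 3/75) plus
   pan-assay-interference (PAINS) substructure alerts.
3. **ADME gate** — solubility class, GI absorption, blood–brain-barrier
   permeation, P-gp substrate and CYP-inhibition flags from SwissADME-style
   prediction tables.
4. **Toxicity gate** — mutagenic / tumorigenic / reproductive / irritant risk
   levels from DataWarrior-style tables.
5. **Consensus docking (Rank-by-Rank)** — per-program competition ranks
   averaged across docking programs; shortlist the lowest mean ranks.
6. **MD post-analysis** — RMSD, RMSF, radius of gyration, Shrake–Rupley SASA,
   hydrogen-bond counts, residue-contact timelines, PCA, and free-energy
   landscapes over multi-model PDB trajectories.

The core statistic is Rank-by-Rank consensus: for compound *i* and docking
programs *p* = 1…m, with r_ip the within-program competition rank
("1224" ranking — ties share the minimal rank of their block),

    mean_rank_i = (1/m) · Σ_p r_ip

and the shortlist is the n compounds with the smallest mean rank (tie blocks
are never split). Ranking makes heterogeneous score scales (AutoDock kcal/mol,
PLANTS or rDock native scores) commensurable and is invariant under any
strictly increasing rescaling of a program's scores.

The package ships the published 25-compound × 7-program CDK4/6 consensus
docking campaign as reference data, and a synthetic-data module that generates
every input class with known ground truth — molecule libraries with planted
rule violations, score tables with a planted true ranking, ADME/tox tables
with planted pass rates, and harmonic-fluctuation trajectories with known
per-atom variance — so every stage is testable without external downloads.

## Worked example

Consensus ranking of the bundled CDK4/6 campaign:

```sh
python -c "
from mnp_funnel.datasets import load_reference_scores
load_reference_scores().to_csv('docking.csv')"
mnp-funnel consensus --scores docking.csv --top 6 --out ranks.csv
```

```
consensus ordering (best first):
 * CMNPD7986        mean rank 2.857
 * CMNPD11585       mean rank 3.571
 * CMNPD14217       mean rank 5.143
 * 205813-99-6      mean rank 7.000
 * 223130-61-8      mean rank 7.571
 * CMNPD2744        mean rank 7.571
   CMNPD13472       mean rank 7.714
   ...
```

The six starred compounds — the best mean ranks over the seven docking
programs, with 223130-61-8 and CMNPD2744 exactly tied at 53/7 — are the MD
follow-up shortlist of the campaign. `ranks.csv` holds the full 25 × 7
competition-rank matrix plus the mean-rank column.

Drug-likeness filtering of a synthetic library with planted violations:

```python
from mnp_funnel.synthetic_data import gen_molecules
from mnp_funnel.chem_filters import write_smiles_file

records, truth = gen_molecules(
    40, {"lipinski": 0.1, "veber": 0.1, "gsk": 0.1, "pains": 0.1}, seed=1)
write_smiles_file(records, "lib.smi")
```

```sh
mnp-funnel filter --in lib.smi --out survivors.smi --report report.csv
```

```
lipinski       40 -> 36
veber          36 -> 31
egan           31 -> 31
muegge         31 -> 31
ghose          31 -> 31
varma          31 -> 31
gsk            31 -> 28
pfizer         28 -> 28
pains          28 -> 24
```

Each stage prints compounds in → out; the 24 survivors are exactly the 24
all-pass molecules the generator planted (the remaining 16 were planted to
violate Lipinski, Veber, GSK or PAINS; a violator can fall at an earlier
overlapping stage, but the final survivor set is order-independent).

A full funnel is one YAML config (`mnp-funnel run --config funnel.yaml`), with
one block per stage; `mnp-funnel traj --pdb complex.pdb --metrics
rmsd,rmsf,rg,sasa,contacts,pca,fel --active-site 19,24,41,99,103,104,162`
writes per-metric CSV series for a trajectory.

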