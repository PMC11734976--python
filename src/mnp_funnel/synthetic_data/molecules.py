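"""Synthetic molecule libraries with planted rule violations.

Builds SMILES libraries from a curated template pool — real drug-like
scaffolds with small substituent variations — rather than random graph
generation, so every emitted structure is valid chemistry and its rule
verdicts are guaranteed by construction.  Each template class targets
one drug-likeness rule (or the PAINS gate): "benign" templates pass all
eight rules and raise no PAINS alert; a violator class genuinely fails
its target rule when descriptors are recomputed.

Because the rule sets share descriptor bounds (e.g. any double Lipinski
breach also breaks Muegge's matching bounds), a violator may incidentally
fail overlapping rules; the returned truth table records the verdicts
actually computed for every rule, so it is always sound.
"""

from __future__ import annotations

import random
from typing import Mapping

import pandas as pd
from rdkit import Chem

from ..chem_filters import (
    RULES,
    MoleculeRecord,
    compute_descriptors,
    evaluate_rule,
    pains_screen,
)

__all__ = ["gen_molecules", "UnsatisfiablePlanError"]


class UnsatisfiablePlanError(ValueError):
    """The violation plan cannot be met (bad fractions or pool exhausted)."""


# Template pools.  ``{R}`` marks the substitution point; candidates are
# verified against their class predicate at generation time, so a
# substituent that flips a verdict is silently discarded.
_SUBSTITUENTS = ["", "C", "F", "Cl", "OC", "CC", "O", "N"]

_BENIGN_TEMPLATES = [
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1{R}",  # atenolol-like
    "CCN(CC)CC(=O)Nc1c(C)cc({R})cc1C",  # lidocaine-like
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1{R}",  # salbutamol-like
    "COCCc1ccc(OCC(O)CNC(C)C)cc1{R}",  # metoprolol-like
    "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC",  # trimethoprim
    "Cc1cc(NS(=O)(=O)c2ccc(N)cc2{R})no1",  # sulfonamide
    "CCN(CC)CCOC(=O)c1ccc(N)cc1{R}",  # procaine-like
    "CC(=O)Nc1ccc(OCCN2CCOCC2)cc1{R}",  # morpholino-acetanilide
    "CCOC(=O)c1ccc(NC(C)=O)cc1{R}",  # acet-benzocaine
    "NC(Cc1c[nH]c2ccccc12)C(=O)NCCO",  # tryptophan amide
    "O=C(NCCc1ccccc1{R})c1cccnc1",  # nicotinamide phenethyl
    "CCOc1ccc(NC(=O)CCN2CCCC2)cc1{R}",  # pyrrolidino-phenetidide
    "CC(=O)Nc1ccc(S(N)(=O)=O)cc1NC(C)=O",  # diacetamido-sulfonamide
    "CC(=O)Nc1ccc(S(=O)(=O)Nc2ccccn2)cc1NC(C)=O",
]

# one violator pool per rule; comments give the breached condition(s)
_VIOLATOR_TEMPLATES: dict[str, list[str]] = {
    # >=2 breaches needed to fail Lipinski's one-violation allowance:
    # MW>500 plus HBD>5 / HBA>10 (oligosaccharide) or MW>500 plus cLogP>5
    "lipinski": [
        "OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1OC1OC(CO)C(O)C(O)C1O",
        "COCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1OC1OC(CO)C(O)C(O)C1O",
        "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC",
        "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC",
        "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC",
        "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC",
        "OCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC",
        "OCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC",
    ],
    # 11-12 rotatable bonds: fails Veber's RotB<=10, inside Varma's <=12
    "veber": [
        "COCCCCCCCCCCC(=O)NC",
        "COCCCCCCCCCCC(=O)NCC",
        "COCCCCCCCCCC(=O)NCC",
        "COCCCCCCCCCCCC(=O)N",
        "CCOCCCCCCCCCC(=O)NC",
        "CCOCCCCCCCCCCC(=O)N",
        "COCCCCCCCCCCCC(=O)NC",
        "CCOCCCCCCCCCC(=O)NCC",
    ],
    # TPSA in (131.6, 140]: fails Egan, passes Veber/Muegge
    "egan": [
        "NS(=O)(=O)c1ccc(NC(=O)c2ccccc2C(N)=O)cc1{R}",
        "NS(=O)(=O)c1ccc(NC(=O)c2ccc(C(N)=O)cc2)cc1{R}",
    ],
    # MW<200 with drug-like everything else: fails only Muegge's MW>=200
    "muegge": [
        "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
        "CC(=O)Nc1ccc(OCCO)cc1",
        "CC(N)COc1c(C)cccc1C",
        "CC(=O)Nc1ccc(OCC)cc1",
        "CC(=O)Nc1ccc(OC)cc1C",
        "CC(=O)Nc1ccc(O)cc1OC",
        "OCC(O)COc1ccccc1C",
        "CNC(=O)c1ccccc1OCC",
    ],
    # WLOGP<-0.4 at MW>=200 (xanthines): fails only Ghose's logP floor
    "ghose": [
        "CCn1c(=O)c2c(ncn2C)n(C)c1=O",
        "Cn1c(=O)c2c(ncn2CC)n(C)c1=O",
        "OCCn1c(=O)c2c(ncn2C)n(C)c1=O",
        "CCn1c(=O)c2c(ncn2CC)n(C)c1=O",
        "OCCn1c(=O)c2c(ncn2CC)n(C)c1=O",
        "OCCn1c(=O)c2c(ncn2C)n(CC)c1=O",
        "Cn1c(=O)c2c(ncn2CCO)n(C)c1=O",
        "CCn1c(=O)c2c(ncn2C)n(CC)c1=O",
    ],
    # HBD+HBA>9 while each stays under its Lipinski cap
    "varma": [
        "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OCCOC",
        "COCCOc1cc(Cc2cnc(N)nc2N)cc(OC)c1OCC",
        "COc1cc(Cc2cnc(N)nc2N)cc(OCCOC)c1OC",
        "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OCCOCC",
        "CCOCCOc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC",
        "COCCOc1cc(Cc2cnc(N)nc2N)cc(OCC)c1OC",
    ],
    # MW in (400, 480]: fails GSK 4/400 only
    "gsk": [
        "COc1ccc(C(=O)NCCCN2CCN(c3ccccc3OC)CC2)cc1OC",
        "COc1ccc(C(=O)NCCCN2CCN(c3ccccc3OC)CC2)cc1OCC",
        "CCOc1ccc(C(=O)NCCCN2CCN(c3ccccc3OC)CC2)cc1OC",
        "COc1ccc(C(=O)NCCCCN2CCN(c3ccccc3OC)CC2)cc1OC",
        "COc1ccc(C(=O)NCCCN2CCN(c3ccccc3OCC)CC2)cc1OC",
        "CCOc1ccc(C(=O)NCCCCN2CCN(c3ccccc3OC)CC2)cc1OC",
    ],
    # cLogP in (3, 4] with TPSA<75: trips the 3/75 toxicity-risk rule only
    "pfizer": [
        "CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1",
        "CN(C)CCC(c1ccc(C)cc1)c1ccccn1",
        "CN(C)CCC(c1ccc(Br)cc1)c1ccccn1",
        "CN(C)CCC(c1cccc(Cl)c1)c1ccccn1",
        "CN(C)CCC(c1ccccc1Cl)c1ccccn1",
        "CN(C)CCC(c1ccc(Cl)cc1)c1cccnc1",
        "CN(C)CCC(c1ccc(C)cc1)c1cccnc1",
        "CN(C)CCC(c1cccc(Br)c1)c1ccccn1",
    ],
    # catechol amides: pass all eight rules, raise a PAINS alert
    "pains": [
        "Oc1ccc(CCNC(=O)CCCC)cc1O",
        "Oc1ccc(CCNC(=O)c2ccccc2)cc1O",
        "Oc1ccc(CCNC(=O)CCCCC)cc1O",
        "Oc1ccc(CCNC(=O)c2ccccc2C)cc1O",
        "Oc1ccc(CCNC(=O)CCCCCC)cc1O",
        "Oc1ccc(CCNC(=O)Cc2ccccc2)cc1O",
        "Oc1ccc(CCNC(=O)c2ccc(C)cc2)cc1O",
        "Oc1ccc(CCNC(=O)CCCCCCC)cc1O",
    ],
}

_PLAN_KEYS = tuple(RULES) + ("pains",)


def _expand(template: str) -> list[str]:
    if "{R}" not in template:
        return [template]
    out = []
    for sub in _SUBSTITUENTS:
        if sub:
            out.append(template.replace("{R}", sub))
        else:  # drop an empty substituent together with its parentheses
            out.append(template.replace("({R})", "").replace("{R}", ""))
    return out


def _class_ok(smiles: str, target: str | None) -> bool:
    """Does this SMILES satisfy its class predicate?"""
    try:
        desc = compute_descriptors(smiles)
        alerts = pains_screen(smiles).alerts
    except ValueError:
        return False
    verdicts = {r: evaluate_rule(desc, r).passed for r in RULES}
    if target is None:  # benign: pass everything
        return all(verdicts.values()) and not alerts
    if target == "pains":  # PAINS hit but rule-clean
        return bool(alerts) and all(verdicts.values())
    return not verdicts[target]


def _draw_pool(
    pool: list[str], target: str | None, count: int, rng: random.Random,
    used: set[str],
) -> list[str]:
    candidates = [smi for tpl in pool for smi in _expand(tpl)]
    rng.shuffle(candidates)
    picked: list[str] = []
    for smi in candidates:
        if len(picked) == count:
            break
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in used:
            continue
        if _class_ok(smi, target):
            picked.append(canonical)
            used.add(canonical)
    if len(picked) < count:
        label = target or "benign"
        raise UnsatisfiablePlanError(
            f"template pool for class {label!r} exhausted: "
            f"needed {count}, found {len(picked)} distinct structures"
        )
    return picked


def gen_molecules(
    n: int,
    violation_plan: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Generate n molecules with a planted per-rule violation plan.

    ``violation_plan`` maps a rule name (or ``"pains"``) to the fraction
    of the library that must fail it; ``round(n * fraction)`` molecules
    are planted per entry and the remainder are benign all-pass
    structures.  Fractions must lie in [0, 1] and the planted counts must
    not exceed n.

    Returns the molecule records (shuffled order) and a truth table with
    one row per molecule: the planted class, the computed verdict of
    every rule, the PAINS alert count, and a ``violated_rules`` summary
    column.  Identical arguments give byte-identical output.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    plan = dict(violation_plan or {})
    for key, frac in plan.items():
        if key not in _PLAN_KEYS:
            raise UnsatisfiablePlanError(f"unknown rule in plan: {key!r}")
        if not 0.0 <= frac <= 1.0:
            raise UnsatisfiablePlanError(
                f"fraction for {key!r} must be in [0, 1], got {frac}"
            )
    counts = {k: round(n * f) for k, f in plan.items() if round(n * f) > 0}
    n_planted = sum(counts.values())
    if n_planted > n:
        raise UnsatisfiablePlanError(
            f"planted counts {counts} sum to {n_planted} > n = {n}"
        )

    rng = random.Random(seed)
    used: set[str] = set()
    assignments: list[tuple[str, str]] = []  # (planted class, smiles)
    for rule in sorted(counts):
        for smi in _draw_pool(
            _VIOLATOR_TEMPLATES[rule], rule, counts[rule], rng, used
        ):
            assignments.append((rule, smi))
    for smi in _draw_pool(
        _BENIGN_TEMPLATES, None, n - n_planted, rng, used
    ):
        assignments.append(("benign", smi))
    rng.shuffle(assignments)

    records, rows = [], []
    for i, (planted, smi) in enumerate(assignments):
        mol_id = f"SYN{i:04d}"
        records.append(MoleculeRecord(id=mol_id, smiles=smi))
        desc = compute_descriptors(smi)
        verdicts = {r: evaluate_rule(desc, r).passed for r in RULES}
        alerts = pains_screen(smi).alerts
        violated = [r for r, ok in verdicts.items() if not ok]
        if alerts:
            violated.append("pains")
        rows.append(
            {
                "id": mol_id,
                "smiles": smi,
                "planted": planted,
                **{f"pass_{r}": ok for r, ok in verdicts.items()},
                "pains_alerts": len(alerts),
                "violated_rules": ";".join(violated),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["id", "smiles", "planted"]
        + [f"pass_{r}" for r in RULES]
        + ["pains_alerts", "violated_rules"],
    ).set_index("id")
    return records, truth
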