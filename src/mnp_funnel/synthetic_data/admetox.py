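"""Synthetic ADME and toxicity prediction tables with planted pass rates.

Emits tables in the dialects the parsers accept: a SwissADME-style CSV
(solubility classes from three models, GI absorption, BBB permeation,
Pgp substrate, five CYP inhibition flags) and a DataWarrior-style risk
table (mutagenic / tumorigenic / reproductive effective / irritant at
none / low / high).  Exactly ``round(n * pass_fraction)`` records pass
every criterion in *both* tables; each remaining record violates at
least one named criterion in each table, so the ADME gate and the tox
gate each retain exactly the planted count when run on the full set.
"""

from __future__ import annotations

import random

import pandas as pd

__all__ = ["gen_adme_tox_tables"]

_PASS_SOL = ["Soluble", "Very soluble", "Highly soluble"]
_FAIL_SOL = ["Insoluble", "Poorly soluble", "Moderately soluble"]

_ADME_COLUMNS = [
    "Molecule",
    "ESOL Class",
    "Ali Class",
    "Silicos-IT class",
    "GI absorption",
    "BBB permeant",
    "Pgp substrate",
    "CYP1A2 inhibitor",
    "CYP2C19 inhibitor",
    "CYP2C9 inhibitor",
    "CYP2D6 inhibitor",
    "CYP3A4 inhibitor",
]

_TOX_COLUMNS = [
    "Compound",
    "Mutagenic",
    "Tumorigenic",
    "Reproductive Effective",
    "Irritant",
]

# (column, failing value factory) choices for planting an ADME violation
_ADME_BREAKS = [
    ("ESOL Class", lambda rng: rng.choice(_FAIL_SOL)),
    ("Ali Class", lambda rng: rng.choice(_FAIL_SOL)),
    ("Silicos-IT class", lambda rng: rng.choice(_FAIL_SOL)),
    ("GI absorption", lambda rng: "Low"),
    ("BBB permeant", lambda rng: "Yes"),
    ("Pgp substrate", lambda rng: "Yes"),
    ("CYP1A2 inhibitor", lambda rng: "Yes"),
    ("CYP2C19 inhibitor", lambda rng: "Yes"),
    ("CYP2C9 inhibitor", lambda rng: "Yes"),
    ("CYP2D6 inhibitor", lambda rng: "Yes"),
    ("CYP3A4 inhibitor", lambda rng: "Yes"),
]

_TOX_BREAKS = [
    ("Mutagenic", lambda rng: rng.choice(["low", "high"])),
    ("Tumorigenic", lambda rng: rng.choice(["low", "high"])),
    ("Reproductive Effective", lambda rng: rng.choice(["low", "high"])),
    ("Irritant", lambda rng: "high"),
]


def _passing_adme_row(mol_id: str, rng: random.Random) -> dict:
    return {
        "Molecule": mol_id,
        "ESOL Class": rng.choice(_PASS_SOL),
        "Ali Class": rng.choice(_PASS_SOL),
        "Silicos-IT class": rng.choice(_PASS_SOL),
        "GI absorption": "High",
        "BBB permeant": "No",
        "Pgp substrate": "No",
        "CYP1A2 inhibitor": "No",
        "CYP2C19 inhibitor": "No",
        "CYP2C9 inhibitor": "No",
        "CYP2D6 inhibitor": "No",
        "CYP3A4 inhibitor": "No",
    }


def _passing_tox_row(mol_id: str, rng: random.Random) -> dict:
    return {
        "Compound": mol_id,
        "Mutagenic": "none",
        "Tumorigenic": "none",
        "Reproductive Effective": "none",
        "Irritant": rng.choice(["none", "low"]),
    }


def gen_adme_tox_tables(
    n: int, pass_fraction: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate paired ADME and tox tables over the same n compound ids.

    Returns ``(adme_table, tox_table, truth)`` where the truth table
    lists, per id, whether it was planted as passing and which columns
    were broken.  Identical arguments give identical output.
    """
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValueError("pass_fraction must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = random.Random(seed)
    n_pass = round(n * pass_fraction)
    passes = [True] * n_pass + [False] * (n - n_pass)
    rng.shuffle(passes)

    adme_rows, tox_rows, truth_rows = [], [], []
    for i, ok in enumerate(passes):
        mol_id = f"SYN{i:04d}"
        adme = _passing_adme_row(mol_id, rng)
        tox = _passing_tox_row(mol_id, rng)
        broken: list[str] = []
        if not ok:
            # break >=1 criterion in each table
            for col, make in rng.sample(
                _ADME_BREAKS, rng.randint(1, 2)
            ):
                adme[col] = make(rng)
                broken.append(col)
            for col, make in rng.sample(_TOX_BREAKS, rng.randint(1, 2)):
                tox[col] = make(rng)
                broken.append(col)
        adme_rows.append(adme)
        tox_rows.append(tox)
        truth_rows.append(
            {
                "id": mol_id,
                "planted_pass": ok,
                "violated_rules": ";".join(sorted(set(broken))),
            }
        )
    adme_table = pd.DataFrame(adme_rows, columns=_ADME_COLUMNS)
    tox_table = pd.DataFrame(tox_rows, columns=_TOX_COLUMNS)
    truth = pd.DataFrame(
        truth_rows, columns=["id", "planted_pass", "violated_rules"]
    ).set_index("id")
    return adme_table, tox_table, truth
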