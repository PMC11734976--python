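"""ADME and toxicity pass criteria over external prediction tables.

The funnel does not predict pharmacokinetics itself; it consumes tables
produced by prediction services (SwissADME-style ADME CSVs, DataWarrior
style toxicity risk tables) and applies the screening criteria:

ADME pass — all three solubility models report at least "Soluble", GI
absorption High, not BBB-permeant, not a P-glycoprotein substrate, and
non-inhibitor of CYP1A2/2C19/2C9/2D6/3A4.

Tox pass — mutagenic, tumorigenic and reproductive risks "none";
irritant risk at most "low".

Parsers are alias- and case-tolerant because the services vary their
headers between releases; delimiter is sniffed (CSV or TSV).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AdmeRecord",
    "ToxRecord",
    "parse_adme_table",
    "parse_tox_table",
    "adme_pass",
    "tox_pass",
]

SOLUBILITY_CLASSES = (
    "Insoluble",
    "Poorly soluble",
    "Moderately soluble",
    "Soluble",
    "Very soluble",
    "Highly soluble",
)
#: "Highly soluble" is what SwissADME emits above "Very soluble"; the
#: criterion is a lower bound, so it passes too.
PASSING_SOLUBILITY = ("Soluble", "Very soluble", "Highly soluble")
YES_NO = ("Yes", "No")
RISK_LEVELS = ("none", "low", "high")


@dataclass(frozen=True)
class AdmeRecord:
    id: str
    sol_esol: str
    sol_ali: str
    sol_silicosit: str
    gi_absorption: str
    bbb_permeant: str
    pgp_substrate: str
    cyp1a2: str
    cyp2c19: str
    cyp2c9: str
    cyp2d6: str
    cyp3a4: str


@dataclass(frozen=True)
class ToxRecord:
    id: str
    mutagenic: str
    tumorigenic: str
    reproductive_effective: str
    irritant: str


class MissingColumnError(ValueError):
    pass


def _norm(name: str) -> str:
    return " ".join(str(name).lower().split())


# field -> accepted header aliases (normalized)
_ADME_ALIASES: dict[str, tuple[str, ...]] = {
    "id": ("molecule", "id", "name", "compound", "compound id"),
    "sol_esol": ("esol class", "esol solubility class", "class"),
    "sol_ali": ("ali class", "ali solubility class", "class.1"),
    "sol_silicosit": (
        "silicos-it class",
        "silicos-it solubility class",
        "silicosit class",
        "class.2",
    ),
    "gi_absorption": ("gi absorption", "gastrointestinal absorption"),
    "bbb_permeant": ("bbb permeant", "bbb"),
    "pgp_substrate": ("pgp substrate", "p-gp substrate", "pgp"),
    "cyp1a2": ("cyp1a2 inhibitor", "cyp1a2"),
    "cyp2c19": ("cyp2c19 inhibitor", "cyp2c19"),
    "cyp2c9": ("cyp2c9 inhibitor", "cyp2c9"),
    "cyp2d6": ("cyp2d6 inhibitor", "cyp2d6"),
    "cyp3a4": ("cyp3a4 inhibitor", "cyp3a4"),
}

_TOX_ALIASES: dict[str, tuple[str, ...]] = {
    "id": ("compound", "id", "name", "molecule", "structure name"),
    "mutagenic": ("mutagenic", "mutagenicity"),
    "tumorigenic": ("tumorigenic", "tumorigenicity"),
    "reproductive_effective": (
        "reproductive effective",
        "reproductive effect",
        "reproductive toxicity",
    ),
    "irritant": ("irritant", "irritant effects"),
}

_ADME_VOCAB = {
    "sol_esol": SOLUBILITY_CLASSES,
    "sol_ali": SOLUBILITY_CLASSES,
    "sol_silicosit": SOLUBILITY_CLASSES,
    "gi_absorption": ("High", "Low"),
    "bbb_permeant": YES_NO,
    "pgp_substrate": YES_NO,
    "cyp1a2": YES_NO,
    "cyp2c19": YES_NO,
    "cyp2c9": YES_NO,
    "cyp2d6": YES_NO,
    "cyp3a4": YES_NO,
}


def _read_table(path) -> pd.DataFrame:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        delim = csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        delim = ","
    return pd.read_csv(path, sep=delim)


def _map_columns(
    frame: pd.DataFrame, aliases: dict[str, tuple[str, ...]], kind: str
) -> dict[str, str]:
    normed = {_norm(c): c for c in frame.columns}
    mapping = {}
    for fld, names in aliases.items():
        for name in names:
            if name in normed:
                mapping[fld] = normed[name]
                break
        else:
            raise MissingColumnError(
                f"{kind} table is missing a column for {fld!r} "
                f"(accepted headers: {list(names)})"
            )
    return mapping


def _canon(value: str, vocab: tuple[str, ...]) -> str | None:
    v = _norm(value)
    for item in vocab:
        if v == item.lower():
            return item
    return None


def parse_adme_table(path) -> list[AdmeRecord]:
    """Parse a SwissADME-style prediction table into records.

    Rows with an out-of-vocabulary cell are rejected (and logged), not
    silently coerced; a missing required column raises
    :class:`MissingColumnError` naming the field.
    """
    frame = _read_table(path)
    cols = _map_columns(frame, _ADME_ALIASES, "ADME")
    records = []
    for _, row in frame.iterrows():
        values = {"id": str(row[cols["id"]])}
        ok = True
        for fld, vocab in _ADME_VOCAB.items():
            canon = _canon(str(row[cols[fld]]), vocab)
            if canon is None:
                logger.warning(
                    "rejecting ADME row %s: %r is not a valid %s value",
                    values["id"], row[cols[fld]], fld,
                )
                ok = False
                break
            values[fld] = canon
        if ok:
            records.append(AdmeRecord(**values))
    return records


_BOOL_RISK = {"true": "high", "false": "none", "yes": "high", "no": "none"}


def parse_tox_table(path) -> list[ToxRecord]:
    """Parse a DataWarrior-style risk table into records.

    Risk cells are ``none`` / ``low`` / ``high``; boolean-only dialects
    are accepted by mapping True→high and False→none.
    """
    frame = _read_table(path)
    cols = _map_columns(frame, _TOX_ALIASES, "toxicity")
    records = []
    for _, row in frame.iterrows():
        values = {"id": str(row[cols["id"]])}
        ok = True
        for fld in (
            "mutagenic",
            "tumorigenic",
            "reproductive_effective",
            "irritant",
        ):
            raw = _norm(str(row[cols[fld]]))
            raw = _BOOL_RISK.get(raw, raw)
            if raw not in RISK_LEVELS:
                logger.warning(
                    "rejecting toxicity row %s: %r is not a valid %s level",
                    values["id"], row[cols[fld]], fld,
                )
                ok = False
                break
            values[fld] = raw
        if ok:
            records.append(ToxRecord(**values))
    return records


def adme_pass(rec: AdmeRecord) -> tuple[bool, list[str]]:
    """Apply the ADME criteria; returns (passed, violated criteria)."""
    violations = []
    if rec.sol_esol not in PASSING_SOLUBILITY:
        violations.append("ESOL solubility")
    if rec.sol_ali not in PASSING_SOLUBILITY:
        violations.append("Ali solubility")
    if rec.sol_silicosit not in PASSING_SOLUBILITY:
        violations.append("Silicos-IT solubility")
    if rec.gi_absorption != "High":
        violations.append("GI absorption")
    if rec.bbb_permeant != "No":
        violations.append("BBB")
    if rec.pgp_substrate != "No":
        violations.append("Pgp")
    for cyp in ("cyp1a2", "cyp2c19", "cyp2c9", "cyp2d6", "cyp3a4"):
        if getattr(rec, cyp) != "No":
            violations.append(cyp.upper())
    return not violations, violations


def tox_pass(rec: ToxRecord) -> tuple[bool, list[str]]:
    """Apply the toxicity criteria; returns (passed, violated criteria)."""
    violations = []
    if rec.mutagenic != "none":
        violations.append("mutagenic")
    if rec.tumorigenic != "none":
        violations.append("tumorigenic")
    if rec.reproductive_effective != "none":
        violations.append("reproductive")
    if rec.irritant not in ("none", "low"):
        violations.append("irritant")
    return not violations, violations
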