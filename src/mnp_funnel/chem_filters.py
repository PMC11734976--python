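"""Drug-likeness rule cascade and PAINS screening.

Computes the physicochemical descriptors that oral-bioavailability rule
sets test (molecular weight, logP, H-bond donors/acceptors, TPSA,
rotatable bonds, molar refractivity, atom/ring counts) and applies eight
published medicinal-chemistry filters — Lipinski, Veber, Egan, Muegge,
Ghose, Varma, GSK 4/400 and Pfizer 3/75 — plus the PAINS substructure
screen, as a cascade over a compound library.

Descriptors come from RDKit.  Both ``clogp`` and ``wlogp`` are backed by
the Wildman–Crippen atomic-contribution estimator, the only logP model
RDKit ships; rule sets written against other estimators (Egan, Ghose)
therefore see the same number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

__all__ = [
    "MoleculeRecord",
    "DescriptorVector",
    "RuleVerdict",
    "PainsResult",
    "FilterReport",
    "RULES",
    "parse_smiles_file",
    "write_smiles_file",
    "deduplicate",
    "compute_descriptors",
    "evaluate_rule",
    "pains_screen",
    "apply_cascade",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """A compound identifier paired with its SMILES string."""

    id: str
    smiles: str


@dataclass(frozen=True)
class DescriptorVector:
    """Physicochemical descriptors feeding every rule filter.

    Units: ``mw`` g/mol, ``tpsa`` Å²; logP and molar refractivity are
    unitless; the rest are counts.
    """

    mw: float
    clogp: float
    wlogp: float
    hbd: int
    hba: int
    tpsa: float
    rotb: int
    mr: float
    heavy_atoms: int
    total_atoms: int
    rings: int
    carbons: int
    heteroatoms: int


@dataclass(frozen=True)
class RuleVerdict:
    rule: str
    passed: bool
    violations: tuple[str, ...]


@dataclass(frozen=True)
class PainsResult:
    id: str
    alerts: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.alerts


@dataclass
class FilterReport:
    """Per-stage survivor counts and the full pass/fail matrix."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    matrix: pd.DataFrame | None = None
    rejected: list[str] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)


class UnknownRuleError(ValueError):
    pass


class InvalidSmilesError(ValueError):
    pass


# ---------------------------------------------------------------------------
# descriptors


def _mol_from_smiles(smiles: str, id: str = "?") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparsable SMILES for {id!r}: {smiles!r}")
    return mol


def compute_descriptors(record: MoleculeRecord | str) -> DescriptorVector:
    """Compute the full descriptor vector for one molecule.

    Accepts a :class:`MoleculeRecord` or a bare SMILES string.  Raises
    :class:`InvalidSmilesError` when the SMILES does not parse.
    """
    if isinstance(record, str):
        record = MoleculeRecord(id="?", smiles=record)
    mol = _mol_from_smiles(record.smiles, record.id)
    # recompute from the canonical form so atom order cannot leak into
    # summation order: canonical-SMILES-equal inputs give identical vectors
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    molh = Chem.AddHs(mol)
    logp = Crippen.MolLogP(mol)
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        clogp=logp,
        wlogp=logp,
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(mol),
        mr=Crippen.MolMR(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        total_atoms=molh.GetNumAtoms(),
        rings=rdMolDescriptors.CalcNumRings(mol),
        carbons=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6),
        heteroatoms=sum(
            1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6)
        ),
    )


# ---------------------------------------------------------------------------
# rule filters
#
# Each checker returns the list of violated conditions.  Thresholds follow
# the original rule publications / SwissADME conventions.


def _lipinski(d: DescriptorVector) -> list[str]:
    v = []
    if d.mw > 500:
        v.append("MW>500")
    if d.clogp > 5:
        v.append("cLogP>5")
    if d.hbd > 5:
        v.append("HBD>5")
    if d.hba > 10:
        v.append("HBA>10")
    return v


def _veber(d: DescriptorVector) -> list[str]:
    v = []
    if d.rotb > 10:
        v.append("RotB>10")
    if d.tpsa > 140:
        v.append("TPSA>140")
    return v


def _egan(d: DescriptorVector) -> list[str]:
    v = []
    if d.wlogp > 5.88:
        v.append("WLOGP>5.88")
    if d.tpsa > 131.6:
        v.append("TPSA>131.6")
    return v


def _muegge(d: DescriptorVector) -> list[str]:
    v = []
    if not 200 <= d.mw <= 600:
        v.append("MW outside 200-600")
    if not -2 <= d.clogp <= 5:
        v.append("cLogP outside -2-5")
    if d.tpsa > 150:
        v.append("TPSA>150")
    if d.rings > 7:
        v.append("rings>7")
    if d.carbons <= 4:
        v.append("carbons<=4")
    if d.heteroatoms <= 1:
        v.append("heteroatoms<=1")
    if d.rotb > 15:
        v.append("RotB>15")
    if d.hbd > 5:
        v.append("HBD>5")
    if d.hba > 10:
        v.append("HBA>10")
    return v


def _ghose(d: DescriptorVector) -> list[str]:
    v = []
    if not 160 <= d.mw <= 480:
        v.append("MW outside 160-480")
    if not -0.4 <= d.wlogp <= 5.6:
        v.append("WLOGP outside -0.4-5.6")
    if not 40 <= d.mr <= 130:
        v.append("MR outside 40-130")
    if not 20 <= d.total_atoms <= 70:
        v.append("atoms outside 20-70")
    return v


def _varma(d: DescriptorVector) -> list[str]:
    v = []
    if d.mw > 500:
        v.append("MW>500")
    if d.tpsa > 125:
        v.append("TPSA>125")
    if d.rotb > 12:
        v.append("RotB>12")
    if d.hbd + d.hba > 9:
        v.append("HBD+HBA>9")
    return v


def _gsk(d: DescriptorVector) -> list[str]:
    v = []
    if d.mw > 400:
        v.append("MW>400")
    if d.clogp > 4:
        v.append("cLogP>4")
    return v


def _pfizer(d: DescriptorVector) -> list[str]:
    # toxicity-risk rule: flagged only when BOTH conditions hold
    if d.clogp > 3 and d.tpsa < 75:
        return ["cLogP>3 and TPSA<75"]
    return []


_RULE_FUNCS = {
    "lipinski": _lipinski,
    "veber": _veber,
    "egan": _egan,
    "muegge": _muegge,
    "ghose": _ghose,
    "varma": _varma,
    "gsk": _gsk,
    "pfizer": _pfizer,
}

#: Canonical rule order used by :func:`apply_cascade` when none is given.
RULES: tuple[str, ...] = tuple(_RULE_FUNCS)

#: Lipinski tolerates one violated condition in its classical formulation.
LIPINSKI_ALLOWED_VIOLATIONS = 1


def evaluate_rule(
    desc: DescriptorVector, rule: str, *, lipinski_strict: bool = False
) -> RuleVerdict:
    """Apply one named rule to a descriptor vector.

    ``lipinski`` passes with at most one violated condition unless
    ``lipinski_strict`` is set; every other rule demands zero violations.
    """
    try:
        func = _RULE_FUNCS[rule]
    except KeyError:
        raise UnknownRuleError(
            f"unknown rule {rule!r}; expected one of {sorted(_RULE_FUNCS)}"
        ) from None
    violations = func(desc)
    if rule == "lipinski" and not lipinski_strict:
        passed = len(violations) <= LIPINSKI_ALLOWED_VIOLATIONS
    else:
        passed = not violations
    return RuleVerdict(rule=rule, passed=passed, violations=tuple(violations))


# ---------------------------------------------------------------------------
# PAINS

_pains_catalog: FilterCatalog | None = None


def _get_pains_catalog() -> FilterCatalog:
    global _pains_catalog
    if _pains_catalog is None:
        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS_A)
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS_B)
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS_C)
        _pains_catalog = FilterCatalog(params)
    return _pains_catalog


def pains_screen(record: MoleculeRecord | str) -> PainsResult:
    """Match a molecule against the PAINS A+B+C substructure families.

    Reports every matching pattern name; an empty alert list means the
    compound passes the PAINS gate.
    """
    if isinstance(record, str):
        record = MoleculeRecord(id="?", smiles=record)
    mol = _mol_from_smiles(record.smiles, record.id)
    catalog = _get_pains_catalog()
    alerts = tuple(
        entry.GetDescription() for entry in catalog.GetMatches(mol)
    )
    return PainsResult(id=record.id, alerts=alerts)


# ---------------------------------------------------------------------------
# library I/O and dedup


def parse_smiles_file(path) -> list[MoleculeRecord]:
    """Read a ``.smi`` file: one ``SMILES<whitespace>id`` per line."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append(MoleculeRecord(id=mol_id, smiles=smiles))
    return records


def write_smiles_file(records: Iterable[MoleculeRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def parse_sdf_file(path) -> list[MoleculeRecord]:
    """Read an SDF; molecule title (or ``_Name``) becomes the id."""
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        records.append(MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(mol)))
    return records


def deduplicate(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[str]]:
    """Drop structural duplicates by canonical-SMILES identity.

    The first id encountered wins; the ids of dropped duplicates are
    returned for logging.
    """
    seen: dict[str, str] = {}
    kept, dropped = [], []
    for rec in records:
        canonical = Chem.MolToSmiles(_mol_from_smiles(rec.smiles, rec.id))
        if canonical in seen:
            dropped.append(rec.id)
        else:
            seen[canonical] = rec.id
            kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# cascade


def apply_cascade(
    records: Sequence[MoleculeRecord],
    rules: Sequence[str] = RULES,
    *,
    pains: bool = True,
    lipinski_strict: bool = False,
) -> tuple[list[MoleculeRecord], FilterReport]:
    """Run the rule cascade over a molecule set.

    A compound survives iff every rule verdict passes and (when the PAINS
    gate is enabled) it raises no PAINS alert.  The report carries the
    per-stage in/out counts of the funnel and the complete per-compound
    boolean pass/fail matrix — the survivor set is therefore independent
    of the rule order, only the stage counts depend on it.

    Unparsable SMILES are dropped up front and recorded in
    ``report.rejected``.
    """
    if not rules and not pains:
        raise ValueError("cascade needs at least one rule or the PAINS gate")
    for rule in rules:
        if rule not in _RULE_FUNCS:
            raise UnknownRuleError(f"unknown rule {rule!r}")

    report = FilterReport()
    valid: list[MoleculeRecord] = []
    for rec in records:
        try:
            _mol_from_smiles(rec.smiles, rec.id)
        except InvalidSmilesError:
            report.rejected.append(rec.id)
        else:
            valid.append(rec)

    columns = list(rules) + (["pains"] if pains else [])
    rows = {}
    for rec in valid:
        desc = compute_descriptors(rec)
        row = {
            rule: evaluate_rule(
                desc, rule, lipinski_strict=lipinski_strict
            ).passed
            for rule in rules
        }
        if pains:
            row["pains"] = pains_screen(rec).passed
        rows[rec.id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    matrix = matrix.reindex([r.id for r in valid])
    report.matrix = matrix

    alive = pd.Series(True, index=matrix.index)
    for stage in columns:
        n_in = int(alive.sum())
        alive &= matrix[stage]
        report.stages.append((stage, n_in, int(alive.sum())))

    survivor_ids = set(matrix.index[alive]) if len(matrix) else set()
    survivors = [rec for rec in valid if rec.id in survivor_ids]
    return survivors, report
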