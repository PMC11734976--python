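"""End-to-end funnel orchestration.

Chains the screening stages — docking-score threshold, drug-likeness /
PAINS cascade, ADME gate, toxicity gate, consensus ranking with top-N
selection — over file inputs declared in a single config mapping, and
reports per-stage survivor counts and ids (the funnel chart of a
screening campaign, as data).  Every stage is optional; survivors of
one stage become the input id set of the next.

Config layout (YAML or dict)::

    seed: 1
    threshold: {scores: hits.csv, cutoff: -7.0}
    chem_filters: {input: lib.smi, rules: [lipinski, veber], pains: true}
    adme: {input: swissadme.csv}
    tox: {input: datawarrior.csv}
    consensus: {scores: docking.csv, top: 6}

The docking-score cutoff has no default: it is a campaign decision and
must be stated explicitly when the threshold stage is enabled.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import adme_tox, chem_filters
from .consensus_ranker import ScoreTable, rank_by_rank, score_threshold_filter, select_top

logger = logging.getLogger(__name__)

__all__ = ["FunnelReport", "StageResult", "run_funnel", "report_render"]

STAGE_ORDER = ("threshold", "chem_filters", "adme", "tox", "consensus")


class ConfigError(ValueError):
    pass


@dataclass
class StageResult:
    name: str
    n_in: int
    n_out: int
    survivors: list[str]


@dataclass
class FunnelReport:
    stages: list[StageResult] = field(default_factory=list)
    config_hash: str = ""
    seed: int | None = None
    timestamp: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "survivors": list(s.survivors),
                }
                for s in self.stages
            ],
            "config_hash": self.config_hash,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "extras": self.extras,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FunnelReport":
        report = cls(
            config_hash=data.get("config_hash", ""),
            seed=data.get("seed"),
            timestamp=data.get("timestamp"),
            extras=data.get("extras", {}),
        )
        report.stages = [
            StageResult(
                name=s["name"],
                n_in=int(s["n_in"]),
                n_out=int(s["n_out"]),
                survivors=[str(x) for x in s["survivors"]],
            )
            for s in data["stages"]
        ]
        return report

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "FunnelReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def stage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_out) for s in self.stages],
            columns=["stage", "n_in", "n_out"],
        )


def _restrict(ids: list[str], alive: set[str] | None) -> list[str]:
    return ids if alive is None else [i for i in ids if i in alive]


def run_funnel(config: dict, timestamp: bool = True) -> FunnelReport:
    """Execute the enabled stages in funnel order.

    Returns the report; a stage receiving zero compounds completes with
    an empty survivor set (warning logged) and the funnel carries on so
    the report still shows every enabled stage.
    """
    unknown = set(config) - set(STAGE_ORDER) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    report = FunnelReport(
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        seed=config.get("seed"),
        timestamp=time.time() if timestamp else None,
    )
    alive: set[str] | None = None  # None = no stage has run yet

    def finish(name: str, n_in: int, survivors: list[str]) -> None:
        nonlocal alive
        alive = set(survivors)
        report.stages.append(
            StageResult(name=name, n_in=n_in, n_out=len(survivors),
                        survivors=sorted(survivors))
        )
        if not survivors:
            logger.warning("stage %s left zero compounds", name)

    if "threshold" in config:
        cfg = config["threshold"]
        if "cutoff" not in cfg:
            raise ConfigError("threshold stage requires an explicit cutoff")
        frame = pd.read_csv(cfg["scores"], index_col=0)
        scores = {
            str(i): float(v) for i, v in frame.iloc[:, 0].items()
        }
        scores = {
            i: v for i, v in scores.items() if alive is None or i in alive
        }
        kept = score_threshold_filter(scores, float(cfg["cutoff"]))
        finish("threshold", len(scores), sorted(kept))

    if "chem_filters" in config:
        cfg = config["chem_filters"]
        records = chem_filters.parse_smiles_file(cfg["input"])
        records = [r for r in records if alive is None or r.id in alive]
        records, dropped = chem_filters.deduplicate(records)
        if dropped:
            logger.info("dropped %d duplicate structures", len(dropped))
        survivors, _ = chem_filters.apply_cascade(
            records,
            rules=tuple(cfg.get("rules", chem_filters.RULES)),
            pains=bool(cfg.get("pains", True)),
            lipinski_strict=bool(cfg.get("lipinski_strict", False)),
        )
        finish("chem_filters", len(records), [r.id for r in survivors])

    if "adme" in config:
        records = adme_tox.parse_adme_table(config["adme"]["input"])
        records = [r for r in records if alive is None or r.id in alive]
        kept = [r.id for r in records if adme_tox.adme_pass(r)[0]]
        finish("adme", len(records), kept)

    if "tox" in config:
        records = adme_tox.parse_tox_table(config["tox"]["input"])
        records = [r for r in records if alive is None or r.id in alive]
        kept = [r.id for r in records if adme_tox.tox_pass(r)[0]]
        finish("tox", len(records), kept)

    if "consensus" in config:
        cfg = config["consensus"]
        table = ScoreTable.from_csv(cfg["scores"])
        if alive is not None:
            keep = [i for i, c in enumerate(table.compounds) if c in alive]
            if not keep:
                finish("consensus", 0, [])
                return report
            table = ScoreTable(
                compounds=[table.compounds[i] for i in keep],
                programs=table.programs,
                scores=table.scores[keep],
            )
        cons = rank_by_rank(table)
        top = int(cfg.get("top", len(table.compounds)))
        selected = select_top(cons, top)
        report.extras["consensus_ordering"] = cons.ordering
        report.extras["mean_rank"] = {
            c: float(v) for c, v in cons.mean_rank.items()
        }
        finish("consensus", len(table.compounds), selected)

    if not report.stages:
        raise ConfigError("config enables no stages")
    return report


def report_render(report: FunnelReport) -> str:
    """Human-readable funnel table (deterministic formatting)."""
    lines = [f"{'stage':<14}{'n_in':>8}{'n_out':>8}"]
    for s in report.stages:
        lines.append(f"{s.name:<14}{s.n_in:>8}{s.n_out:>8}")
    if report.stages:
        final = report.stages[-1]
        lines.append(f"final survivors: {', '.join(final.survivors) or '(none)'}")
    return "\n".join(lines)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config file must hold a mapping")
    return config
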