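"""Staged hit-triage funnel with an elimination ledger and consensus ranking.

A virtual-screening campaign triages a compound library through ordered
stages: an energy cutoff on docking scores (strictly below the threshold
survives), a drug-likeness rule stage (all required rules Accepted), and a
ligand-efficiency metric stage (all metric flags pass).  Every stage
records who entered, who survived and why each elimination happened, so
the familiar "N -> n1 -> n2" screening narrative is fully auditable.

Survivors of the last stage can be ordered by a consensus (Borda-like
mean-rank) aggregation over any set of direction-aware criteria; ties
share mean ranks and final ordering breaks ties lexicographically by
compound id for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .druglikeness import RuleOutcome
from .errors import ContractError
from .ligand_efficiency import EfficiencyReport, MetricThresholds
from .tables_io import CompoundRecord, Role, ScoreTable

__all__ = [
    "Criterion",
    "ConsensusConfig",
    "FunnelConfig",
    "StageRecord",
    "ScreeningLedger",
    "RankTable",
    "apply_energy_cutoff",
    "apply_rule_stage",
    "apply_metric_stage",
    "consensus_rank",
    "run_funnel",
]


@dataclass(frozen=True)
class Criterion:
    name: str
    better: str = "lower"  # "lower" | "higher"
    weight: float = 1.0

    def __post_init__(self):
        if self.better not in ("lower", "higher"):
            raise ContractError("criterion direction must be 'lower' or 'higher'")
        if self.weight < 0:
            raise ContractError("criterion weight must be >= 0")


@dataclass(frozen=True)
class ConsensusConfig:
    criteria: tuple[Criterion, ...]
    aggregation: str = "mean_rank"  # "mean_rank" | "weighted_mean_rank"

    def __post_init__(self):
        if not self.criteria:
            raise ContractError("at least one consensus criterion required")
        if all(c.weight == 0 for c in self.criteria):
            raise ContractError("criterion weights must not all be zero")


@dataclass
class FunnelConfig:
    vs_cutoff: float = -8.0  # kcal/mol, strict '<' survives
    dock_cutoff: float = -8.0
    required_rules: tuple[str, ...] = ("Lipinski", "Pfizer")
    metric_thresholds: MetricThresholds = field(default_factory=MetricThresholds)
    consensus: ConsensusConfig | None = None
    candidate_roles: tuple[Role, ...] = (Role.ANALOG,)


@dataclass
class StageRecord:
    name: str
    entering: list[str]
    surviving: list[str]
    eliminations: dict[str, str]

    def __post_init__(self):
        if set(self.surviving) | set(self.eliminations) != set(self.entering):
            raise ContractError(f"stage {self.name}: survivors + eliminated != entering")
        if set(self.surviving) & set(self.eliminations):
            raise ContractError(f"stage {self.name}: survivors overlap eliminated")


@dataclass
class ScreeningLedger:
    stages: list[StageRecord] = field(default_factory=list)

    def add(self, record: StageRecord) -> None:
        if self.stages and set(record.entering) != set(self.stages[-1].surviving):
            raise ContractError(
                f"stage {record.name}: entrants differ from previous survivors"
            )
        self.stages.append(record)

    @property
    def final_survivors(self) -> list[str]:
        return list(self.stages[-1].surviving) if self.stages else []

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, len(s.entering), len(s.surviving)) for s in self.stages]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            for cid in s.entering:
                rows.append(
                    {
                        "stage": s.name,
                        "compound_id": cid,
                        "survived": cid in set(s.surviving),
                        "reason": s.eliminations.get(cid, ""),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class RankTable:
    """Per-candidate metric values, per-criterion ranks and final order."""

    table: pd.DataFrame  # indexed by candidate id

    @property
    def order(self) -> list[str]:
        return list(self.table.index)

    def rank_of(self, candidate: str) -> float:
        return float(self.table.loc[candidate, "final_rank"])


def apply_energy_cutoff(
    scores: ScoreTable, cutoff: float, candidates: Sequence[str] | None = None
) -> tuple[list[str], dict[str, str]]:
    """Keep entries with binding energy strictly below the cutoff."""
    survivors, eliminations = [], {}
    wanted = None if candidates is None else set(candidates)
    for entry in scores:
        if wanted is not None and entry.compound_id not in wanted:
            continue
        if entry.binding_energy < cutoff:
            survivors.append(entry.compound_id)
        else:
            eliminations[entry.compound_id] = (
                f"BE {entry.binding_energy:g} kcal/mol not < cutoff {cutoff:g}"
            )
    return survivors, eliminations


def apply_rule_stage(
    candidates: Sequence[str],
    outcomes: Mapping[str, Mapping[str, RuleOutcome]],
    required_rules: Sequence[str],
) -> tuple[list[str], dict[str, str]]:
    """Keep candidates for which every required rule is Accepted."""
    survivors, eliminations = [], {}
    for cid in candidates:
        if cid not in outcomes:
            raise ContractError(f"no rule outcomes for candidate {cid!r}")
        failed = []
        for rule in required_rules:
            if rule not in outcomes[cid]:
                raise ContractError(f"candidate {cid!r} missing outcome for rule {rule!r}")
            if not outcomes[cid][rule].accepted:
                failed.append(rule)
        if failed:
            eliminations[cid] = "failed rule(s): " + ", ".join(failed)
        else:
            survivors.append(cid)
    return survivors, eliminations


def apply_metric_stage(
    candidates: Sequence[str],
    reports: Mapping[str, EfficiencyReport],
    thresholds: MetricThresholds | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Keep candidates whose efficiency-metric flags all pass.

    Reports are expected to have been evaluated against the same
    ``thresholds`` (kept as an argument for reason strings).
    """
    thresholds = thresholds or MetricThresholds()
    survivors, eliminations = [], {}
    for cid in candidates:
        if cid not in reports:
            raise ContractError(f"no efficiency report for candidate {cid!r}")
        rep = reports[cid]
        if rep.passes:
            survivors.append(cid)
        else:
            bits = []
            for name in rep.failed_metrics():
                value = getattr(rep, name.lower(), None)
                if name == "LELP":
                    lo, hi = thresholds.lelp_range
                    bits.append(f"LELP {rep.lelp:.3f} outside [{lo:g}, {hi:g}]")
                elif value is not None:
                    bits.append(f"{name} {value:.3f} below threshold")
                else:
                    bits.append(name)
            eliminations[cid] = "; ".join(bits)
    return survivors, eliminations


def consensus_rank(
    candidates: Sequence[str],
    metrics: Mapping[str, Mapping[str, float]],
    config: ConsensusConfig,
) -> RankTable:
    """Direction-aware mean-rank aggregation over candidates."""
    cands = list(candidates)
    if not cands:
        return RankTable(pd.DataFrame(columns=["aggregate", "final_rank"]))
    for cid in cands:
        if cid not in metrics:
            raise ContractError(f"no metric values for candidate {cid!r}")
        for crit in config.criteria:
            if crit.name not in metrics[cid]:
                raise ContractError(
                    f"candidate {cid!r} missing value for criterion {crit.name!r}"
                )
    data: dict[str, list[float]] = {}
    rank_cols: dict[str, np.ndarray] = {}
    for crit in config.criteria:
        vals = np.asarray([float(metrics[c][crit.name]) for c in cands])
        ranks = rankdata(vals if crit.better == "lower" else -vals, method="average")
        data[crit.name] = vals.tolist()
        rank_cols[f"rank_{crit.name}"] = ranks
    weights = np.asarray(
        [c.weight if config.aggregation == "weighted_mean_rank" else 1.0 for c in config.criteria]
    )
    stacked = np.stack([rank_cols[f"rank_{c.name}"] for c in config.criteria])
    aggregate = (weights[:, None] * stacked).sum(axis=0) / weights.sum()
    df = pd.DataFrame({**data, **rank_cols, "aggregate": aggregate}, index=cands)
    df = df.loc[sorted(cands, key=lambda c: (df.loc[c, "aggregate"], c))]
    df["final_rank"] = rankdata(df["aggregate"].to_numpy(), method="average")
    return RankTable(df)


def run_funnel(
    records: Sequence[CompoundRecord],
    scores: ScoreTable,
    rule_outcomes: Mapping[str, Mapping[str, RuleOutcome]],
    efficiency_reports: Mapping[str, EfficiencyReport],
    config: FunnelConfig | None = None,
    consensus_metrics: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[ScreeningLedger, RankTable]:
    """Execute dock-cutoff -> rules -> metrics stages over the candidates.

    Only compounds whose role is in ``config.candidate_roles`` enter the
    funnel (parent and control compounds are comparators, not candidates).
    All inputs join on compound_id; orphan candidates raise.
    """
    config = config or FunnelConfig()
    candidates = [r.compound_id for r in records if r.role in config.candidate_roles]
    scored = {e.compound_id for e in scores}
    orphans = [c for c in candidates if c not in scored]
    if orphans:
        raise ContractError(f"candidates without scores: {orphans}")

    ledger = ScreeningLedger()
    survivors, elim = apply_energy_cutoff(scores, config.dock_cutoff, candidates)
    ledger.add(StageRecord("dock_cutoff", list(candidates), survivors, elim))

    entering = ledger.final_survivors
    survivors, elim = apply_rule_stage(entering, rule_outcomes, config.required_rules)
    ledger.add(StageRecord("rules", entering, survivors, elim))

    entering = ledger.final_survivors
    survivors, elim = apply_metric_stage(
        entering, efficiency_reports, config.metric_thresholds
    )
    ledger.add(StageRecord("metrics", entering, survivors, elim))

    finalists = ledger.final_survivors
    if config.consensus is not None and finalists:
        metrics = consensus_metrics
        if metrics is None:
            metrics = {
                c: {"binding_energy": scores.energy_of(c)} for c in finalists
            }
        ranking = consensus_rank(finalists, metrics, config.consensus)
    elif finalists:
        metrics = {c: {"binding_energy": scores.energy_of(c)} for c in finalists}
        ranking = consensus_rank(
            finalists, metrics, ConsensusConfig((Criterion("binding_energy", "lower"),))
        )
    else:
        ranking = RankTable(pd.DataFrame(columns=["aggregate", "final_rank"]))
    return ledger, ranking
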