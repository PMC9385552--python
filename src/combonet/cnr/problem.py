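"""Problem construction for comparative network reconstruction."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ..mra import ResponseMatrix
from ..synthetic import DOSE_LABELS, parse_condition_id

Edge = tuple[str, str]  # (target, source): coefficient r[target, source]


@dataclass(frozen=True)
class Hyperparams:
    """Penalty weights: eta per edge, theta per between-line difference.

    ``theta = math.inf`` forbids any difference between cell lines.
    """

    eta: float = 0.1
    theta: float = 2.0

    def __post_init__(self) -> None:
        if self.eta < 0 or self.theta < 0:
            raise ValueError("hyperparameters must be non-negative")


def expand_downstream_targets(
    target_map: Mapping[str, list[str]],
    topology: Iterable[Edge],
    drug: str = "MEKi",
    node: str = "MEK1",
) -> dict[str, list[str]]:
    """Add a node's topology children to one drug's target set.

    Used for inhibitors that block catalytic activity as well as the
    phosphorylation of their target, so downstream nodes feel a direct effect.
    """
    out = {d: sorted(set(t)) for d, t in target_map.items()}
    if drug in out:
        children = {i for (i, j) in topology if j == node}
        out[drug] = sorted(set(out[drug]) | children)
    return out


@dataclass
class RowSpec:
    """Per-node slice of the reconstruction problem (rows decouple exactly)."""

    node: str
    sources: list[str]  # candidate in-edge sources, fixed order
    prior_sources: list[str]
    svars: list[tuple[str, list[str]]]  # (drug, measured dose labels targeting node)


@dataclass
class CNRProblem:
    lines: list[str]
    nodes: list[str]
    conditions: list[str]
    applied: dict[str, tuple[tuple[str, str], ...]]
    R: dict[str, ResponseMatrix]
    candidate_edges: list[Edge]
    prior_edges: set[Edge]
    drug_target_map: dict[str, list[str]]
    dose_levels: dict[str, dict[str, float]] | None
    hyper: Hyperparams
    bound: float = 10.0
    delta: float = 1e-6
    rows: list[RowSpec] = field(default_factory=list)

    def row_for(self, node: str) -> RowSpec:
        return next(r for r in self.rows if r.node == node)

    def free_indicator_keys(self) -> list[tuple]:
        """Global keys of all indicator variables that are not fixed."""
        keys: list[tuple] = []
        for row in self.rows:
            for j in row.sources:
                if j not in row.prior_sources:
                    keys.append(("edge", (row.node, j)))
            if math.isfinite(self.hyper.theta) and len(self.lines) > 1:
                for j in row.sources:
                    keys.append(("diff", (row.node, j)))
                for drug, _ in row.svars:
                    keys.append(("sdiff", (drug, row.node)))
        return keys


def build_problem(
    R_by_line: Mapping[str, ResponseMatrix],
    prior_edges: Iterable[Edge],
    drug_target_map: Mapping[str, list[str]],
    hyperparams: Hyperparams | None = None,
    conditions: Mapping[str, tuple] | None = None,
    candidate_edges: Iterable[Edge] | None = None,
    dose_levels: Mapping[str, Mapping[str, float]] | None = None,
    bound: float = 10.0,
    delta: float = 1e-6,
) -> CNRProblem:
    """Assemble the reconstruction problem.

    ``prior_edges`` are fixed present; ``candidate_edges`` (default: all
    ordered off-diagonal pairs) may be added at cost eta each.  Conditions are
    parsed from the response-matrix column labels ("DRUG@IC50+DRUG2@IC50")
    unless given explicitly as {condition_id: ((drug, dose_label), ...)}.
    """
    lines = list(R_by_line)
    if not lines:
        raise ValueError("need at least one cell line")
    first = R_by_line[lines[0]]
    nodes = first.nodes
    cond_ids = first.conditions
    for ln in lines[1:]:
        if R_by_line[ln].nodes != nodes or R_by_line[ln].conditions != cond_ids:
            raise ValueError("response matrices are not aligned across cell lines")

    if conditions is None:
        applied = {cid: parse_condition_id(cid) for cid in cond_ids}
    else:
        applied = {cid: tuple(conditions[cid]) for cid in cond_ids}

    node_set = set(nodes)
    for cid, pairs in applied.items():
        for drug, label in pairs:
            if drug not in drug_target_map:
                raise ValueError(f"condition {cid!r} references unknown drug {drug!r}")
            targets = [t for t in drug_target_map[drug] if t in node_set]
            if not targets:
                raise ValueError(f"drug {drug!r} has no mappable target among the nodes")
            if label not in DOSE_LABELS:
                raise ValueError(f"condition {cid!r} uses unknown dose label {label!r}")

    if candidate_edges is None:
        candidates = [(i, j) for i in nodes for j in nodes if i != j]
    else:
        candidates = list(dict.fromkeys(candidate_edges))
        for i, j in candidates:
            if i == j:
                raise ValueError(f"self-loop candidate edge ({i},{j})")
            if i not in node_set or j not in node_set:
                raise ValueError(f"candidate edge ({i},{j}) references unknown node")
    prior = set(prior_edges)
    if not prior <= set(candidates):
        missing = prior - set(candidates)
        raise ValueError(f"prior edges not among candidates: {sorted(missing)}")

    # Measured dose labels per (drug, target) pair, in IC10<IC50<IC90 order.
    measured: dict[tuple[str, str], list[str]] = {}
    for pairs in applied.values():
        for drug, label in pairs:
            for t in drug_target_map[drug]:
                if t in node_set:
                    labels = measured.setdefault((drug, t), [])
                    if label not in labels:
                        labels.append(label)
    measured = {k: sorted(v, key=DOSE_LABELS.index) for k, v in measured.items()}

    rows = []
    for node in nodes:
        sources = [j for (i, j) in candidates if i == node]
        prior_sources = [j for (i, j) in sorted(prior) if i == node]
        svars = sorted((d, labels) for (d, t), labels in measured.items() if t == node)
        rows.append(RowSpec(node, sources, prior_sources, svars))

    return CNRProblem(
        lines=lines,
        nodes=nodes,
        conditions=cond_ids,
        applied=applied,
        R={ln: R_by_line[ln] for ln in lines},
        candidate_edges=candidates,
        prior_edges=prior,
        drug_target_map={d: list(t) for d, t in drug_target_map.items()},
        dose_levels={d: dict(v) for d, v in dose_levels.items()} if dose_levels else None,
        hyper=hyperparams or Hyperparams(),
        bound=bound,
        delta=delta,
        rows=rows,
    )
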