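"""Synthetic two-cell-line ground truths, study designs and noisy datasets.

Emulates the structure of the study this package targets: 9 phospho-protein
nodes, 9 inhibitors tested at two doses each (one drug at a single dose),
plus a configurable number of two-drug IC50+IC50 combinations, measured in
two cell lines that share a topology but differ in a small number of planted
edge weights or direct perturbation strengths.  Responses follow the
steady-state relation R = -inv(r) @ s with additive Gaussian noise on the
log2 scale; viability follows the saturating two-node model (form 4c).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mra import InteractionMatrix, ResponseMatrix, simulate_response
from .viability import predict_viability

DEFAULT_NODES = [
    "CREB1",
    "EGFR",
    "ERK1",
    "GSK3",
    "MEK1",
    "p70S6K",
    "PRAS40",
    "RPS6",
    "AKT1",
]
DEFAULT_DRUGS = [
    "EGFRi",
    "IGF1Ri",
    "RAFi",
    "MEKi",
    "ERKi",
    "GSK3i",
    "PI3Ki",
    "AKTi",
    "mTORi",
]
# Drugs whose kinase target is unmeasured perturb the first measured
# downstream node(s); MEKi is additionally expanded to MEK1's topology
# children when the ground truth is generated.
DEFAULT_TARGET_MAP = {
    "EGFRi": ["EGFR"],
    "IGF1Ri": ["MEK1", "AKT1"],
    "RAFi": ["MEK1"],
    "MEKi": ["MEK1"],
    "ERKi": ["ERK1"],
    "GSK3i": ["GSK3"],
    "PI3Ki": ["AKT1"],
    "AKTi": ["AKT1"],
    "mTORi": ["AKT1", "p70S6K"],
}
DEFAULT_SINGLE_DOSE_DRUG = "RAFi"
DEFAULT_CELL_LINES = ["parental", "mutant"]

DOSE_LABELS = ("IC10", "IC50", "IC90")


def condition_id(applied: tuple[tuple[str, str], ...]) -> str:
    return "+".join(f"{drug}@{label}" for drug, label in applied)


def parse_condition_id(cond: str) -> tuple[tuple[str, str], ...]:
    parts = []
    for chunk in cond.split("+"):
        drug, _, label = chunk.partition("@")
        if not label:
            raise ValueError(f"malformed condition id {cond!r}")
        parts.append((drug, label))
    return tuple(parts)


@dataclass
class StudyDesign:
    """Perturbation design: drugs, dose levels, conditions, cell lines."""

    nodes: list[str]
    drugs: list[str]
    dose_levels: dict[str, dict[str, float]]  # drug -> {IC10/IC50/IC90: conc}
    conditions: dict[str, tuple[tuple[str, str], ...]]  # id -> ((drug, label), ...)
    cell_lines: list[str] = field(default_factory=lambda: list(DEFAULT_CELL_LINES))
    single_dose_drugs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition identifiers must be unique")
        for drug, levels in self.dose_levels.items():
            c10 = levels.get("IC10", 0.0)
            c50 = levels.get("IC50", 0.5)
            c90 = levels.get("IC90", 1.0)
            if not (0 < c10 < c50 < c90 == 1.0):
                raise ValueError(
                    f"dose levels for {drug} must satisfy 0 < IC10 < IC50 < IC90 = 1"
                )
        for cid, applied in self.conditions.items():
            for drug, label in applied:
                if drug not in self.dose_levels or label not in self.dose_levels[drug]:
                    raise ValueError(f"condition {cid!r} references undefined dose {drug}@{label}")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_measurements(self) -> int:
        """Total response-matrix entries across all cell lines."""
        return self.n_conditions * len(self.nodes) * len(self.cell_lines)

    def measured_doses(self) -> dict[str, list[str]]:
        """Dose labels at which each drug actually appears in some condition."""
        out: dict[str, set[str]] = {}
        for applied in self.conditions.values():
            for drug, label in applied:
                out.setdefault(drug, set()).add(label)
        return {d: sorted(v, key=DOSE_LABELS.index) for d, v in out.items()}


def make_study_design(
    nodes: list[str] | None = None,
    drugs: list[str] | None = None,
    combo_count: int = 17,
    single_dose_drug: str | None = DEFAULT_SINGLE_DOSE_DRUG,
    cell_lines: list[str] | None = None,
    dose_levels: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> StudyDesign:
    """Build a design with single-drug conditions at two doses (except the
    single-dose drug, IC90 only) plus ``combo_count`` distinct two-drug
    IC50+IC50 combinations drawn deterministically from ``seed``.
    """
    nodes = list(DEFAULT_NODES if nodes is None else nodes)
    drugs = list(DEFAULT_DRUGS if drugs is None else drugs)
    cell_lines = list(DEFAULT_CELL_LINES if cell_lines is None else cell_lines)
    if single_dose_drug is not None and single_dose_drug not in drugs:
        single_dose_drug = None
    rng = np.random.default_rng(seed)

    if dose_levels is None:
        dose_levels = {}
        for drug in drugs:
            c50 = float(rng.uniform(0.1, 0.4))
            c10 = float(c50 * rng.uniform(0.1, 0.5))
            dose_levels[drug] = {"IC10": c10, "IC50": c50, "IC90": 1.0}

    conditions: dict[str, tuple[tuple[str, str], ...]] = {}
    for drug in drugs:
        labels = ["IC90"] if drug == single_dose_drug else ["IC50", "IC90"]
        for label in labels:
            applied = ((drug, label),)
            conditions[condition_id(applied)] = applied

    combo_pool = [
        (a, b)
        for a, b in itertools.combinations(sorted(d for d in drugs if d != single_dose_drug), 2)
    ]
    if combo_count > len(combo_pool):
        raise ValueError(
            f"combo_count={combo_count} exceeds the {len(combo_pool)} available two-drug pairs"
        )
    if combo_count > 0:
        picks = rng.choice(len(combo_pool), size=combo_count, replace=False)
        for idx in sorted(picks):
            a, b = combo_pool[idx]
            applied = ((a, "IC50"), (b, "IC50"))
            conditions[condition_id(applied)] = applied

    return StudyDesign(
        nodes=nodes,
        drugs=drugs,
        dose_levels=dose_levels,
        conditions=conditions,
        cell_lines=cell_lines,
        single_dose_drugs=[single_dose_drug] if single_dose_drug else [],
    )


@dataclass
class GroundTruth:
    """True networks, direct effects and viability parameters per cell line."""

    nodes: list[str]
    cell_lines: list[str]
    r: dict[str, InteractionMatrix]
    # (cell_line, drug, dose_label, target) -> direct effect (< 0)
    s_spec: dict[tuple[str, str, str, str], float]
    target_map: dict[str, list[str]]
    k_m: dict[str, tuple[float, float]]  # cell line -> (K_M,AKT, K_M,ERK)
    planted_diffs: list[tuple[str, tuple]] = field(default_factory=list)

    def count_differences(self) -> int:
        """Count (edge or drug-target) coordinates that differ between lines."""
        a, b = self.cell_lines[:2]
        n = int((self.r[a].values.to_numpy() != self.r[b].values.to_numpy()).sum())
        pairs = {(d, t) for (_, d, _, t) in self.s_spec}
        for d, t in pairs:
            if any(
                self.s_spec.get((a, d, lab, t)) != self.s_spec.get((b, d, lab, t))
                for lab in DOSE_LABELS
            ):
                n += 1
        return n

    def edges(self) -> list[tuple[str, str]]:
        """Union of (target, source) edges over cell lines."""
        out = set()
        for im in self.r.values():
            out.update(im.edges())
        return sorted(out)

    def s_vector(self, cell_line: str, applied, delta_check: bool = False) -> pd.Series:
        """Total direct-effect vector for one condition."""
        s = pd.Series(0.0, index=self.nodes)
        for drug, label in applied:
            for target in self.target_map[drug]:
                s[target] += self.s_spec[(cell_line, drug, label, target)]
        return s


def _is_identifiable(truth: "GroundTruth", design: StudyDesign) -> bool:
    """Check that noiseless data pin down every row's parameters uniquely.

    For each cell line and node, the least-squares design (source-node
    response rows plus per-(drug, dose) applied-indicator columns) must have
    full column rank, otherwise the exact-fit solution is not unique and
    parameter recovery is impossible even without noise.
    """
    cond_list = list(design.conditions.values())
    for line in truth.cell_lines:
        R = {}
        for applied in cond_list:
            resp = simulate_response(truth.r[line], truth.s_vector(line, applied))
            for node in truth.nodes:
                R.setdefault(node, []).append(resp[node])
        edges = truth.r[line].edges()
        for node in truth.nodes:
            cols = [np.asarray(R[j]) for (i, j) in edges if i == node]
            svar_labels = sorted(
                {
                    (d, lab)
                    for applied in cond_list
                    for d, lab in applied
                    if node in truth.target_map.get(d, [])
                }
            )
            for d, lab in svar_labels:
                cols.append(
                    np.asarray(
                        [1.0 if (d, lab) in applied else 0.0 for applied in cond_list]
                    )
                )
            if cols:
                A = np.column_stack(cols)
                if np.linalg.matrix_rank(A, tol=1e-8) < A.shape[1]:
                    return False
    return True


def _sample_topology(rng, nodes, n_edges, weight_range):
    pool = [(i, j) for i in nodes for j in nodes if i != j]
    idx = rng.choice(len(pool), size=n_edges, replace=False)
    edges = {}
    for k in idx:
        w = rng.uniform(*weight_range) * rng.choice([-1.0, 1.0])
        edges[pool[k]] = float(w)
    return edges


def generate_ground_truth(
    design: StudyDesign,
    n_edges: int = 16,
    n_diffs: int = 13,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.3, 1.2),
    diff_factor_range: tuple[float, float] = (1.5, 3.0),
    target_map: dict[str, list[str]] | None = None,
    expand_mek_children: bool = True,
    k_m_range: tuple[float, float] = (1.0, 3.0),
    ensure_identifiable: bool = True,
    max_retries: int = 100,
) -> GroundTruth:
    """Sample a shared random topology plus ``n_diffs`` planted differences.

    Differences multiply (or divide) the second line's coefficient by a factor
    in ``diff_factor_range``; a perturbation difference scales both dose levels
    of one (drug, target) pair, preserving 0 > s(IC50) > s(IC90).
    """
    nodes = design.nodes
    n = len(nodes)
    if n_edges > n * (n - 1):
        raise ValueError(f"n_edges={n_edges} exceeds {n * (n - 1)} possible edges")
    rng = np.random.default_rng(seed)
    base_map = {d: list(t) for d, t in (target_map or DEFAULT_TARGET_MAP).items()}
    base_map = {d: base_map.get(d, []) for d in design.drugs}
    for d, targets in base_map.items():
        unknown = [t for t in targets if t not in nodes]
        if unknown:
            raise ValueError(f"drug {d} targets unmeasured nodes {unknown}")

    measured = design.measured_doses()

    for _ in range(max_retries):
        edges = _sample_topology(rng, nodes, n_edges, weight_range)
        resolved_map = {d: list(t) for d, t in base_map.items()}
        if expand_mek_children and "MEKi" in resolved_map and "MEK1" in nodes:
            children = sorted({i for (i, j) in edges if j == "MEK1"})
            resolved_map["MEKi"] = sorted(set(resolved_map["MEKi"]) | set(children))
        drug_target_pairs = sorted(
            (d, t) for d in design.drugs for t in resolved_map.get(d, []) if d in measured
        )
        if n_diffs > n_edges + len(drug_target_pairs):
            raise ValueError(
                f"n_diffs={n_diffs} exceeds {n_edges} edges + {len(drug_target_pairs)} perturbation pairs"
            )

        line_a, line_b = design.cell_lines[0], design.cell_lines[1] if len(design.cell_lines) > 1 else design.cell_lines[0]
        edges_b = dict(edges)
        s_spec: dict[tuple[str, str, str, str], float] = {}
        for drug, t_list in resolved_map.items():
            if drug not in measured:
                continue
            for target in t_list:
                s90 = -float(rng.uniform(0.5, 2.0))
                s50 = s90 * float(rng.uniform(0.3, 0.7))
                for line in design.cell_lines:
                    if "IC90" in measured[drug]:
                        s_spec[(line, drug, "IC90", target)] = s90
                    if "IC50" in measured[drug]:
                        s_spec[(line, drug, "IC50", target)] = s50

        # Plant differences on the second line.
        diff_pool = [("edge", e) for e in sorted(edges)] + [
            ("perturbation", p) for p in drug_target_pairs
        ]
        planted: list[tuple[str, tuple]] = []
        if n_diffs > 0 and len(design.cell_lines) > 1:
            chosen = rng.choice(len(diff_pool), size=n_diffs, replace=False)
            for k in sorted(chosen):
                kind, key = diff_pool[k]
                factor = float(rng.uniform(*diff_factor_range))
                if rng.random() < 0.5:
                    factor = 1.0 / factor
                if kind == "edge":
                    edges_b[key] = edges_b[key] * factor
                else:
                    drug, target = key
                    for label in measured[drug]:
                        s_spec[(line_b, drug, label, target)] *= factor
                planted.append((kind, key))

        r_by_line = {}
        ok = True
        for line, edge_map in [(line_a, edges)] + [
            (ln, edges_b) for ln in design.cell_lines[1:]
        ]:
            im = InteractionMatrix.from_edges(nodes, edge_map, cell_line=line)
            arr = im.values.to_numpy()
            if np.linalg.cond(arr) > 1e8:
                ok = False
                break
            r_by_line[line] = im
        if not ok:
            continue

        k_m = {
            line: (float(rng.uniform(*k_m_range)), float(rng.uniform(*k_m_range)))
            for line in design.cell_lines
        }

        candidate = GroundTruth(
            nodes=nodes,
            cell_lines=list(design.cell_lines),
            r=r_by_line,
            s_spec=s_spec,
            target_map=resolved_map,
            k_m=k_m,
            planted_diffs=planted,
        )

        # The saturating viability model needs 1 - R_AKT/K - R_ERK/K > 0 at
        # every training condition; reject truths whose network amplification
        # pushes responses outside that regime.
        if "AKT1" in nodes and "ERK1" in nodes:
            ok = True
            for line in design.cell_lines:
                ka, ke = k_m[line]
                for applied in design.conditions.values():
                    R = simulate_response(r_by_line[line], candidate.s_vector(line, applied))
                    if 1.0 - R["AKT1"] / ka - R["ERK1"] / ke < 0.2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue

        if ensure_identifiable and not _is_identifiable(candidate, design):
            continue

        return candidate
    raise RuntimeError(f"could not sample an invertible topology in {max_retries} tries")


def simulate_dataset(
    truth: GroundTruth,
    design: StudyDesign,
    noise_sd: float = 0.1,
    viability_noise_sd: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    akt_node: str = "AKT1",
    erk_node: str = "ERK1",
) -> tuple[dict[str, ResponseMatrix], pd.DataFrame]:
    """Simulate noisy response matrices and a replicate-level viability table.

    Responses: per condition, R = -inv(r) @ s plus iid Gaussian noise on the
    log2 scale.  Viability: form-4c model evaluated on the *noiseless* pAKT
    and pERK responses, plus truncated Gaussian noise per replicate.
    """
    if noise_sd < 0 or viability_noise_sd < 0:
        raise ValueError("noise standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    cond_ids = list(design.conditions)
    responses: dict[str, ResponseMatrix] = {}
    via_rows = []
    for line in design.cell_lines:
        cols = {}
        for cid in cond_ids:
            s = truth.s_vector(line, design.conditions[cid])
            R = simulate_response(truth.r[line], s)
            cols[cid] = R
            ka, ke = truth.k_m[line]
            r_akt = R[akt_node] if akt_node in R.index else 0.0
            r_erk = R[erk_node] if erk_node in R.index else 0.0
            v_true = float(
                predict_viability("4c", {"K_AKT": ka, "K_ERK": ke}, r_akt, r_erk)
            )
            for rep in range(replicates):
                v = v_true + rng.normal(0.0, viability_noise_sd) if viability_noise_sd > 0 else v_true
                via_rows.append((cid, line, rep, max(v, 0.0)))
        mat = pd.DataFrame(cols, index=truth.nodes)
        if noise_sd > 0:
            mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
        responses[line] = ResponseMatrix(mat, cell_line=line)
    viability = pd.DataFrame(
        via_rows, columns=["condition", "cell_line", "replicate", "viability"]
    )
    return responses, viability
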