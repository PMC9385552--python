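"""Simulate and optimize unseen multi-drug combinations.

For each cell line, the response to drugs A+B+C at normalized concentrations
c is R = -inv(r) @ (s_A(c_A) + s_B(c_B) + s_C(c_C)), where each s is the
fitted concentration-inhibition curve summed over the drug's direct targets;
viability follows the fitted signaling-to-viability model.  Selectivity is
the difference in predicted viability between the two cell lines.

Concentration optimization (per drug capped at its IC10) uses multi-start
SLSQP seeded from a coarse feasibility grid, which tests validate against a
dense grid oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .dose import DoseResponseParams
from .mra import InteractionMatrix
from .viability import predict_viability

__all__ = [
    "CellLineModel",
    "ComboPrediction",
    "OptimizerConfig",
    "simulate_combo",
    "optimize_selectivity",
    "select_controls",
    "rank_all_triples",
    "power_analysis",
    "search_space_size",
    "validation_stats",
]


@dataclass
class CellLineModel:
    """Everything needed to predict one cell line's viability at arbitrary doses."""

    name: str
    r: InteractionMatrix
    dose_params: dict[tuple[str, str], DoseResponseParams]  # (drug, target) -> curve
    k_m_akt: float
    k_m_erk: float
    akt_node: str = "AKT1"
    erk_node: str = "ERK1"
    form: str = "4c"
    _rinv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        arr = self.r.values.to_numpy()
        if np.linalg.matrix_rank(arr) < arr.shape[0]:
            raise np.linalg.LinAlgError(f"singular interaction matrix for {self.name}")
        self._rinv = np.linalg.inv(arr)

    @property
    def drugs(self) -> list[str]:
        return sorted({d for d, _ in self.dose_params})

    def response_contribution(self, node: str, drug: str, conc) -> np.ndarray:
        """Contribution of one drug at concentration(s) ``conc`` to one node's
        log2FC: -sum_t rinv[node, t] * s_t(conc)."""
        i = self.r.nodes.index(node)
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError("concentration outside [0, 1]: no extrapolation")
        acc = np.zeros_like(c, dtype=float)
        found = False
        for (d, target), p in self.dose_params.items():
            if d != drug:
                continue
            found = True
            t = self.r.nodes.index(target)
            acc = acc - self._rinv[i, t] * (p.imax * c / (p.ki + c))
        if not found:
            raise KeyError(f"no dose parameters for drug {drug!r} in line {self.name}")
        return acc

    def viability_at(self, drugs: Sequence[str], conc) -> np.ndarray:
        """Predicted viability for given per-drug concentration arrays."""
        conc = [np.asarray(c, dtype=float) for c in conc]
        ra = sum(self.response_contribution(self.akt_node, d, c) for d, c in zip(drugs, conc))
        re = sum(self.response_contribution(self.erk_node, d, c) for d, c in zip(drugs, conc))
        return predict_viability(
            self.form, {"K_AKT": self.k_m_akt, "K_ERK": self.k_m_erk}, ra, re, strict=False
        )


@dataclass
class ComboPrediction:
    drugs: tuple[str, ...]
    conc: dict[str, float]
    v: dict[str, float]  # cell line -> predicted viability
    selectivity: float  # v_first_line - v_second_line
    anti_selectivity: float
    objective: float = float("nan")
    success: bool = True
    message: str = ""


@dataclass
class OptimizerConfig:
    v_min: float = 0.8
    conc_cap: Mapping[str, float] | float = 1.0  # per-drug cap (normalized IC10)
    n_starts: int = 6
    grid_resolution: int = 5
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 < self.v_min < 1:
            raise ValueError("v_min must be in (0, 1)")

    def cap_for(self, drug: str) -> float:
        cap = self.conc_cap[drug] if isinstance(self.conc_cap, Mapping) else float(self.conc_cap)
        if not 0 < cap <= 1:
            raise ValueError(f"concentration cap for {drug} must be in (0, 1]")
        return cap


def _line_pair(models: Mapping[str, CellLineModel]) -> tuple[str, str]:
    lines = list(models)
    if len(lines) != 2:
        raise ValueError("selectivity needs exactly two cell-line models")
    return lines[0], lines[1]


def simulate_combo(
    models: Mapping[str, CellLineModel],
    drugs: Sequence[str],
    conc: Mapping[str, float],
) -> ComboPrediction:
    """Predict both lines' viability for one combination at fixed doses.

    The first model in ``models`` is the reference (parental) line:
    selectivity = v_first - v_second; anti-selectivity is its negation.
    """
    first, second = _line_pair(models)
    drugs = tuple(drugs)
    cvec = [float(conc[d]) for d in drugs]
    v = {
        ln: float(models[ln].viability_at(drugs, [np.asarray(c) for c in cvec]))
        for ln in (first, second)
    }
    sel = v[first] - v[second]
    return ComboPrediction(
        drugs=drugs,
        conc={d: c for d, c in zip(drugs, cvec)},
        v=v,
        selectivity=sel,
        anti_selectivity=-sel,
    )


def _grid_eval(models, drugs, caps, n_points):
    """Vectorized viability of both lines on a full product grid."""
    axes = [np.linspace(0.0, cap, n_points) for cap in caps]
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = [m.ravel() for m in mesh]
    vs = {ln: models[ln].viability_at(drugs, flat) for ln in models}
    return flat, vs


def _refine(models, drugs, caps, objective, constraint, x0, tol):
    bounds = [(0.0, cap) for cap in caps]
    cons = [{"type": "ineq", "fun": constraint}] if constraint is not None else []
    res = minimize(
        objective, x0=np.asarray(x0, dtype=float), method="SLSQP",
        bounds=bounds, constraints=cons,
        options={"maxiter": 200, "ftol": tol},
    )
    x = np.clip(res.x, 0.0, caps)
    return x, float(objective(x)), res


def optimize_selectivity(
    models: Mapping[str, CellLineModel],
    drugs: Sequence[str],
    direction: str = "anti_selective",
    config: OptimizerConfig | None = None,
) -> ComboPrediction:
    """Find doses minimizing one line's viability with the other protected.

    ``direction="selective"`` minimizes the second (mutant) line's viability
    keeping the first (parental) line above ``v_min``; ``"anti_selective"``
    swaps the roles.  Multi-start local optimization from a coarse grid.
    """
    config = config or OptimizerConfig()
    first, second = _line_pair(models)
    if direction == "selective":
        x_line, y_line = second, first
    elif direction == "anti_selective":
        x_line, y_line = first, second
    else:
        raise ValueError("direction must be 'selective' or 'anti_selective'")
    drugs = tuple(drugs)
    caps = np.array([config.cap_for(d) for d in drugs])

    def v_of(line, x):
        return float(models[line].viability_at(drugs, [np.asarray(c) for c in x]))

    objective = lambda x: v_of(x_line, x)
    constraint = lambda x: v_of(y_line, x) - config.v_min

    flat, vs = _grid_eval(models, drugs, caps, config.grid_resolution)
    vx, vy = vs[x_line], vs[y_line]
    feasible = vy >= config.v_min - 1e-12
    order = np.argsort(np.where(feasible, vx, np.inf))
    starts = [np.array([f[k] for f in flat]) for k in order[: config.n_starts]]
    starts.append(np.zeros(len(drugs)))

    best_x, best_obj = np.zeros(len(drugs)), 1.0  # zero dose is always feasible
    for x0 in starts:
        x, obj, _ = _refine(models, drugs, caps, objective, constraint, x0, config.tol)
        if constraint(x) >= -1e-6 and obj < best_obj:
            best_x, best_obj = x, obj

    pred = simulate_combo(models, drugs, dict(zip(drugs, best_x)))
    pred.objective = best_obj
    return pred


def select_controls(
    models: Mapping[str, CellLineModel],
    drugs: Sequence[str],
    config: OptimizerConfig | None = None,
    target_v: float = 0.8,
) -> ComboPrediction:
    """Doses bringing both lines as close as possible to the target viability."""
    config = config or OptimizerConfig()
    first, second = _line_pair(models)
    drugs = tuple(drugs)
    caps = np.array([config.cap_for(d) for d in drugs])

    def objective(x):
        cvec = [np.asarray(c) for c in x]
        vx = float(models[first].viability_at(drugs, cvec))
        vy = float(models[second].viability_at(drugs, cvec))
        return (vx - target_v) ** 2 + (vy - target_v) ** 2

    flat, vs = _grid_eval(models, drugs, caps, config.grid_resolution)
    grid_obj = (vs[first] - target_v) ** 2 + (vs[second] - target_v) ** 2
    order = np.argsort(grid_obj)
    starts = [np.array([f[k] for f in flat]) for k in order[: config.n_starts]]

    best_x = starts[0]
    best_obj = float(objective(best_x))
    for x0 in starts:
        x, obj, _ = _refine(models, drugs, caps, objective, None, x0, config.tol)
        if obj < best_obj:
            best_x, best_obj = x, obj

    pred = simulate_combo(models, drugs, dict(zip(drugs, best_x)))
    pred.objective = best_obj
    return pred


def rank_all_triples(
    models: Mapping[str, CellLineModel],
    direction: str = "anti_selective",
    config: OptimizerConfig | None = None,
    anti_selectivity_floor: float = 0.1,
    drugs: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[ComboPrediction]]:
    """Optimize every 3-drug combination and rank by achieved (anti-)selectivity.

    Returns the full ranked table (with a ``passes_floor`` column) and the
    per-triple predictions; per-triple failures are recorded, not raised.
    """
    config = config or OptimizerConfig()
    if drugs is None:
        sets = [set(m.drugs) for m in models.values()]
        drugs = sorted(set.intersection(*sets))
    if len(drugs) < 3:
        raise ValueError("need at least three drugs")
    preds = []
    rows = []
    for triple in itertools.combinations(drugs, 3):
        try:
            pred = optimize_selectivity(models, triple, direction, config)
        except Exception as exc:  # per-triple failures are collected
            pred = ComboPrediction(
                drugs=triple, conc={}, v={}, selectivity=float("nan"),
                anti_selectivity=float("nan"), success=False, message=str(exc),
            )
        preds.append(pred)
        score = pred.anti_selectivity if direction == "anti_selective" else pred.selectivity
        row = {
            "drugs": "+".join(triple),
            "score": score,
            "selectivity": pred.selectivity,
            "anti_selectivity": pred.anti_selectivity,
            "success": pred.success,
        }
        for d in triple:
            row[f"conc_{d}"] = pred.conc.get(d, float("nan"))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("score", ascending=False, ignore_index=True)
    table["passes_floor"] = table["score"] > anti_selectivity_floor
    preds.sort(
        key=lambda p: (
            p.anti_selectivity if direction == "anti_selective" else p.selectivity
        )
        if p.success and not math.isnan(p.selectivity)
        else -math.inf,
        reverse=True,
    )
    return table, preds


def power_analysis(
    group_a: Sequence[float],
    group_b: Sequence[float],
    noise_sd: float = 0.25,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of noisy re-simulations with a significant group difference.

    Per simulation, iid Gaussian noise is added to each combination's
    predicted selectivity and the groups are compared by a two-sided
    rank-sum test at ``alpha``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        na = a + rng.normal(0.0, noise_sd, size=a.shape)
        nb = b + rng.normal(0.0, noise_sd, size=b.shape)
        if stats.ranksums(na, nb).pvalue < alpha:
            hits += 1
    return hits / n_sims


def search_space_size(n_drugs: int, k: int, n_conc: int) -> int:
    """Number of k-drug combinations times concentration grid size per drug."""
    if not 0 <= k <= n_drugs:
        raise ValueError("need 0 <= k <= n_drugs")
    if n_conc < 1:
        raise ValueError("n_conc must be at least 1")
    return math.comb(n_drugs, k) * n_conc**k


def validation_stats(
    measured: pd.DataFrame,
    groups: Mapping[str, str],
    parental: str,
    mutant: str,
    references: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Statistics for validation experiments.

    ``measured`` has columns (combo, cell_line, replicate, viability);
    ``groups`` maps combo -> group label (e.g. "anti_selective"/"control");
    ``references`` optionally maps combo -> a monotherapy anti-selectivity
    to test against.  Per combo: mean anti-selectivity (mutant - parental,
    paired by replicate) and one-sided t-tests vs zero / vs the reference.
    Groups are compared by a two-sided rank-sum test on per-combo means.
    """
    required = {"combo", "cell_line", "replicate", "viability"}
    if not required.issubset(measured.columns):
        raise ValueError(f"measured table needs columns {sorted(required)}")
    rows = []
    for combo, sub in measured.groupby("combo"):
        piv = sub.pivot_table(
            index="replicate", columns="cell_line", values="viability", aggfunc="mean"
        )
        if parental not in piv.columns or mutant not in piv.columns:
            raise ValueError(f"combo {combo!r} lacks measurements for both lines")
        anti = (piv[mutant] - piv[parental]).dropna().to_numpy()
        row = {
            "combo": combo,
            "group": groups.get(combo, ""),
            "n_replicates": len(anti),
            "anti_selectivity_mean": float(np.mean(anti)),
        }
        if len(anti) >= 2:
            row["p_vs_zero"] = float(
                stats.ttest_1samp(anti, 0.0, alternative="greater").pvalue
            )
            if references and combo in references:
                row["p_vs_reference"] = float(
                    stats.ttest_1samp(anti, references[combo], alternative="greater").pvalue
                )
        else:
            row["p_vs_zero"] = float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    labels = sorted(set(groups.values()))
    summary: dict = {}
    if len(labels) == 2:
        g0 = table.loc[table["group"] == labels[0], "anti_selectivity_mean"]
        g1 = table.loc[table["group"] == labels[1], "anti_selectivity_mean"]
        if len(g0) and len(g1):
            res = stats.ranksums(g0, g1)
            summary = {"group_test": "ranksums", "statistic": float(res.statistic), "pvalue": float(res.pvalue)}
    return table, summary
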