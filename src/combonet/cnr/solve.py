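"""Exact solution of the reconstruction program.

The objective (summed squared residuals + eta per active edge + theta per
between-line difference) and every constraint decompose over network nodes:
the residuals of node i involve only i's incoming edge weights and the direct
effects targeting i.  Each per-node subproblem is solved exactly by branch
and bound over its binary indicators; for each full indicator assignment the
continuous part is a linearly-constrained least-squares problem.

Dose-ordering constraints 0 > s(IC50) > s(IC90) (with strictness margin
delta) are reparametrized as non-negative slack variables, turning the
continuous subproblem into a box-constrained least-squares solve.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear
from scipy.stats import pearsonr

from ..mra import InteractionMatrix, PerturbationMatrix, ResidualMatrix, residuals, rms_of_residuals
from .problem import CNRProblem, RowSpec

_TOL = 1e-9


@dataclass
class CNRResult:
    """Solution of the reconstruction program."""

    lines: list[str]
    nodes: list[str]
    conditions: list[str]
    r: dict[str, InteractionMatrix]
    # (cell_line, drug, dose_label, target) -> direct effect
    s_values: dict[tuple[str, str, str, str], float]
    indicators: dict[tuple, int]
    residuals: dict[str, ResidualMatrix]
    ssr: float
    objective: float
    rms: float
    status: str
    fit_correlation: float
    hyper: object = None
    applied: dict[str, tuple] = field(default_factory=dict)

    def perturbation_matrix(self, line: str) -> PerturbationMatrix:
        vals = pd.DataFrame(0.0, index=self.nodes, columns=self.conditions)
        for cid in self.conditions:
            for drug, label in self.applied[cid]:
                for node in self.nodes:
                    key = (line, drug, label, node)
                    if key in self.s_values:
                        vals.loc[node, cid] += self.s_values[key]
        return PerturbationMatrix(vals, cell_line=line)

    def predicted_responses(self, line: str) -> pd.DataFrame:
        S = self.perturbation_matrix(line).values.to_numpy()
        sol = np.linalg.solve(self.r[line].values.to_numpy(), -S)
        return pd.DataFrame(sol, index=self.nodes, columns=self.conditions)

    def active_edges(self) -> list[tuple[str, str]]:
        return sorted(k[1] for k, v in self.indicators.items() if k[0] == "edge" and v)

    def active_differences(self) -> set[tuple]:
        return {k for k, v in self.indicators.items() if k[0] in ("diff", "sdiff") and v}


class _RowSolver:
    """Branch-and-bound solver for one node's subproblem."""

    def __init__(self, problem: CNRProblem, row: RowSpec):
        self.problem = problem
        self.row = row
        self.lines = problem.lines
        self.n_cond = len(problem.conditions)
        self.theta_finite = math.isfinite(problem.hyper.theta)
        self.b_raw = {
            ln: problem.R[ln].values.loc[row.node].to_numpy(dtype=float)
            for ln in self.lines
        }
        self.src_rows = {
            ln: {j: problem.R[ln].values.loc[j].to_numpy(dtype=float) for j in row.sources}
            for ln in self.lines
        }
        # For each svar drug: per condition, the level index applied (or -1).
        self.level_by_cond: dict[str, np.ndarray] = {}
        for drug, labels in row.svars:
            lv = np.full(self.n_cond, -1, dtype=int)
            for c_idx, cid in enumerate(problem.conditions):
                for d, lab in problem.applied[cid]:
                    if d == drug and row.node in [
                        t for t in problem.drug_target_map[d] if t in problem.nodes
                    ]:
                        lv[c_idx] = labels.index(lab)
            self.level_by_cond[drug] = lv
        self._cache: dict[frozenset, tuple] = {}

    # -- continuous subproblem ------------------------------------------------

    def solve_assignment(self, assign: dict) -> tuple:
        """Return (ssr, rvals, svals) for a full indicator assignment."""
        key = frozenset(assign.items())
        if key in self._cache:
            return self._cache[key]
        row, prob = self.row, self.problem
        delta, B = prob.delta, prob.bound
        nL, nC = len(self.lines), self.n_cond
        cols: list[np.ndarray] = []
        lb: list[float] = []
        ub: list[float] = []
        meta: list[tuple] = []  # ('r', j, line|None) or ('u', drug, level, line|None)

        for j in row.sources:
            if not assign.get(("edge", j), 0):
                continue
            per_line = bool(assign.get(("diff", j), 0))
            groups = [[ln] for ln in self.lines] if per_line else [self.lines]
            for grp in groups:
                col = np.zeros(nL * nC)
                for ln in grp:
                    x = self.lines.index(ln)
                    col[x * nC : (x + 1) * nC] = self.src_rows[ln][j]
                cols.append(col)
                lb.append(-B)
                ub.append(B)
                meta.append(("r", j, grp[0] if per_line else None))

        const = np.zeros(nL * nC)
        for drug, labels in row.svars:
            lv = self.level_by_cond[drug]
            per_line = bool(assign.get(("sdiff", drug), 0))
            groups = [[ln] for ln in self.lines] if per_line else [self.lines]
            for grp in groups:
                mask_line = np.zeros(nL * nC, dtype=bool)
                for ln in grp:
                    x = self.lines.index(ln)
                    mask_line[x * nC : (x + 1) * nC] = True
                for level in range(len(labels)):
                    col = np.zeros(nL * nC)
                    hit = np.tile(lv >= level, nL) & mask_line
                    col[hit] = -1.0
                    cols.append(col)
                    lb.append(0.0)
                    ub.append(2 * B)
                    meta.append(("u", drug, level, grp[0] if per_line else None))
            offs = np.where(lv >= 0, -(lv + 1) * delta, 0.0)
            const += np.tile(offs, nL)

        b = np.concatenate([self.b_raw[ln] for ln in self.lines]) - const

        if not cols:
            ssr = float(np.sum(b**2))
            out = (ssr, {}, self._svals_from({}, assign))
            self._cache[key] = out
            return out

        A = np.column_stack(cols)
        lo, hi = np.array(lb), np.array(ub)
        x, _, _, _ = np.linalg.lstsq(A, b, rcond=None)
        if np.all(x >= lo - 1e-10) and np.all(x <= hi + 1e-10):
            x = np.clip(x, lo, hi)
        else:
            try:
                res = lsq_linear(A, b, bounds=(lo, hi), method="bvls", tol=1e-14)
            except (ValueError, np.linalg.LinAlgError):
                res = lsq_linear(A, b, bounds=(lo, hi), method="trf", tol=1e-14)
            x = res.x
        ssr = float(np.sum((A @ x - b) ** 2))

        rvals: dict[tuple[str, str], float] = {}
        uvals: dict[tuple[str, int, str | None], float] = {}
        for val, m in zip(x, meta):
            if m[0] == "r":
                _, j, ln = m
                for line in self.lines if ln is None else [ln]:
                    rvals[(line, j)] = float(val)
            else:
                _, drug, level, ln = m
                uvals[(drug, level, ln)] = float(val)
        out = (ssr, rvals, self._svals_from(uvals, assign))
        self._cache[key] = out
        return out

    def _svals_from(self, uvals, assign) -> dict[tuple[str, str, str], float]:
        """Map slack variables back to s-values: s_k = -(k+1)*delta - sum(u_0..u_k)."""
        delta = self.problem.delta
        svals = {}
        for drug, labels in self.row.svars:
            per_line = bool(assign.get(("sdiff", drug), 0))
            for line in self.lines:
                grp = line if per_line else None
                acc = 0.0
                for level, label in enumerate(labels):
                    acc += uvals.get((drug, level, grp), 0.0)
                    svals[(line, drug, label)] = -(level + 1) * delta - acc
        return svals

    # -- discrete search ------------------------------------------------------

    def _keys(self, overrides: dict) -> tuple[dict, list]:
        fixed: dict[tuple, int] = {}
        for j in self.row.sources:
            if j in self.row.prior_sources:
                fixed[("edge", j)] = 1
        if not self.theta_finite or len(self.lines) < 2:
            for j in self.row.sources:
                fixed.setdefault(("diff", j), 0)
            for drug, _ in self.row.svars:
                fixed.setdefault(("sdiff", drug), 0)
        for k, v in overrides.items():
            fixed[k] = int(v)
        order = []
        for j in self.row.sources:
            if ("edge", j) not in fixed:
                order.append(("edge", j))
        for j in self.row.sources:
            if ("diff", j) not in fixed:
                order.append(("diff", j))
        for drug, _ in self.row.svars:
            if ("sdiff", drug) not in fixed:
                order.append(("sdiff", drug))
        return fixed, order

    def _penalty(self, assign) -> float:
        eta, theta = self.problem.hyper.eta, self.problem.hyper.theta
        n_edges = sum(assign.get(("edge", j), 0) for j in self.row.sources)
        n_diffs = sum(v for k, v in assign.items() if k[0] in ("diff", "sdiff"))
        pen = eta * n_edges
        if n_diffs:
            pen += theta * n_diffs  # inf if theta is inf
        return pen

    def _normalize(self, assign: dict) -> dict:
        """Force diff indicators of absent edges to zero."""
        out = dict(assign)
        for j in self.row.sources:
            if not out.get(("edge", j), 0):
                out[("diff", j)] = 0
        return out

    def solve_enumerate(self, overrides: dict | None = None) -> tuple:
        fixed, order = self._keys(overrides or {})
        best = (math.inf, None)
        for bits in itertools.product((0, 1), repeat=len(order)):
            assign = self._normalize({**fixed, **dict(zip(order, bits))})
            ssr, rv, sv = self.solve_assignment(assign)
            obj = ssr + self._penalty(assign)
            if obj < best[0] - _TOL:
                best = (obj, (assign, ssr, rv, sv))
        return best

    def solve_bnb(self, overrides: dict | None = None, max_nodes: int = 200_000) -> tuple:
        fixed, order = self._keys(overrides or {})
        best_obj = math.inf
        best_sol = None
        visited = 0

        def evaluate(assign):
            nonlocal best_obj, best_sol
            assign = self._normalize(assign)
            ssr, rv, sv = self.solve_assignment(assign)
            obj = ssr + self._penalty(assign)
            if obj < best_obj - _TOL:
                best_obj, best_sol = obj, (assign, ssr, rv, sv)
            return obj

        # Heuristic incumbents.
        evaluate({**fixed, **{k: 0 for k in order}})
        if order:
            evaluate({**fixed, **{k: 1 if k[0] == "edge" else 0 for k in order}})

        def relax(partial):
            """Lower bound: undecided indicators maximally free, penalty only
            for decided-active ones (SSR can only grow on any completion)."""
            assign = dict(partial)
            for k in order:
                if k not in assign:
                    assign[k] = 1
            ssr, _, _ = self.solve_assignment(self._normalize(assign))
            return ssr + self._penalty({k: v for k, v in partial.items()})

        def recurse(partial, depth):
            nonlocal visited
            visited += 1
            if visited > max_nodes:
                raise RuntimeError(
                    f"branch-and-bound node limit exceeded for node {self.row.node}"
                )
            if relax(partial) >= best_obj - 1e-12:
                return
            while depth < len(order):
                k = order[depth]
                if k[0] == "diff" and not partial.get(("edge", k[1]), 1):
                    partial = {**partial, k: 0}
                    depth += 1
                    continue
                for val in (0, 1):
                    recurse({**partial, k: val}, depth + 1)
                return
            evaluate(partial)

        recurse(dict(fixed), 0)
        return best_obj, best_sol


def solve(
    problem: CNRProblem,
    backend: str = "bnb",
    indicator_overrides: dict | None = None,
) -> CNRResult:
    """Solve the reconstruction program to optimality.

    ``backend`` is "bnb" (branch and bound, default) or "enumerate"
    (exhaustive over all indicator assignments; oracle for small instances).
    ``indicator_overrides`` maps global indicator keys — ("edge", (i, j)),
    ("diff", (i, j)), ("sdiff", (drug, target)) — to fixed 0/1 values.
    """
    overrides = indicator_overrides or {}
    per_row_overrides: dict[str, dict] = {row.node: {} for row in problem.rows}
    for key, val in overrides.items():
        kind, ident = key
        if kind in ("edge", "diff"):
            node, j = ident
        elif kind == "sdiff":
            drug, node = ident
            j = drug
        else:
            raise ValueError(f"unknown indicator kind {kind!r}")
        if node not in per_row_overrides:
            raise ValueError(f"indicator {key} references unknown node {node!r}")
        per_row_overrides[node][(kind, j if kind != "sdiff" else drug)] = int(val)

    total_obj = 0.0
    total_ssr = 0.0
    indicators: dict[tuple, int] = {}
    rvals_all: dict[tuple[str, str, str], float] = {}
    svals_all: dict[tuple[str, str, str, str], float] = {}
    for row in problem.rows:
        solver = _RowSolver(problem, row)
        if backend == "enumerate":
            obj, sol = solver.solve_enumerate(per_row_overrides[row.node])
        elif backend == "bnb":
            obj, sol = solver.solve_bnb(per_row_overrides[row.node])
        else:
            raise ValueError(f"unknown backend {backend!r}")
        if sol is None:
            raise RuntimeError(f"no solution found for node {row.node}")
        assign, ssr, rv, sv = sol
        total_obj += obj
        total_ssr += ssr
        for j in row.sources:
            indicators[("edge", (row.node, j))] = assign.get(("edge", j), 0)
            indicators[("diff", (row.node, j))] = assign.get(("diff", j), 0)
        for drug, _ in row.svars:
            indicators[("sdiff", (drug, row.node))] = assign.get(("sdiff", drug), 0)
        for (line, j), val in rv.items():
            rvals_all[(line, row.node, j)] = val
        for (line, drug, label), val in sv.items():
            svals_all[(line, drug, label, row.node)] = val

    r_by_line = {}
    for ln in problem.lines:
        vals = pd.DataFrame(0.0, index=problem.nodes, columns=problem.nodes)
        np.fill_diagonal(vals.values, -1.0)
        for (line, i, j), w in rvals_all.items():
            if line == ln:
                vals.loc[i, j] = w
        r_by_line[ln] = InteractionMatrix(vals, cell_line=ln)

    result = CNRResult(
        lines=problem.lines,
        nodes=problem.nodes,
        conditions=problem.conditions,
        r=r_by_line,
        s_values=svals_all,
        indicators=indicators,
        residuals={},
        ssr=total_ssr,
        objective=total_obj,
        rms=0.0,
        status="optimal",
        fit_correlation=float("nan"),
        hyper=problem.hyper,
        applied=problem.applied,
    )
    eps_by_line = {}
    measured_flat, predicted_flat = [], []
    for ln in problem.lines:
        S = result.perturbation_matrix(ln)
        eps = residuals(r_by_line[ln], S, problem.R[ln])
        eps_by_line[ln] = eps
        measured_flat.append(problem.R[ln].values.to_numpy().ravel())
        try:
            predicted_flat.append(result.predicted_responses(ln).to_numpy().ravel())
        except np.linalg.LinAlgError:
            predicted_flat = None
            break
    result.residuals = eps_by_line
    result.rms = rms_of_residuals(list(eps_by_line.values()))
    if predicted_flat is not None:
        m = np.concatenate(measured_flat)
        p = np.concatenate(predicted_flat)
        if np.std(m) > 0 and np.std(p) > 0:
            result.fit_correlation = float(pearsonr(m, p)[0])
    return result
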