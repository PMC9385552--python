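"""Hyperparameter selection by leave-one-out cross-validation and the final fit.

Only multi-drug conditions are held out: every single-drug condition is
needed to estimate the corresponding direct-effect parameter.  The held-out
response column is predicted from the refit model as -inv(r) @ (sum of the
single-drug direct effects), scored by per-entry mean squared error.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ..mra import ResponseMatrix
from .problem import Hyperparams, build_problem
from .solve import CNRResult, solve


def _drop_condition(R_by_line, cond):
    out = {}
    for ln, R in R_by_line.items():
        out[ln] = ResponseMatrix(R.values.drop(columns=[cond]), cell_line=R.cell_line)
    return out


def _predict_column(result: CNRResult, line: str, applied) -> np.ndarray:
    s = np.zeros(len(result.nodes))
    for drug, label in applied:
        for idx, node in enumerate(result.nodes):
            key = (line, drug, label, node)
            if key in result.s_values:
                s[idx] += result.s_values[key]
    return np.linalg.solve(result.r[line].values.to_numpy(), -s)


def loocv_select_hyperparams(
    R_by_line: Mapping[str, ResponseMatrix],
    prior_edges: Iterable,
    drug_target_map: Mapping[str, list[str]],
    eta_grid: Iterable[float],
    theta_grid: Iterable[float],
    candidate_edges: Iterable | None = None,
    conditions: Mapping | None = None,
    backend: str = "bnb",
    **build_kwargs,
) -> tuple[Hyperparams, list[tuple[str, str]], pd.DataFrame]:
    """Grid-search (eta, theta) by leave-one-out over multi-drug conditions.

    Returns the selected hyperparameters (ties broken toward smaller eta,
    then larger theta: prefer sparser, more-shared models), the non-prior
    edges active in the full refit at that point, and the CV-error table.
    """
    eta_grid = list(eta_grid)
    theta_grid = list(theta_grid)
    if not eta_grid or not theta_grid:
        raise ValueError("hyperparameter grids must be non-empty")

    probe = build_problem(
        R_by_line, prior_edges, drug_target_map,
        Hyperparams(eta_grid[0], theta_grid[0]),
        conditions=conditions, candidate_edges=candidate_edges, **build_kwargs,
    )
    holdouts = [cid for cid in probe.conditions if len(probe.applied[cid]) >= 2]
    if not holdouts:
        raise ValueError("LOOCV needs at least one multi-drug condition")

    records = []
    for eta in eta_grid:
        for theta in theta_grid:
            hp = Hyperparams(eta, theta)
            sq_sum = 0.0
            n_entries = 0
            for cid in holdouts:
                reduced = _drop_condition(R_by_line, cid)
                prob = build_problem(
                    reduced, prior_edges, drug_target_map, hp,
                    conditions={c: probe.applied[c] for c in probe.conditions if c != cid}
                    if conditions is not None else None,
                    candidate_edges=candidate_edges, **build_kwargs,
                )
                fit = solve(prob, backend=backend)
                for ln in prob.lines:
                    pred = _predict_column(fit, ln, probe.applied[cid])
                    obs = R_by_line[ln].values[cid].to_numpy()
                    sq_sum += float(np.sum((pred - obs) ** 2))
                    n_entries += len(obs)
            records.append({"eta": eta, "theta": theta, "cv_mse": sq_sum / n_entries})
    cv = pd.DataFrame(records)

    best_mse = cv["cv_mse"].min()
    near = cv[cv["cv_mse"] <= best_mse + 1e-9]
    near = near.sort_values(["eta", "theta"], ascending=[True, False])
    sel = near.iloc[0]
    hp = Hyperparams(float(sel["eta"]), float(sel["theta"]))

    full = build_problem(
        R_by_line, prior_edges, drug_target_map, hp,
        conditions=conditions, candidate_edges=candidate_edges, **build_kwargs,
    )
    fit = solve(full, backend=backend)
    added = sorted(set(fit.active_edges()) - set(full.prior_edges))
    return hp, added, cv


def final_model(
    R_by_line: Mapping[str, ResponseMatrix],
    topology: Iterable,
    theta: float,
    drug_target_map: Mapping[str, list[str]],
    eta: float = 0.1,
    backend: str = "bnb",
    **build_kwargs,
) -> CNRResult:
    """Refit with the topology fixed; only difference indicators remain free.

    ``theta = math.inf`` forbids differences, giving a shared least-squares
    model on the fixed topology.
    """
    topology = list(topology)
    prob = build_problem(
        R_by_line,
        prior_edges=topology,
        drug_target_map=drug_target_map,
        hyperparams=Hyperparams(eta, theta),
        candidate_edges=topology,
        **build_kwargs,
    )
    return solve(prob, backend=backend)
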