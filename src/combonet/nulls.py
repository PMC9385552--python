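"""Randomization ensembles for assessing the significance of a fitted model.

Three modes:

* ``random_topology`` — refit with random edge sets of fixed size, no
  differences between cell lines allowed.
* ``node_permutation`` — permute the node labels of the input responses,
  keep the actual topology, no differences allowed.
* ``random_differences`` — keep the actual topology and activate a fixed
  number of randomly chosen difference indicators.

Each model's fit is summarized by the root-mean-square of residuals; the
empirical p-value uses the add-one rule (k+1)/(n+1), counting ties as
"at least as good as the reference".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .cnr import Hyperparams, build_problem, solve
from .mra import ResponseMatrix

MODES = ("random_topology", "node_permutation", "random_differences")


@dataclass
class NullEnsemble:
    mode: str
    n_models: int
    rms_values: np.ndarray
    reference_rms: float
    seed: int

    def __post_init__(self) -> None:
        self.rms_values = np.asarray(self.rms_values, dtype=float)
        if len(self.rms_values) != self.n_models:
            raise ValueError("rms_values length does not match n_models")
        if np.any(self.rms_values < 0) or self.reference_rms < 0:
            raise ValueError("RMS values must be non-negative")


def _solve_rms(R_by_line, edges, drug_target_map, overrides=None, theta=math.inf, **kw):
    prob = build_problem(
        R_by_line,
        prior_edges=edges,
        drug_target_map=drug_target_map,
        hyperparams=Hyperparams(0.0, theta),
        candidate_edges=edges,
        **kw,
    )
    return solve(prob, indicator_overrides=overrides).rms


def _permute_nodes(R_by_line, perm: np.ndarray) -> dict[str, ResponseMatrix]:
    out = {}
    for ln, R in R_by_line.items():
        vals = R.values.copy()
        vals.index = [R.nodes[p] for p in perm]
        vals = vals.loc[R.nodes]
        out[ln] = ResponseMatrix(vals, cell_line=R.cell_line)
    return out


def null_ensemble(
    R_by_line: Mapping[str, ResponseMatrix],
    topology: Iterable[tuple[str, str]],
    drug_target_map: Mapping[str, list[str]],
    mode: str,
    n_models: int,
    seed: int = 0,
    n_random_edges: int | None = None,
    n_random_diffs: int | None = None,
    reference_differences: Iterable[tuple] | None = None,
    **build_kwargs,
) -> NullEnsemble:
    """Build a null ensemble and the matching reference RMS.

    ``topology`` is the actual model's edge set.  For ``random_topology``,
    ``n_random_edges`` defaults to the size of the actual topology.  For
    ``random_differences``, ``n_random_diffs`` difference indicators are
    activated uniformly at random among all edge-difference and
    perturbation-difference slots; the reference is the actual model's chosen
    difference set (``reference_differences``), or none.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if n_models < 1:
        raise ValueError("n_models must be at least 1")
    rng = np.random.default_rng(seed)
    topology = sorted(set(topology))
    nodes = next(iter(R_by_line.values())).nodes

    if mode == "random_topology":
        pool = [(i, j) for i in nodes for j in nodes if i != j]
        m = n_random_edges if n_random_edges is not None else len(topology)
        if m > len(pool):
            raise ValueError(f"requested {m} edges but only {len(pool)} candidates exist")
        reference_rms = _solve_rms(R_by_line, topology, drug_target_map, **build_kwargs)
        rms = []
        for _ in range(n_models):
            idx = rng.choice(len(pool), size=m, replace=False)
            edges = [pool[k] for k in idx]
            rms.append(_solve_rms(R_by_line, edges, drug_target_map, **build_kwargs))
    elif mode == "node_permutation":
        reference_rms = _solve_rms(R_by_line, topology, drug_target_map, **build_kwargs)
        rms = []
        for _ in range(n_models):
            perm = rng.permutation(len(nodes))
            permuted = _permute_nodes(R_by_line, perm)
            rms.append(_solve_rms(permuted, topology, drug_target_map, **build_kwargs))
    else:  # random_differences
        if n_random_diffs is None:
            raise ValueError("random_differences mode needs n_random_diffs")
        probe = build_problem(
            R_by_line, topology, drug_target_map,
            Hyperparams(0.0, 1.0), candidate_edges=topology, **build_kwargs,
        )
        slots = [("diff", e) for e in topology]
        for row in probe.rows:
            slots += [("sdiff", (drug, row.node)) for drug, _ in row.svars]
        slots = sorted(set(slots))
        if n_random_diffs > len(slots):
            raise ValueError(f"requested {n_random_diffs} differences but only {len(slots)} slots")
        ref_over = {k: 0 for k in slots}
        for key in reference_differences or []:
            ref_over[tuple(key)] = 1
        reference_rms = _solve_rms(
            R_by_line, topology, drug_target_map, overrides=ref_over, theta=1.0, **build_kwargs
        )
        rms = []
        for _ in range(n_models):
            idx = rng.choice(len(slots), size=n_random_diffs, replace=False)
            overrides = {k: 0 for k in slots}
            for k in idx:
                overrides[slots[k]] = 1
            rms.append(
                _solve_rms(
                    R_by_line, topology, drug_target_map,
                    overrides=overrides, theta=1.0, **build_kwargs,
                )
            )

    return NullEnsemble(
        mode=mode,
        n_models=n_models,
        rms_values=np.array(rms),
        reference_rms=float(reference_rms),
        seed=seed,
    )


def empirical_pvalue(ensemble: NullEnsemble) -> float:
    """p = (k + 1) / (n + 1), k = number of null models fitting at least as
    well (RMS <= reference); ties count toward k."""
    k = int(np.sum(ensemble.rms_values <= ensemble.reference_rms))
    return (k + 1) / (ensemble.n_models + 1)
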