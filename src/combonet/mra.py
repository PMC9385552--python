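"""Modular response analysis data model and forward/residual algebra.

The steady-state relation between a local interaction matrix ``r`` (log-log
partial derivatives, diagonal fixed at -1), direct perturbation effects ``s``
and the measured global response ``R`` (log2 fold changes) is

    r @ R + s = 0          (residual form:  eps = r @ R + s)

so the forward solve is ``R = -inv(r) @ s``.  Inhibitors have ``s < 0`` and,
absent feedback, reduce their own target's activity under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "InteractionMatrix",
    "PerturbationMatrix",
    "ResidualMatrix",
    "residuals",
    "simulate_response",
    "rms_of_residuals",
]


def _check_unique(labels, what: str) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")


@dataclass
class ResponseMatrix:
    """Node x condition grid of log2 fold changes for one cell line."""

    values: pd.DataFrame
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        _check_unique(self.values.index, "node")
        _check_unique(self.values.columns, "condition")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("response matrix contains non-finite entries")

    @property
    def nodes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class InteractionMatrix:
    """Node x node local response coefficients r_ij; diagonal fixed at -1."""

    values: pd.DataFrame
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        if list(self.values.index) != list(self.values.columns):
            raise ValueError("interaction matrix must have identical row/column labels")
        diag = np.diag(self.values.to_numpy())
        if not np.allclose(diag, -1.0, rtol=0, atol=0):
            raise ValueError("interaction matrix diagonal must equal -1 exactly")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("interaction matrix contains non-finite entries")

    @property
    def nodes(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_edges(
        cls, nodes: list[str], edges: dict[tuple[str, str], float], cell_line: str = ""
    ) -> "InteractionMatrix":
        """Build from a {(target, source): weight} edge map."""
        vals = pd.DataFrame(0.0, index=nodes, columns=nodes)
        np.fill_diagonal(vals.values, -1.0)
        for (i, j), w in edges.items():
            if i == j:
                raise ValueError(f"self-loop ({i},{j}) not allowed")
            vals.loc[i, j] = w
        return cls(vals, cell_line)

    def edges(self) -> dict[tuple[str, str], float]:
        out = {}
        arr = self.values.to_numpy()
        nodes = self.nodes
        for a in range(len(nodes)):
            for b in range(len(nodes)):
                if a != b and arr[a, b] != 0.0:
                    out[(nodes[a], nodes[b])] = arr[a, b]
        return out


@dataclass
class PerturbationMatrix:
    """Node x condition grid of scaled direct perturbation effects s_ik."""

    values: pd.DataFrame
    cell_line: str = ""
    support: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        if self.support is not None:
            mask = ~self.support.astype(bool)
            off = self.values.to_numpy()[mask.to_numpy()]
            if np.any(off != 0.0):
                raise ValueError("perturbation effects outside the licensed support")


@dataclass
class ResidualMatrix:
    values: pd.DataFrame
    cell_line: str = ""


def _align(r: InteractionMatrix, s, R: ResponseMatrix):
    s_values = s.values if isinstance(s, PerturbationMatrix) else pd.DataFrame(s)
    if list(r.values.columns) != list(R.values.index):
        raise ValueError("node labels of r and R do not align")
    if list(s_values.index) != list(R.values.index) or list(s_values.columns) != list(
        R.values.columns
    ):
        raise ValueError("labels of s and R do not align")
    return s_values


def residuals(r: InteractionMatrix, s, R: ResponseMatrix) -> ResidualMatrix:
    """eps = r @ R + s, entrywise."""
    s_values = _align(r, s, R)
    eps = r.values.to_numpy() @ R.values.to_numpy() + s_values.to_numpy()
    return ResidualMatrix(
        pd.DataFrame(eps, index=R.values.index, columns=R.values.columns),
        cell_line=R.cell_line,
    )


def simulate_response(r: InteractionMatrix, s_total) -> pd.Series:
    """Solve r @ R + s = 0 for R, i.e. R = -inv(r) @ s_total.

    ``s_total`` is a node-indexed vector of summed direct effects.
    """
    s_vec = pd.Series(s_total)
    if list(s_vec.index) != list(r.nodes):
        s_vec = s_vec.reindex(r.nodes)
        if s_vec.isna().any():
            raise ValueError("s_total index does not match interaction matrix nodes")
    arr = r.values.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[0]:
        raise np.linalg.LinAlgError(
            f"interaction matrix for {r.cell_line or 'cell line'} is singular"
        )
    sol = np.linalg.solve(arr, -s_vec.to_numpy())
    return pd.Series(sol, index=r.nodes)


def rms_of_residuals(eps) -> float:
    """Root mean square over all residual entries.

    Accepts a ResidualMatrix, an array, or an iterable of them (entries pooled).
    """
    if isinstance(eps, (ResidualMatrix,)):
        blocks = [eps.values.to_numpy()]
    elif isinstance(eps, (pd.DataFrame, np.ndarray)):
        blocks = [np.asarray(eps, dtype=float)]
    else:
        blocks = []
        for item in eps:
            if isinstance(item, ResidualMatrix):
                blocks.append(item.values.to_numpy())
            else:
                blocks.append(np.asarray(item, dtype=float))
    flat = np.concatenate([b.ravel() for b in blocks]) if blocks else np.array([])
    if flat.size == 0:
        raise ValueError("cannot compute RMS of an empty residual set")
    return float(np.sqrt(np.mean(flat**2)))
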