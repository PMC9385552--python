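"""Tabular input/output, normalization of raw readouts, and serialization.

Conventions: matrices and tables are TSV with a one-line header; condition
identifiers are strings like ``"DRUG1@IC50+DRUG2@IC50"``; configuration is
YAML; models and results are JSON.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnr import CNRResult
from .mra import InteractionMatrix, ResponseMatrix
from .synthetic import GroundTruth, StudyDesign

# -- raw-readout normalization ------------------------------------------------


def compute_log2fc(treatment: pd.DataFrame, dmso: pd.DataFrame, cell_line: str = "") -> ResponseMatrix:
    """log2(treatment / mean DMSO) per node per condition.

    ``treatment``: nodes x conditions raw readouts; ``dmso``: nodes x
    replicate vehicle readouts.  All readouts must be strictly positive.
    """
    for name, df in (("treatment", treatment), ("DMSO", dmso)):
        bad = df.le(0)
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-positive {name} readout at node {df.index[r]!r}, column {df.columns[c]!r}"
            )
    if list(treatment.index) != list(dmso.index):
        raise ValueError("treatment and DMSO tables have different node labels")
    ref = dmso.mean(axis=1)
    return ResponseMatrix(np.log2(treatment.div(ref, axis=0)), cell_line=cell_line)


def normalize_viability(
    raw: pd.DataFrame,
    dmso_label: str = "DMSO",
    pao_label: str = "PAO",
) -> pd.DataFrame:
    """Plate normalization: v = (treatment - PAO_mean) / (DMSO_mean - PAO_mean).

    ``raw`` has columns (condition, cell_line, replicate, value); DMSO and
    PAO control wells are rows with those condition labels.  Values below
    zero are kept and flagged in a ``below_zero`` column.
    """
    required = {"condition", "cell_line", "replicate", "value"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw table needs columns {sorted(required)}")
    out = []
    for line, sub in raw.groupby("cell_line"):
        dmso = sub.loc[sub["condition"] == dmso_label, "value"]
        pao = sub.loc[sub["condition"] == pao_label, "value"]
        if dmso.empty or pao.empty:
            raise ValueError(f"cell line {line!r} lacks DMSO or PAO control wells")
        d, p = dmso.mean(), pao.mean()
        if d <= p:
            raise ValueError(f"DMSO mean <= PAO mean for cell line {line!r}")
        treat = sub[~sub["condition"].isin([dmso_label, pao_label])].copy()
        treat["viability"] = (treat["value"] - p) / (d - p)
        out.append(treat[["condition", "cell_line", "replicate", "viability"]])
    result = pd.concat(out, ignore_index=True)
    result["below_zero"] = result["viability"] < 0
    return result


# -- tabular round-trips ------------------------------------------------------


def write_response_matrix(R: ResponseMatrix, path) -> None:
    R.values.to_csv(path, sep="\t", index_label="node")


def read_response_matrix(path, cell_line: str = "") -> ResponseMatrix:
    df = pd.read_csv(path, sep="\t", index_col="node", float_precision="round_trip")
    df.index.name = None
    return ResponseMatrix(df, cell_line=cell_line)


def write_viability_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_viability_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_edge_list(r_by_line: dict[str, InteractionMatrix], path) -> None:
    rows = []
    for line, im in r_by_line.items():
        for (i, j), w in sorted(im.edges().items()):
            rows.append((j, i, line, w))
    pd.DataFrame(rows, columns=["source", "target", "cell_line", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> dict[str, InteractionMatrix]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    nodes = sorted(set(df["source"]) | set(df["target"]))
    out = {}
    for line, sub in df.groupby("cell_line"):
        edges = {(r.target, r.source): r.weight for r in sub.itertuples()}
        out[line] = InteractionMatrix.from_edges(nodes, edges, cell_line=line)
    return out


def read_prior_edges(path) -> list[tuple[str, str]]:
    """Prior-topology TSV with columns (source, target)."""
    df = pd.read_csv(path, sep="\t")
    return [(r.target, r.source) for r in df.itertuples()]


# -- JSON serialization -------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def save_design(design: StudyDesign, path) -> None:
    payload = {
        "nodes": design.nodes,
        "drugs": design.drugs,
        "dose_levels": design.dose_levels,
        "conditions": {cid: list(map(list, app)) for cid, app in design.conditions.items()},
        "cell_lines": design.cell_lines,
        "single_dose_drugs": design.single_dose_drugs,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonify))


def load_design(path) -> StudyDesign:
    payload = json.loads(Path(path).read_text())
    return StudyDesign(
        nodes=payload["nodes"],
        drugs=payload["drugs"],
        dose_levels=payload["dose_levels"],
        conditions={
            cid: tuple(tuple(p) for p in app) for cid, app in payload["conditions"].items()
        },
        cell_lines=payload["cell_lines"],
        single_dose_drugs=payload.get("single_dose_drugs", []),
    )


def save_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "nodes": truth.nodes,
        "cell_lines": truth.cell_lines,
        "r": {ln: truth.r[ln].values.to_numpy().tolist() for ln in truth.cell_lines},
        "s_spec": [[list(k), v] for k, v in sorted(truth.s_spec.items())],
        "target_map": truth.target_map,
        "k_m": {ln: list(km) for ln, km in truth.k_m.items()},
        "planted_diffs": [[kind, list(key)] for kind, key in truth.planted_diffs],
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonify))


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    nodes = payload["nodes"]
    r = {
        ln: InteractionMatrix(
            pd.DataFrame(payload["r"][ln], index=nodes, columns=nodes), cell_line=ln
        )
        for ln in payload["cell_lines"]
    }
    return GroundTruth(
        nodes=nodes,
        cell_lines=payload["cell_lines"],
        r=r,
        s_spec={tuple(k): v for k, v in payload["s_spec"]},
        target_map=payload["target_map"],
        k_m={ln: tuple(v) for ln, v in payload["k_m"].items()},
        planted_diffs=[(kind, tuple(key)) for kind, key in payload["planted_diffs"]],
    )


def save_cnr_result(result: CNRResult, path) -> None:
    payload = {
        "lines": result.lines,
        "nodes": result.nodes,
        "conditions": result.conditions,
        "r": {ln: result.r[ln].values.to_numpy().tolist() for ln in result.lines},
        "s_values": [[list(k), v] for k, v in sorted(result.s_values.items())],
        "indicators": [[k[0], list(k[1]), v] for k, v in sorted(result.indicators.items())],
        "objective": None if math.isinf(result.objective) else result.objective,
        "ssr": result.ssr,
        "rms": result.rms,
        "status": result.status,
        "fit_correlation": result.fit_correlation,
        "applied": {cid: list(map(list, app)) for cid, app in result.applied.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonify))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
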