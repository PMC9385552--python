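"""Map short-term signaling response to cell viability.

Six candidate model forms relate the log2 fold changes of pAKT and pERK
(``R_AKT``, ``R_ERK``) to viability ``v`` relative to vehicle control:

========  ==========  ====================================================
form      type        v as a function of responses
========  ==========  ====================================================
``4a``    linear      1 - v = sum_i beta_i * R_i            (all nodes)
``4b``    linear      1 - v = beta_AKT*R_AKT + beta_ERK*R_ERK
``4c``    nonlinear   v = 1 / (1 - R_AKT/K_AKT - R_ERK/K_ERK)
``4d``    nonlinear   v = 1 / ((1 - R_AKT/K_AKT) * (1 - R_ERK/K_ERK))
``4e``    nonlinear   v = 3 / (1 + 2^(-R_ERK/K_ERK) + 2^(-R_AKT/K_AKT))
``4f``    nonlinear   v = 2/(1 + 2^(-R_ERK/K_ERK)) * 2/(1 + 2^(-R_AKT/K_AKT))
========  ==========  ====================================================

For the nonlinear forms the K parameters are the response magnitudes giving a
50% viability reduction (4c, 4d), 25% (4e) or 33% (4f).  Model comparison uses
the mean residual standard error of the full fit and the L2-norm of held-out
residuals from per-cell-line leave-one-out cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .mra import ResponseMatrix

LINEAR_FORMS = ("4a", "4b")
NONLINEAR_FORMS = ("4c", "4d", "4e", "4f")
ALL_FORMS = LINEAR_FORMS + NONLINEAR_FORMS

_K_START_GRID = (0.5, 1.0, 2.0, 4.0)
_POOLED = "__pooled__"


def predict_viability(form, params, r_akt, r_erk, responses=None, strict=True):
    """Evaluate one model form at the given responses.

    ``params`` is the per-group parameter mapping (``{"K_AKT": .., "K_ERK": ..}``
    for nonlinear forms, ``{"beta_<node>": ..}`` for linear).  ``responses`` is
    required for form 4a: a (conditions x nodes) array/DataFrame of all node
    responses.  With ``strict`` the 4c denominator must stay positive.
    """
    r_akt = np.asarray(r_akt, dtype=float)
    r_erk = np.asarray(r_erk, dtype=float)
    if form == "4a":
        if responses is None:
            raise ValueError("form 4a needs the full node-response matrix")
        if isinstance(responses, pd.DataFrame):
            beta = np.asarray([params[f"beta_{n}"] for n in responses.columns])
        else:
            beta = np.asarray([v for k, v in params.items() if k.startswith("beta_")])
        X = np.asarray(responses, dtype=float)
        return 1.0 - X @ beta
    if form == "4b":
        return 1.0 - (params["beta_AKT"] * r_akt + params["beta_ERK"] * r_erk)
    ka, ke = params["K_AKT"], params["K_ERK"]
    if ka <= 0 or ke <= 0:
        raise ValueError("K parameters must be positive")
    if form == "4c":
        den = 1.0 - r_akt / ka - r_erk / ke
        if strict and np.any(den <= 0):
            raise ValueError("form 4c denominator is non-positive at these responses")
        return 1.0 / np.maximum(den, 1e-9)
    if form == "4d":
        da = 1.0 - r_akt / ka
        de = 1.0 - r_erk / ke
        if strict and (np.any(da <= 0) or np.any(de <= 0)):
            raise ValueError("form 4d denominator is non-positive at these responses")
        return 1.0 / (np.maximum(da, 1e-9) * np.maximum(de, 1e-9))
    if form == "4e":
        return 3.0 / (1.0 + 2.0 ** (-r_erk / ke) + 2.0 ** (-r_akt / ka))
    if form == "4f":
        return (2.0 / (1.0 + 2.0 ** (-r_erk / ke))) * (2.0 / (1.0 + 2.0 ** (-r_akt / ka)))
    raise ValueError(f"unknown model form {form!r}")


def mean_viability(viability: pd.DataFrame) -> pd.DataFrame:
    """Average replicate viabilities to one value per (condition, cell line)."""
    required = {"condition", "cell_line", "viability"}
    if not required.issubset(viability.columns):
        raise ValueError(f"viability table needs columns {sorted(required)}")
    if (viability["viability"] < 0).any():
        raise ValueError("negative viability values")
    return (
        viability.groupby(["cell_line", "condition"], sort=False)["viability"]
        .mean()
        .reset_index()
    )


@dataclass
class ViabilityModelFit:
    """Fitted signaling-to-viability model plus fit metrics."""

    form: str
    params: dict[str, dict[str, float]]  # group (cell line or pooled) -> params
    sigma: float
    loocv_l2: float
    per_cell_line: bool
    conditions: dict[str, list[str]]
    n_obs: int
    pvalues: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    bootstrap_cis: dict | None = None

    @property
    def kind(self) -> str:
        return "linear" if self.form in LINEAR_FORMS else "nonlinear"

    def params_for(self, cell_line: str) -> dict[str, float]:
        return self.params[cell_line if self.per_cell_line else _POOLED]

    def predict(self, cell_line, r_akt, r_erk, responses=None, strict=True):
        return predict_viability(
            self.form, self.params_for(cell_line), r_akt, r_erk, responses, strict
        )


def _design_for_line(responses, viability_mean, line, akt_node, erk_node):
    R = responses[line]
    sub = viability_mean[viability_mean["cell_line"] == line]
    conds = [c for c in R.conditions if c in set(sub["condition"])]
    if not conds:
        raise ValueError(f"no overlapping conditions for cell line {line!r}")
    v = sub.set_index("condition").loc[conds, "viability"].to_numpy()
    ra = R.values.loc[akt_node, conds].to_numpy()
    re = R.values.loc[erk_node, conds].to_numpy()
    X_all = R.values.loc[:, conds].T  # conditions x nodes
    return conds, v, ra, re, X_all


def _fit_linear(form, v, ra, re, X_all):
    if form == "4a":
        X = X_all.to_numpy()
        names = [f"beta_{n}" for n in X_all.columns]
    else:
        X = np.column_stack([ra, re])
        names = ["beta_AKT", "beta_ERK"]
    model = sm.OLS(1.0 - v, X).fit()
    params = dict(zip(names, model.params))
    pvalues = dict(zip(names, model.pvalues))
    return params, pvalues


def _fit_nonlinear(form, v, ra, re, starts=None):
    def fun(x):
        pred = predict_viability(form, {"K_AKT": x[0], "K_ERK": x[1]}, ra, re, strict=False)
        return pred - v

    if starts is None:
        starts = [(ka0, ke0) for ka0 in _K_START_GRID for ke0 in _K_START_GRID]
    best = None
    trace = []
    for x0 in starts:
        res = least_squares(
            fun, x0=list(x0), bounds=(1e-8, np.inf), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        trace.append((x0, res.status, res.cost))
        if res.status > 0 and (best is None or res.cost < best.cost - 0.0):
            best = res
    if best is None:
        raise RuntimeError(f"nonlinear fit of form {form} did not converge; starts tried: {trace}")
    return {"K_AKT": float(best.x[0]), "K_ERK": float(best.x[1])}


def _fit_groups(form, groups, starts_by_group=None):
    """groups: {name: (v, ra, re, X_all)} -> (params, pvalues, ssr, n, p)."""
    params, pvalues = {}, {}
    ssr = 0.0
    n = 0
    p = 0
    for name, (v, ra, re, X_all) in groups.items():
        if form in LINEAR_FORMS:
            prm, pv = _fit_linear(form, v, ra, re, X_all)
            pvalues[name] = pv
        else:
            starts = starts_by_group.get(name) if starts_by_group else None
            prm = _fit_nonlinear(form, v, ra, re, starts=starts)
        params[name] = prm
        pred = predict_viability(
            form, prm, ra, re, responses=X_all if form == "4a" else None, strict=False
        )
        ssr += float(np.sum((pred - v) ** 2))
        n += len(v)
        p += len(prm)
    return params, pvalues, ssr, n, p


def fit_viability_model(
    responses: Mapping[str, ResponseMatrix],
    viability: pd.DataFrame,
    form: str = "4c",
    per_cell_line: bool = True,
    akt_node: str = "AKT1",
    erk_node: str = "ERK1",
    compute_loocv: bool = True,
) -> ViabilityModelFit:
    """Fit one model form to replicate-averaged viability data.

    Replicates are averaged per condition before fitting.  With
    ``per_cell_line`` separate parameters are fitted for each line; otherwise
    a single pooled parameter set is used.
    """
    if form not in ALL_FORMS:
        raise ValueError(f"unknown model form {form!r}")
    vmean = mean_viability(viability)
    lines = list(responses)
    data = {ln: _design_for_line(responses, vmean, ln, akt_node, erk_node) for ln in lines}
    n_total = sum(len(d[1]) for d in data.values())
    n_params = 2 if form != "4a" else len(next(iter(responses.values())).nodes)
    min_obs = (n_params * (len(lines) if per_cell_line else 1)) + 1
    if n_total < min_obs:
        raise ValueError(f"need at least {min_obs} conditions, got {n_total}")

    def groups_of(data_by_line):
        if per_cell_line:
            return {ln: d[1:] for ln, d in data_by_line.items()}
        v = np.concatenate([d[1] for d in data_by_line.values()])
        ra = np.concatenate([d[2] for d in data_by_line.values()])
        re = np.concatenate([d[3] for d in data_by_line.values()])
        X = pd.concat([d[4] for d in data_by_line.values()], axis=0)
        return {_POOLED: (v, ra, re, X)}

    params, pvalues, ssr, n, p = _fit_groups(form, groups_of(data))
    dof = max(n - p, 1)
    sigma = math.sqrt(ssr / dof)

    flags = []
    for grp, prm in params.items():
        for key, val in prm.items():
            if key.startswith("K_") and val <= 1e-7:
                flags.append(f"{grp}:{key} at lower bound")

    # Warm starts for refits: the full-data optimum plus one grid point.
    warm = None
    if form in NONLINEAR_FORMS:
        warm = {
            grp: [(prm["K_AKT"], prm["K_ERK"]), (1.0, 1.0)]
            for grp, prm in params.items()
        }

    loocv_l2 = float("nan")
    if compute_loocv:
        sq = 0.0
        for ln in lines:
            conds, v, ra, re, X_all = data[ln]
            for idx in range(len(conds)):
                keep = np.arange(len(conds)) != idx
                held_data = dict(data)
                held_data[ln] = (
                    [c for k, c in zip(keep, conds) if k],
                    v[keep],
                    ra[keep],
                    re[keep],
                    X_all.iloc[keep],
                )
                prm_cv, _, _, _, _ = _fit_groups(form, groups_of(held_data), warm)
                grp = ln if per_cell_line else _POOLED
                pred = predict_viability(
                    form,
                    prm_cv[grp],
                    ra[idx : idx + 1],
                    re[idx : idx + 1],
                    responses=X_all.iloc[idx : idx + 1] if form == "4a" else None,
                    strict=False,
                )
                sq += float((pred[0] - v[idx]) ** 2)
        loocv_l2 = math.sqrt(sq)

    return ViabilityModelFit(
        form=form,
        params=params,
        sigma=sigma,
        loocv_l2=loocv_l2,
        per_cell_line=per_cell_line,
        conditions={ln: data[ln][0] for ln in lines},
        n_obs=n_total,
        pvalues=pvalues,
        flags=flags,
    )


def compare_models(fits: list[ViabilityModelFit]) -> pd.DataFrame:
    """Tabulate fits on the same data, ordered best to worst by LOOCV L2-norm."""
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0].conditions
    for fit in fits[1:]:
        if fit.conditions != ref:
            raise ValueError("fits were made on different data")
    rows = [
        {"form": f.form, "type": f.kind, "sigma": f.sigma, "loocv_l2": f.loocv_l2}
        for f in fits
    ]
    return pd.DataFrame(rows).sort_values("loocv_l2", ignore_index=True)


def prediction_correlations(
    fits: list[ViabilityModelFit],
    responses: Mapping[str, ResponseMatrix],
    akt_node: str = "AKT1",
    erk_node: str = "ERK1",
) -> pd.DataFrame:
    """Pairwise Pearson correlations among model-form predictions."""
    preds = {}
    for fit in fits:
        vals = []
        for ln, conds in fit.conditions.items():
            R = responses[ln]
            vals.append(
                fit.predict(
                    ln,
                    R.values.loc[akt_node, conds].to_numpy(),
                    R.values.loc[erk_node, conds].to_numpy(),
                    responses=R.values.loc[:, conds].T if fit.form == "4a" else None,
                    strict=False,
                )
            )
        preds[fit.form] = np.concatenate(vals)
    return pd.DataFrame(preds).corr()


def bootstrap_ci(
    responses: Mapping[str, ResponseMatrix],
    viability: pd.DataFrame,
    form: str = "4c",
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    per_cell_line: bool = True,
    akt_node: str = "AKT1",
    erk_node: str = "ERK1",
    max_failure_rate: float = 0.2,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Nonparametric bootstrap percentile CIs for the model parameters.

    Conditions are resampled with replacement within each cell line.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    vmean = mean_viability(viability)
    lines = list(responses)
    data = {ln: _design_for_line(responses, vmean, ln, akt_node, erk_node) for ln in lines}
    warm = None
    if form in NONLINEAR_FORMS:
        if per_cell_line:
            full_groups = {ln: data[ln][1:] for ln in lines}
        else:
            full_groups = {
                _POOLED: (
                    np.concatenate([data[ln][1] for ln in lines]),
                    np.concatenate([data[ln][2] for ln in lines]),
                    np.concatenate([data[ln][3] for ln in lines]),
                    pd.concat([data[ln][4] for ln in lines], axis=0),
                )
            }
        full_params, _, _, _, _ = _fit_groups(form, full_groups)
        warm = {
            grp: [(prm["K_AKT"], prm["K_ERK"]), (1.0, 1.0)]
            for grp, prm in full_params.items()
        }
    draws: dict[str, dict[str, list[float]]] = {}
    failures = 0
    for _ in range(n_boot):
        resampled = {}
        for ln in lines:
            conds, v, ra, re, X_all = data[ln]
            idx = rng.integers(0, len(conds), size=len(conds))
            resampled[ln] = (
                [conds[i] for i in idx],
                v[idx],
                ra[idx],
                re[idx],
                X_all.iloc[idx],
            )
        try:
            if per_cell_line:
                groups = {ln: resampled[ln][1:] for ln in lines}
            else:
                groups = {
                    _POOLED: (
                        np.concatenate([resampled[ln][1] for ln in lines]),
                        np.concatenate([resampled[ln][2] for ln in lines]),
                        np.concatenate([resampled[ln][3] for ln in lines]),
                        pd.concat([resampled[ln][4] for ln in lines], axis=0),
                    )
                }
            params, _, _, _, _ = _fit_groups(form, groups, warm)
        except (RuntimeError, np.linalg.LinAlgError):
            failures += 1
            continue
        for grp, prm in params.items():
            for key, val in prm.items():
                draws.setdefault(grp, {}).setdefault(key, []).append(val)
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"bootstrap refit failure rate too high: {failures}/{n_boot}")
    lo = (1 - level) / 2 * 100
    cis = {}
    for grp, by_param in draws.items():
        cis[grp] = {
            key: (float(np.percentile(vals, lo)), float(np.percentile(vals, 100 - lo)))
            for key, vals in by_param.items()
        }
    return cis


def residual_quadratic_slope(
    fit: ViabilityModelFit,
    responses: Mapping[str, ResponseMatrix],
    viability: pd.DataFrame,
    akt_node: str = "AKT1",
    erk_node: str = "ERK1",
) -> float:
    """Coefficient of the quadratic term when regressing residuals on fitted values.

    A residuals-vs-fitted curvature check: values near zero indicate no
    structure left in the residuals.
    """
    vmean = mean_viability(viability)
    fitted, resid = [], []
    for ln, conds in fit.conditions.items():
        R = responses[ln]
        sub = vmean[vmean["cell_line"] == ln].set_index("condition")
        v = sub.loc[conds, "viability"].to_numpy()
        pred = fit.predict(
            ln,
            R.values.loc[akt_node, conds].to_numpy(),
            R.values.loc[erk_node, conds].to_numpy(),
            responses=R.values.loc[:, conds].T if fit.form == "4a" else None,
            strict=False,
        )
        fitted.append(pred)
        resid.append(v - pred)
    f = np.concatenate(fitted)
    r = np.concatenate(resid)
    X = sm.add_constant(np.column_stack([f, f**2]))
    return float(sm.OLS(r, X).fit().params[2])
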