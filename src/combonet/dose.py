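"""Parametrize direct target inhibition as a function of drug concentration.

Each (drug, target, cell line) gets a saturating curve

    s(c) = Imax * c / (KI + c),        0 <= c <= 1,

anchored at the two concentrations estimated during network reconstruction
(normalized so the highest applied concentration, the IC90, equals 1).  Only
interpolation is allowed: evaluating outside [0, 1] raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseParams",
    "fit_inhibition_curve",
    "fit_single_dose_curve",
    "inhibition_at",
    "fit_dose_params",
]


@dataclass(frozen=True)
class DoseResponseParams:
    imax: float  # asymptotic direct effect, <= 0
    ki: float  # half-saturation concentration, > 0
    flagged: bool = False  # True when the closed form failed or KI was imputed
    drug: str = ""
    target: str = ""
    cell_line: str = ""


def fit_inhibition_curve(
    c50: float, s50: float, s90: float, c90: float = 1.0
) -> DoseResponseParams:
    """Exact two-point fit of s(c) = Imax*c/(KI+c) through (c50, s50), (c90, s90).

    Falls back to least squares (and flags the result) if the closed-form KI
    is non-positive, which happens when the anchors decay slower than any
    saturating curve allows.
    """
    if c90 != 1.0:
        raise ValueError("concentrations must be normalized so that c90 == 1")
    if not 0 < c50 < c90:
        raise ValueError(f"need 0 < c50 < 1, got c50={c50}")
    if s50 >= 0 or s90 >= 0:
        raise ValueError("direct inhibitory effects must be negative")
    if s50 <= s90:
        raise ValueError(f"anchors must satisfy 0 > s(IC50) > s(IC90), got {s50} vs {s90}")
    rho = s50 / s90  # in (0, 1) for valid anchors
    if rho > c50:
        ki = c50 * (1.0 - rho) / (rho - c50)
        imax = s90 * (ki + 1.0)
        return DoseResponseParams(imax=float(imax), ki=float(ki))

    # Closed form gives KI <= 0: least-squares fallback, flagged.
    def fun(x):
        imax, ki = x
        pred = imax * np.array([c50, 1.0]) / (ki + np.array([c50, 1.0]))
        return pred - np.array([s50, s90])

    res = least_squares(
        fun, x0=[s90 * 1.5, 0.5], bounds=([-np.inf, 1e-9], [0.0, np.inf])
    )
    return DoseResponseParams(imax=float(res.x[0]), ki=float(res.x[1]), flagged=True)


def fit_single_dose_curve(s90: float, ki: float) -> DoseResponseParams:
    """Curve for a drug measured at a single (IC90) dose: KI fixed, Imax solved."""
    if s90 >= 0:
        raise ValueError("direct inhibitory effect must be negative")
    if ki <= 0:
        raise ValueError("KI must be positive")
    return DoseResponseParams(imax=float(s90 * (ki + 1.0)), ki=float(ki), flagged=True)


def inhibition_at(params: DoseResponseParams, conc) -> float | np.ndarray:
    """Evaluate the inhibition curve; interpolation only (0 <= conc <= 1)."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("concentration outside [0, 1]: no extrapolation")
    out = params.imax * c / (params.ki + c)
    return float(out) if np.isscalar(conc) else out


def fit_dose_params(
    s_values: dict,
    dose_levels: dict,
    cell_lines: list[str],
) -> pd.DataFrame:
    """Fit curves for every (drug, target, cell line) from reconstructed s-values.

    ``s_values`` maps (cell_line, drug, dose_label, target) to the estimated
    direct effect; ``dose_levels`` maps drug -> {label: normalized conc}.
    Drugs measured only at IC90 get KI imputed as the median KI of the
    two-dose drugs in the same cell line (flagged).
    """
    pairs: dict[tuple[str, str, str], dict[str, float]] = {}
    for (line, drug, label, target), val in s_values.items():
        pairs.setdefault((line, drug, target), {})[label] = val

    rows = []
    singles = []
    ki_by_line: dict[str, list[float]] = {}
    for (line, drug, target), by_label in sorted(pairs.items()):
        if "IC50" in by_label and "IC90" in by_label:
            p = fit_inhibition_curve(
                dose_levels[drug]["IC50"], by_label["IC50"], by_label["IC90"]
            )
            rows.append((line, drug, target, p.imax, p.ki, p.flagged))
            ki_by_line.setdefault(line, []).append(p.ki)
        elif "IC90" in by_label:
            singles.append((line, drug, target, by_label["IC90"]))
        else:
            raise ValueError(f"no IC90 estimate for ({line}, {drug}, {target})")
    for line, drug, target, s90 in singles:
        if not ki_by_line.get(line):
            raise ValueError(f"no two-dose drugs to impute KI for {drug} in {line}")
        ki = float(np.median(ki_by_line[line]))
        p = fit_single_dose_curve(s90, ki)
        rows.append((line, drug, target, p.imax, p.ki, True))
    return pd.DataFrame(
        rows, columns=["cell_line", "drug", "target", "imax", "ki", "flagged"]
    )


def dose_params_dict(table: pd.DataFrame) -> dict[str, dict[tuple[str, str], DoseResponseParams]]:
    """Convert the fit table into {cell_line: {(drug, target): params}}."""
    out: dict[str, dict[tuple[str, str], DoseResponseParams]] = {}
    for row in table.itertuples():
        out.setdefault(row.cell_line, {})[(row.drug, row.target)] = DoseResponseParams(
            imax=row.imax,
            ki=row.ki,
            flagged=bool(row.flagged),
            drug=row.drug,
            target=row.target,
            cell_line=row.cell_line,
        )
    return out
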