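"""Finite-difference gradient classification of relevant variables.

For every modelling function, each referenced relevant variable and each
observed year, the partial derivative of the function is estimated with a
central finite difference at the observed data vector.  The pooled signs
determine the relationship class: *direct* (derivative positive in at
least an agreement fraction of usable samples), *inverse* (negative), or
*variable* (inconsistent sign).  Near-zero derivatives carry no
directional information and are excluded from the agreement fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gpdrivers.gp import Individual, eval_genome

__all__ = [
    "GradientParams",
    "GradientReport",
    "partial_derivative",
    "classify_relationship",
    "gradient_report",
]


@dataclass
class GradientParams:
    h: float = 1e-4                 # central-difference step on the normalised scale
    zero_tol: float = 1e-8          # |derivative| below this is directionless
    agreement_threshold: float = 0.9


@dataclass
class VariableGradient:
    variable: str
    n_positive: int
    n_negative: int
    n_zero: int
    classification: str
    agreement: float
    per_function: dict[int, str] = field(default_factory=dict)


@dataclass
class GradientReport:
    params: GradientParams
    variables: dict[str, VariableGradient]

    def classifications(self) -> dict[str, str]:
        return {v: g.classification for v, g in self.variables.items()}

    def to_dict(self) -> dict:
        return {
            "params": {
                "h": self.params.h,
                "zero_tol": self.params.zero_tol,
                "agreement_threshold": self.params.agreement_threshold,
            },
            "variables": {
                v: {
                    "n_positive": g.n_positive,
                    "n_negative": g.n_negative,
                    "n_zero": g.n_zero,
                    "classification": g.classification,
                    "agreement": g.agreement,
                    "per_function": {str(k): s for k, s in g.per_function.items()},
                }
                for v, g in self.variables.items()
            },
        }


def _eval_point(individual: Individual, point: dict[str, float]) -> float:
    cols = {v: np.array([point[v]], dtype=float) for v in individual.variables()}
    if not cols:
        cols = {"_": np.empty(1)}
    return float(eval_genome(individual.genome, cols)[0])


def partial_derivative(
    individual: Individual, variable: str, point: dict[str, float], h: float = 1e-4
) -> float:
    """Central-difference partial derivative at a full variable assignment."""
    used = individual.variables()
    if variable not in used:
        raise ValueError(f"variable {variable!r} is not referenced by the individual")
    missing = used - set(point)
    if missing:
        raise ValueError(f"point does not assign {sorted(missing)}")
    up = dict(point)
    dn = dict(point)
    up[variable] = point[variable] + h
    dn[variable] = point[variable] - h
    return (_eval_point(individual, up) - _eval_point(individual, dn)) / (2.0 * h)


def classify_relationship(
    derivatives: np.ndarray,
    agreement_threshold: float = 0.9,
    zero_tol: float = 1e-8,
) -> tuple[str, float]:
    """Classify pooled derivative samples as direct / inverse / variable.

    Returns the class and the agreement fraction (share of usable samples
    carrying the majority sign).  With no usable sample the class is
    ``variable`` with agreement 0.
    """
    d = np.asarray(derivatives, dtype=float)
    d = d[np.isfinite(d)]
    usable = d[np.abs(d) > zero_tol]
    if usable.size == 0:
        return "variable", 0.0
    pos = float(np.mean(usable > 0))
    neg = float(np.mean(usable < 0))
    if pos >= agreement_threshold:
        return "direct", pos
    if neg >= agreement_threshold:
        return "inverse", neg
    return "variable", max(pos, neg)


def gradient_report(
    funcs: list,
    table,
    relevant: list[str],
    params: GradientParams | None = None,
) -> GradientReport:
    """Aggregate finite-difference signs over (function, variable, year) triples.

    ``funcs`` are modelling functions (PooledFunction); evaluation points
    are the observed yearly data vectors of the table, restricted to years
    where every variable the function references is present.
    """
    if params is None:
        params = GradientParams()
    if not funcs:
        raise ValueError("no modelling functions to analyse")
    data = table.data
    report: dict[str, VariableGradient] = {}
    samples: dict[str, list[float]] = {v: [] for v in relevant}
    per_func: dict[str, dict[int, list[float]]] = {v: {} for v in relevant}

    for fi, pf in enumerate(funcs):
        ind = pf.individual
        used = sorted(ind.variables())
        if not used:
            continue
        sub = data[used].dropna()
        for _, row in sub.iterrows():
            point = row.to_dict()
            for v in used:
                if v not in samples:
                    continue
                d = partial_derivative(ind, v, point, params.h)
                if np.isfinite(d):
                    samples[v].append(d)
                    per_func[v].setdefault(fi, []).append(d)

    for v in relevant:
        arr = np.asarray(samples[v], dtype=float)
        usable = arr[np.abs(arr) > params.zero_tol] if arr.size else arr
        cls, agreement = classify_relationship(
            arr, params.agreement_threshold, params.zero_tol
        )
        report[v] = VariableGradient(
            variable=v,
            n_positive=int(np.sum(usable > 0)) if usable.size else 0,
            n_negative=int(np.sum(usable < 0)) if usable.size else 0,
            n_zero=int(arr.size - usable.size),
            classification=cls,
            agreement=agreement,
            per_function={
                fi: classify_relationship(
                    np.asarray(ds), params.agreement_threshold, params.zero_tol
                )[0]
                for fi, ds in per_func[v].items()
            },
        )
    return GradientReport(params=params, variables=report)
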