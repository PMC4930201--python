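"""Synthetic annual time series with known ground truth.

Candidates emulate the structural features of multidecadal ecological and
hydro-climatic monitoring series: AR(1) autocorrelation, linear trends,
step changes in the mean, a mix of positive-only (abundances, nutrient
concentrations) and mixed-sign (climate indices, anomalies) series, and
missing years.  The target is a known sparse expression of a few
candidates plus Gaussian noise, so that driver recovery, gradient signs
and shift years can all be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy

from gpdrivers.preprocess import FeatureTable, normalize

__all__ = ["SyntheticSpec", "GroundTruth", "generate_candidates", "generate_target",
           "synthetic_table"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic study: candidates plus a sparse target.

    ``target_recipe`` is a symbolic expression over candidate names
    (e.g. ``"0.8*x3 - 0.6*x7"``).  ``step_changes`` maps a candidate name
    to ``(year_index, size)``: from that 0-based year on, the candidate's
    mean is offset by ``size``.
    """

    n_years: int = 39
    start_year: int = 1972
    n_candidates: int = 20
    ar_coef: float = 0.6
    innovation_sd: float = 1.0
    mixed_sign_fraction: float = 0.5
    trend_sd: float = 0.02
    step_changes: dict[str, tuple[int, float]] = field(default_factory=dict)
    target_recipe: str = "0.8*x3 - 0.6*x7"
    noise_sd: float = 0.1
    n_missing_years: int = 0
    n_noise_candidates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.ar_coef) < 1.0:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        if self.noise_sd < 0 or self.innovation_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def candidate_names(self) -> list[str]:
        return [f"x{i}" for i in range(1, self.n_candidates + 1)]

    @property
    def noise_names(self) -> list[str]:
        return [f"noise{i}" for i in range(1, self.n_noise_candidates + 1)]

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


@dataclass
class GroundTruth:
    drivers: list[str]
    signs: dict[str, str]                  # driver -> "+" or "-" (majority sign)
    step_years: dict[str, int]             # candidate -> first year of new regime


def _ar1(n: int, phi: float, sd: float, rng) -> np.ndarray:
    x = np.empty(n)
    # stationary start so early years are not systematically small
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def generate_candidates(spec: SyntheticSpec, rng=None) -> pd.DataFrame:
    """Raw (un-normalised) candidate matrix, one AR(1)-based column each."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = spec.n_years
    t = np.arange(n)
    cols: dict[str, np.ndarray] = {}
    n_mixed = int(round(spec.mixed_sign_fraction * spec.n_candidates))
    for i, name in enumerate(spec.candidate_names):
        x = _ar1(n, spec.ar_coef, spec.innovation_sd, rng)
        x = x + rng.normal(0.0, spec.trend_sd) * t
        if name in spec.step_changes:
            change_idx, size = spec.step_changes[name]
            x = x + size * (t >= change_idx)
        if i >= n_mixed:  # positive-only series: shift above zero
            lo = float(np.min(x))
            if lo <= 0.0:
                x = x - lo + 0.5 * spec.innovation_sd
        cols[name] = x
    # structureless negative controls: i.i.d. Gaussian columns
    for name in spec.noise_names:
        cols[name] = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(cols, index=pd.Index(spec.years, name="year"))


def _recipe_signs(expr, names: list[str], data: pd.DataFrame) -> dict[str, str]:
    signs: dict[str, str] = {}
    syms = {n: sympy.Symbol(n) for n in names}
    for name in names:
        d = sympy.diff(expr, syms[name])
        fn = sympy.lambdify([syms[n] for n in names], d, modules="numpy")
        vals = np.asarray(
            fn(*[data[n].to_numpy(dtype=float) for n in names]), dtype=float
        )
        vals = np.broadcast_to(vals, (len(data),))
        vals = vals[np.isfinite(vals)]
        signs[name] = "+" if np.mean(np.sign(vals)) >= 0 else "-"
    return signs


def generate_target(
    spec: SyntheticSpec, candidates: pd.DataFrame, rng=None
) -> tuple[pd.Series, GroundTruth]:
    """Target series from the recipe plus noise, with ground truth attached."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    expr = sympy.sympify(spec.target_recipe)
    names = sorted(str(s) for s in expr.free_symbols)
    unknown = set(names) - set(candidates.columns)
    if unknown:
        raise ValueError(f"recipe references unknown candidates: {sorted(unknown)}")
    syms = [sympy.Symbol(n) for n in names]
    fn = sympy.lambdify(syms, expr, modules="numpy")
    base = np.asarray(
        fn(*[candidates[n].to_numpy(dtype=float) for n in names]), dtype=float
    )
    base = np.broadcast_to(base, (len(candidates),)).copy()
    y = base + rng.normal(0.0, spec.noise_sd, size=len(candidates))

    target = pd.Series(y, index=candidates.index, name="target")
    if spec.n_missing_years > 0:
        # keep the first and last 3 years so no CV fold loses all indices
        eligible = np.arange(3, len(target) - 3)
        drop = rng.choice(eligible, size=min(spec.n_missing_years, len(eligible)),
                          replace=False)
        target.iloc[drop] = np.nan

    truth = GroundTruth(
        drivers=names,
        signs=_recipe_signs(expr, names, candidates),
        step_years={
            name: spec.start_year + idx
            for name, (idx, _size) in spec.step_changes.items()
        },
    )
    return target, truth


def synthetic_table(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Normalised FeatureTable plus ground truth, fully determined by the spec."""
    rng_c = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rng_t = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    raw = generate_candidates(spec, rng_c)
    target_raw, truth = generate_target(spec, raw, rng_t)
    data = raw.apply(lambda col: pd.Series(normalize(col.to_numpy()), index=col.index))
    target = pd.Series(
        normalize(target_raw.to_numpy()), index=target_raw.index, name="target"
    )
    meta = pd.DataFrame(
        {
            "name": list(data.columns),
            "base": list(data.columns),
            "season": "annual",
            "category": "physical",
        }
    )
    table = FeatureTable(data=data, target=target, target_name="target", meta=meta)
    return table, truth
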