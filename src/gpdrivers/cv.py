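"""k-fold cross-validation design and the population pool.

The usable years are split into consecutive, disjoint folds (e.g. 39 years
into 13 folds of 3).  For each fold and run, a fresh GP evolution is trained
on a random 85% sample of the *non-held-out* years and the individual of
the final population with the lowest RMSE on the held-out fold is kept as
that run's candidate.  The best-generalising fraction of all candidates
forms the *population pool*, the substrate for relevance analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from gpdrivers.gp import GPConfig, Individual, eval_genome, evolve, rmse

__all__ = [
    "CVDesign",
    "PooledFunction",
    "PopulationPool",
    "make_folds",
    "sample_training",
    "run_cv",
    "select_pool",
]


@dataclass
class CVDesign:
    """Fold layout and per-fold run schedule."""

    folds: list[list[int]]
    runs_per_fold: int = 50
    train_fraction: float = 0.85
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction <= 1.0:
            raise ValueError("train_fraction must lie in (0, 1]")
        flat = [y for f in self.folds for y in f]
        if len(set(flat)) != len(flat):
            raise ValueError("folds must be disjoint")

    @property
    def years(self) -> list[int]:
        return [y for f in self.folds for y in f]


@dataclass
class PooledFunction:
    """A per-run best individual with its provenance and errors."""

    individual: Individual
    fold: int
    run: int
    train_rmse: float
    val_rmse: float

    def to_dict(self) -> dict:
        return {
            "sexpr": self.individual.to_sexpr(),
            "fold": self.fold,
            "run": self.run,
            "train_rmse": self.train_rmse,
            "val_rmse": self.val_rmse,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PooledFunction":
        return cls(
            individual=Individual.from_sexpr(d["sexpr"]),
            fold=d["fold"],
            run=d["run"],
            train_rmse=d["train_rmse"],
            val_rmse=d["val_rmse"],
        )


@dataclass
class PopulationPool:
    """The retained best-generalising functions plus summary statistics."""

    members: list[PooledFunction]
    keep_fraction: float = 1.0
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = self.compute_summary()

    def compute_summary(self) -> dict:
        errs = np.array([m.val_rmse for m in self.members], dtype=float)
        return {
            "n_functions": len(self.members),
            "mean_val_rmse": float(np.mean(errs)) if errs.size else float("nan"),
            "sd_val_rmse": float(np.std(errs)) if errs.size else float("nan"),
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "keep_fraction": self.keep_fraction,
                "summary": self.summary,
                "members": [m.to_dict() for m in self.members],
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PopulationPool":
        d = json.loads(text)
        return cls(
            members=[PooledFunction.from_dict(m) for m in d["members"]],
            keep_fraction=d["keep_fraction"],
            summary=d["summary"],
        )


def make_folds(years: list[int], fold_size_years: int = 3) -> list[list[int]]:
    """Split an ordered year list into consecutive folds of equal size."""
    years = list(years)
    if fold_size_years < 1:
        raise ValueError("fold_size_years must be >= 1")
    if len(years) % fold_size_years != 0:
        raise ValueError(
            f"{len(years)} years do not divide into folds of {fold_size_years}"
        )
    return [
        years[i : i + fold_size_years] for i in range(0, len(years), fold_size_years)
    ]


def sample_training(train_years: list[int], fraction: float, rng) -> list[int]:
    """Uniform sample without replacement of floor(fraction * n) years."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n = int(np.floor(fraction * len(train_years)))
    if n == 0:
        raise ValueError("training sample would be empty")
    idx = rng.choice(len(train_years), size=n, replace=False)
    return sorted(train_years[i] for i in idx)


def _run_seed(base_seed: int, fold: int, run: int):
    # Deterministic per-run stream: single runs re-execute in isolation.
    return np.random.default_rng(np.random.SeedSequence([base_seed, fold, run]))


def _best_on_fold(population, table, fold_years) -> tuple[Individual, float]:
    sel = table.data.index.isin(fold_years)
    target = table.target.to_numpy(dtype=float)[sel]
    col_cache: dict[str, np.ndarray] = {}
    best, best_key = None, None
    for ind in population:
        cols = {}
        for v in ind.variables():
            if v not in col_cache:
                col_cache[v] = table.data[v].to_numpy(dtype=float)[sel]
            cols[v] = col_cache[v]
        if cols:
            pred = eval_genome(ind.genome, cols)
        else:
            pred = np.full(int(sel.sum()), eval_genome(ind.genome, {"_": np.empty(1)})[0])
        try:
            err = rmse(pred, target)
        except ValueError:
            err = float("inf")
        key = (err, ind.size)
        if best_key is None or key < best_key:
            best, best_key = ind, key
    return best, best_key[0]


def run_cv(table, design: CVDesign, config: GPConfig) -> list[PooledFunction]:
    """One GP evolution per (fold, run); returns each run's best generaliser.

    Per-run seeds derive deterministically from (base seed, fold, run), so
    the candidate list is independent of execution order and reproducible.
    """
    table_years = set(int(y) for y in table.years)
    for f in design.folds:
        if not set(f) <= table_years:
            raise ValueError("CV design years not present in the table")
    candidates: list[PooledFunction] = []
    for fi, fold_years in enumerate(design.folds):
        train_pool = [y for y in design.years if y not in fold_years]
        for run in range(design.runs_per_fold):
            rng = _run_seed(design.base_seed, fi, run)
            sampled = sample_training(train_pool, design.train_fraction, rng)
            best_train, _history, population = evolve(table, sampled, config, rng)
            best_val, val_err = _best_on_fold(population, table, fold_years)
            sel = table.data.index.isin(sampled)
            target = table.target.to_numpy(dtype=float)[sel]
            cols = {
                v: table.data[v].to_numpy(dtype=float)[sel]
                for v in best_val.variables()
            }
            if cols:
                pred = eval_genome(best_val.genome, cols)
            else:
                pred = np.full(len(target), eval_genome(best_val.genome, {"_": np.empty(1)})[0])
            try:
                train_err = rmse(pred, target)
            except ValueError:
                train_err = float("inf")
            candidates.append(
                PooledFunction(
                    individual=best_val.copy(),
                    fold=fi,
                    run=run,
                    train_rmse=train_err,
                    val_rmse=val_err,
                )
            )
    return candidates


def select_pool(
    candidates: list[PooledFunction], keep_fraction: float = 0.16
) -> PopulationPool:
    """Retain the floor(keep_fraction * n) candidates with the smallest
    validation RMSE (ties: smaller tree, then earlier fold/run)."""
    if not candidates:
        raise ValueError("no candidates to select from")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    n_keep = int(np.floor(keep_fraction * len(candidates)))
    if n_keep == 0:
        raise ValueError("keep_fraction retains no candidate")
    ranked = sorted(
        candidates, key=lambda c: (c.val_rmse, c.individual.size, c.fold, c.run)
    )
    return PopulationPool(members=ranked[:n_keep], keep_fraction=keep_fraction)
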