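"""End-to-end orchestration: normalise -> GP/CV -> relevance -> gradient -> CuSUM.

The single global seed fans out deterministically to the synthetic
generator and to every (fold, run) GP evolution, so re-running with the
same configuration reproduces every report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from gpdrivers.cv import CVDesign, PopulationPool, make_folds, run_cv, select_pool
from gpdrivers.cusum import ShiftReport, detect_shift
from gpdrivers.gp import GPConfig
from gpdrivers.gradient import GradientParams, GradientReport, gradient_report
from gpdrivers.preprocess import FeatureTable, assemble_feature_table, read_csv_inputs
from gpdrivers.relevance import RelevanceReport, relevance_report
from gpdrivers.synthetic import SyntheticSpec, synthetic_table

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "write_reports"]

_version = "0.1.0"


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    data_csv: str | None = None
    meta_csv: str | None = None
    synthetic: SyntheticSpec | None = None
    gp: GPConfig = field(default_factory=GPConfig)
    fold_size_years: int = 3
    runs_per_fold: int = 50
    train_fraction: float = 0.85
    keep_fraction: float = 0.16
    alpha: float = 0.001
    p0: float | None = None
    gradient: GradientParams = field(default_factory=GradientParams)
    seed: int = 0

    def __post_init__(self) -> None:
        has_csv = self.data_csv is not None and self.meta_csv is not None
        has_synth = self.synthetic is not None
        if has_csv == has_synth:
            raise ValueError("configure exactly one input source (CSV or synthetic)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            s = dict(d["synthetic"])
            if s.get("step_changes"):
                s["step_changes"] = {k: tuple(v) for k, v in s["step_changes"].items()}
            d["synthetic"] = SyntheticSpec(**s)
        if d.get("gp") is not None:
            g = dict(d["gp"])
            g["init_depth"] = tuple(g["init_depth"])
            g["const_range"] = tuple(g["const_range"])
            g["primitives"] = tuple(g["primitives"])
            d["gp"] = GPConfig(**g)
        if d.get("gradient") is not None:
            d["gradient"] = GradientParams(**d["gradient"])
        return cls(**d)


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    table: FeatureTable
    pool: PopulationPool
    relevance: RelevanceReport
    gradient: GradientReport | None
    shifts: dict[str, ShiftReport]
    ground_truth: object | None = None


def _load_table(config: AnalysisConfig) -> tuple[FeatureTable, object | None]:
    if config.synthetic is not None:
        return synthetic_table(config.synthetic)
    series = read_csv_inputs(config.data_csv, config.meta_csv)
    return assemble_feature_table(series), None


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Execute all stages in order and collect every report.

    CuSUM is applied to the target and to each relevant variable.  If the
    total year count does not divide into whole folds, the earliest
    remainder years are dropped from the CV design (not from the table).
    """
    table, truth = _load_table(config)

    years = [int(y) for y in table.years]
    remainder = len(years) % config.fold_size_years
    fold_years = years[remainder:]
    folds = make_folds(fold_years, config.fold_size_years)
    design = CVDesign(
        folds=folds,
        runs_per_fold=config.runs_per_fold,
        train_fraction=config.train_fraction,
        base_seed=config.seed,
    )
    candidates = run_cv(table, design, config.gp)
    pool = select_pool(candidates, config.keep_fraction)

    relevance = relevance_report(pool, table.columns, config.alpha, config.p0)

    grad: GradientReport | None = None
    if relevance.modelling_functions:
        grad = gradient_report(
            relevance.modelling_functions, table, relevance.relevant, config.gradient
        )

    shifts: dict[str, ShiftReport] = {}
    try:
        shifts[table.target_name] = detect_shift(table.target, table.target_name)
    except ValueError:
        pass
    for v in relevance.relevant:
        try:
            shifts[v] = detect_shift(table.data[v], v)
        except ValueError:
            continue

    return AnalysisResult(
        config=config,
        table=table,
        pool=pool,
        relevance=relevance,
        gradient=grad,
        shifts=shifts,
        ground_truth=truth,
    )


def write_reports(result: AnalysisResult, outdir: str | Path) -> list[Path]:
    """Write pool.json, relevance.csv, gradient.json, shifts.csv, provenance.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pool_path = outdir / "pool.json"
    pool_path.write_text(result.pool.to_json())
    written.append(pool_path)

    directions = result.gradient.classifications() if result.gradient else {}
    rows = result.relevance.to_rows()
    for r in rows:
        r["direction"] = directions.get(r["variable"], "")
    rel_path = outdir / "relevance.csv"
    pd.DataFrame(rows).to_csv(rel_path, index=False)
    written.append(rel_path)

    grad_path = outdir / "gradient.json"
    grad_path.write_text(
        json.dumps(
            result.gradient.to_dict() if result.gradient else {},
            indent=1,
            sort_keys=True,
        )
    )
    written.append(grad_path)

    shift_rows = [
        {
            "series": name,
            "shift_year": r.shift_year if r.shift_year is not None else "",
            "direction": r.direction,
            "magnitude": r.magnitude,
        }
        for name, r in result.shifts.items()
    ]
    shifts_path = outdir / "shifts.csv"
    pd.DataFrame(shift_rows).to_csv(shifts_path, index=False)
    written.append(shifts_path)

    prov_path = outdir / "provenance.json"
    prov_path.write_text(
        json.dumps(
            {
                "package_version": _version,
                "config": result.config.to_dict(),
                "pool_summary": result.pool.summary,
                "relevance_threshold": result.relevance.threshold,
            },
            indent=1,
            sort_keys=True,
        )
    )
    written.append(prov_path)
    return written
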