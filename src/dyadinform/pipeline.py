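"""End-to-end analysis: score -> align -> exclude -> stratify -> eMVI + OLS.

One :func:`run_analysis` call walks every requested (mode, year, dyad,
quartile) cell, computes the seed-ensemble importance panel and the adjusted
linear model for each, and writes tidy CSV outputs plus a JSON manifest that
makes the run bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import (StratumSpec, align_visits, apply_exclusions,
                     assign_quartiles, build_design, score_visit_table)
from .emvi import ImportancePanel, compute_emvi
from .errors import EmptyStratumError, MalformedInputError
from .forest import ForestConfig
from .inference import fit_ols
from .synthetic import generate_cohort, get_preset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisResult", "run_analysis", "prepare_cohort"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_csv: str | None = None
    preset: str | None = None
    n_dyads: int = 450
    modes: tuple[str, ...] = ("prospective", "cross_sectional")
    years: tuple[int, ...] = (1, 2, 3, 4)
    dyad_strata: tuple[str, ...] = ("all", "spousal", "non_spousal")
    quartile_strata: tuple = ("all", 1)
    forest: ForestConfig = field(default_factory=ForestConfig)
    n_replicates: int = 100
    cohort_seed: int = 7
    output_dir: str | None = None

    def validate(self) -> None:
        if not self.modes or not self.years:
            raise MalformedInputError("modes and years must be non-empty")
        if (self.input_csv is None) == (self.preset is None):
            raise MalformedInputError(
                "exactly one of input_csv / preset must be given")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        forest_kwargs = raw.pop("forest", {})
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if forest_kwargs:
            cfg.forest = ForestConfig(**forest_kwargs)
        return cfg


@dataclass
class StratumResult:
    spec: StratumSpec
    panel: ImportancePanel | None
    fit: "object | None"
    n_rows: int
    error: str | None = None


@dataclass
class AnalysisResult:
    strata: list[StratumResult]
    exclusions: dict[str, pd.DataFrame]
    emvi_table: pd.DataFrame
    coefficient_table: pd.DataFrame
    manifest: dict


def prepare_cohort(cfg: RunConfig) -> pd.DataFrame:
    """Load or simulate the raw visit table."""
    if cfg.input_csv is not None:
        return pd.read_csv(cfg.input_csv)
    params = get_preset(cfg.preset, n_dyads=cfg.n_dyads, seed=cfg.cohort_seed)
    return generate_cohort(params)


def _iter_specs(cfg: RunConfig) -> Iterable[StratumSpec]:
    for mode in cfg.modes:
        for year in cfg.years:
            for dyad in cfg.dyad_strata:
                for q in cfg.quartile_strata:
                    yield StratumSpec(mode=mode, outcome_year=year,
                                      dyad_filter=dyad, quartile_filter=q)


def run_analysis(cfg: RunConfig) -> AnalysisResult:
    """Run every requested stratum; optionally write outputs to disk.

    Strata are independent: results do not depend on execution order.  An
    empty stratum is recorded in the manifest and the run continues.
    """
    cfg.validate()
    raw = prepare_cohort(cfg)
    scored, reference = score_visit_table(raw)
    aligned = align_visits(scored)

    per_mode: dict[str, tuple[pd.DataFrame, pd.Series]] = {}
    exclusions: dict[str, pd.DataFrame] = {}
    for mode in cfg.modes:
        retained, log = apply_exclusions(aligned, mode)
        baseline = retained.loc[retained["visit_year"] == 0]
        quartiles = assign_quartiles(
            baseline.set_index("participant_id")["composite"])
        per_mode[mode] = (retained, quartiles)
        exclusions[mode] = log
        logger.info("mode=%s retained=%d excluded=%d", mode,
                    baseline.shape[0], log.shape[0])

    strata: list[StratumResult] = []
    emvi_frames, coef_frames = [], []
    for spec in _iter_specs(cfg):
        retained, quartiles = per_mode[spec.mode]
        t0 = time.perf_counter()
        try:
            X, y, names = build_design(retained, spec, quartiles)
        except EmptyStratumError as exc:
            logger.warning("empty stratum %s", spec.label())
            strata.append(StratumResult(spec, None, None, 0, error=str(exc)))
            continue
        panel = compute_emvi(X, y, cfg.forest, cfg.n_replicates,
                             predictor_names=names)
        try:
            fit = fit_ols(X, y, predictor_names=names)
            coef_frames.append(fit.to_frame(
                mode=spec.mode, year=spec.outcome_year,
                dyad=spec.dyad_filter, quartile=str(spec.quartile_filter)))
        except MalformedInputError as exc:
            fit = None
            logger.warning("OLS skipped for %s: %s", spec.label(), exc)
        emvi_frames.append(panel.to_frame(
            mode=spec.mode, year=spec.outcome_year, dyad=spec.dyad_filter,
            quartile=str(spec.quartile_filter)))
        strata.append(StratumResult(spec, panel, fit, n_rows=len(y)))
        logger.info("stratum %s: n=%d, %.2fs", spec.label(), len(y),
                    time.perf_counter() - t0)

    emvi_table = (pd.concat(emvi_frames, ignore_index=True)
                  if emvi_frames else pd.DataFrame())
    coef_table = (pd.concat(coef_frames, ignore_index=True)
                  if coef_frames else pd.DataFrame())
    manifest = {
        "package_version": __version__,
        "config": _manifest_config(cfg),
        "reference_n": reference.reference_n,
        "strata": [
            {"stratum": r.spec.label(), "n_rows": r.n_rows,
             **({"error": r.error} if r.error else {})}
            for r in strata
        ],
    }
    result = AnalysisResult(strata=strata, exclusions=exclusions,
                            emvi_table=emvi_table,
                            coefficient_table=coef_table, manifest=manifest)
    if cfg.output_dir is not None:
        _write_outputs(result, Path(cfg.output_dir))
    return result


def _manifest_config(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("output_dir", None)  # not part of the computation
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _write_outputs(result: AnalysisResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.emvi_table.to_csv(outdir / "emvi.csv", index=False)
    result.coefficient_table.to_csv(outdir / "coefficients.csv", index=False)
    logs = [df.assign(mode=mode) for mode, df in result.exclusions.items()]
    pd.concat(logs, ignore_index=True).to_csv(outdir / "exclusions.csv",
                                              index=False)
    # forest-plot-ready table: the two CFI predictors per stratum-year cell
    fp = result.emvi_table
    if not fp.empty:
        fp = fp.loc[fp["predictor"].isin(["p_cfi", "s_cfi"])]
    fp.to_csv(outdir / "forest_plot.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
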