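"""End-to-end pipeline driver and publication-style reports.

``run_pipeline`` executes the ordered stages — simulate (optional) →
exposure prep → outcomes → model fits (continuous, tertile,
sex-interaction) → optional selection-model sensitivity fit →
summaries — writing CSV outputs, plain-text tables in the layout of the
descriptive, continuous-estimate and sensitivity tables, and a JSON
manifest with seeds and input hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import exposure as xp
from . import io as pio
from .design import MCMCSettings, SelectionSpec
from .model import ShrinkageLMM
from .outcomes import build_outcomes
from .registry import default_registry, read_lms, read_registry
from .selection import SelectionLMM, compare_mar_mnar
from .simulate import DropoutConfig, TruthConfig, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "render_tables",
           "render_descriptives", "render_estimates", "render_tertiles"]

_KNOWN_KEYS = {"outdir", "mothers", "visits", "registry", "lms", "simulate",
               "model", "selection", "fit_tertile", "fit_interaction",
               "fit_mnar", "seed"}


@dataclasses.dataclass
class PipelineConfig:
    """YAML-serializable pipeline configuration; unknown keys rejected."""

    outdir: str = "run"
    mothers: str | None = None
    visits: str | None = None
    registry: str | None = None
    lms: str | None = None
    simulate: dict | None = None          # TruthConfig fields
    model: dict = dataclasses.field(default_factory=dict)   # ModelSpec-ish
    selection: dict = dataclasses.field(default_factory=dict)
    fit_tertile: bool = True
    fit_interaction: bool = True
    fit_mnar: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _truth_from_dict(d: dict) -> TruthConfig:
    d = dict(d)
    drop = d.pop("dropout", None)
    t = TruthConfig(**d)
    if drop:
        t.dropout = DropoutConfig(**drop)
    return t


def _mcmc_from_dict(d: dict, seed: int) -> MCMCSettings:
    return MCMCSettings(burn_in=d.get("burn_in", 10_000),
                        iterations=d.get("iterations", 50_000),
                        chains=d.get("chains", 2),
                        thin=d.get("thin", 1), seed=seed)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the pipeline; returns the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)

    registry = (read_registry(config.registry) if config.registry
                else default_registry())

    if config.simulate is not None:
        truth = _truth_from_dict(config.simulate)
        write_cohort(truth, config.seed, out / "sim", registry)
        mothers_path = out / "sim" / "mothers.csv"
        visits_path = out / "sim" / "visits.csv"
    else:
        if not config.mothers or not config.visits:
            raise FileNotFoundError(
                "config must provide mothers/visits paths or a simulate "
                "section")
        mothers_path, visits_path = Path(config.mothers), Path(config.visits)
    for p in (mothers_path, visits_path):
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")

    mothers = pio.read_mothers(mothers_path, registry)
    visits = pio.read_visits(visits_path,
                             known_subjects=set(mothers["subject_id"]))

    # exposure prep + descriptives
    kept, excluded = xp.exclude_dilute(mothers)
    matrix = xp.apply_correction_factors(kept, registry)
    completed = xp.substitute_lod_sqrt2(matrix)
    descriptives = xp.descriptive_table(completed, registry)
    descriptives.to_csv(out / "descriptives.csv")
    logger.info("excluded %d dilute samples", len(excluded))

    # outcomes
    lms = read_lms(config.lms) if config.lms else None
    outcomes = build_outcomes(visits, kept, lms)
    outcomes.to_csv(out / "outcomes.csv", index=False)

    mcmc = config.model.get("mcmc", {})
    common = {k: v for k, v in config.model.items() if k != "mcmc"}
    fits: dict[str, ShrinkageLMM] = {}

    def make(coding, interaction, seed_off):
        settings = _mcmc_from_dict(mcmc, config.seed + seed_off)
        return ShrinkageLMM(exposure_coding=coding, interaction=interaction,
                            burn_in=settings.burn_in,
                            iterations=settings.iterations,
                            chains=settings.chains, thin=settings.thin,
                            seed=settings.seed, **common)

    fits["continuous"] = make("continuous", "none", 1).fit(
        kept, visits, registry)
    if config.fit_interaction:
        fits["interaction"] = make("continuous", "sex", 2).fit(
            kept, visits, registry)
    if config.fit_tertile:
        fits["tertile"] = make("tertile", "none", 3).fit(
            kept, visits, registry)

    mnar = None
    if config.fit_mnar:
        sel = SelectionSpec(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in config.selection.items()})
        settings = _mcmc_from_dict(mcmc, config.seed + 4)
        mnar = SelectionLMM(
            selection_covariates=sel.covariates,
            extra_selection_covariates=sel.extra_covariates,
            tau_selection=sel.tau_selection, chains=sel.chains,
            burn_in=settings.burn_in, iterations=settings.iterations,
            thin=settings.thin, seed=settings.seed, **common)
        mnar.fit(mothers, visits, registry)

    # summaries + reports
    for name, est in fits.items():
        est.summary_.to_csv(out / f"summary_{name}.csv")
    if mnar is not None:
        mnar.summary_.to_csv(out / "summary_mnar.csv")
        (out / "dropout_or.json").write_text(json.dumps(mnar.dropout_or_,
                                                        indent=2))
    report = render_tables(fits, descriptives, mnar)
    (out / "report.txt").write_text(report)

    manifest = {
        "seed": config.seed,
        "inputs": {str(p): _hash_file(p) for p in (mothers_path,
                                                   visits_path)},
        "fits": sorted(fits),
        "mnar": mnar is not None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logging.getLogger().removeHandler(fh)
    return out


# ----------------------------------------------------------------------
# report rendering
# ----------------------------------------------------------------------

def render_descriptives(descriptives: pd.DataFrame) -> str:
    lines = ["Metabolite distributions (ug/L; DEHP sum umol/L)",
             f"{'Metabolite':<10}{'%Det':>7}{'GM':>10}{'Min':>10}"
             f"{'P25':>10}{'P75':>10}{'Max':>12}"]
    for code, r in descriptives.iterrows():
        det = "" if pd.isna(r["percent_detected"]) \
            else f"{r['percent_detected']:.1f}"
        lines.append(f"{code:<10}{det:>7}{r['geometric_mean']:>10.3g}"
                     f"{r['min']:>10.3g}{r['p25']:>10.3g}{r['p75']:>10.3g}"
                     f"{r['max']:>12.3g}")
    return "\n".join(lines)


def _fmt_est(summary: pd.DataFrame, name: str) -> str:
    r = summary.loc[name]
    return f"{r['mean']:.2f} ({r['ci2.5']:.2f}, {r['ci97.5']:.2f})"


def render_estimates(fits: dict[str, ShrinkageLMM]) -> str:
    """Continuous-coding estimate table: overall and, when the
    sex-interaction fit is present, girls/boys columns."""
    cont = fits["continuous"]
    if cont.summary_.empty:
        raise ValueError("empty summaries")
    inter = fits.get("interaction")
    lines = ["Adjusted associations, per SD ln concentration",
             f"{'Metabolite':<10}{'Overall':>24}"
             + (f"{'Girls':>24}{'Boys':>24}" if inter is not None else "")]
    for name in cont.data_.exposure_cols:
        row = f"{name:<10}{_fmt_est(cont.summary_, name):>24}"
        if inter is not None:
            s = inter.summary_
            girls = _fmt_est(s, name)
            flat = inter.chains_.reshape(-1, inter.chains_.shape[-1])
            j = inter.param_names_.index(name)
            ji = inter.param_names_.index(f"sex:{name}")
            boys = flat[:, j] + flat[:, ji]
            import numpy as np
            boys_s = (f"{boys.mean():.2f} "
                      f"({np.percentile(boys, 2.5):.2f}, "
                      f"{np.percentile(boys, 97.5):.2f})")
            row += f"{girls:>24}{boys_s:>24}"
        lines.append(row)
    return "\n".join(lines)


def render_tertiles(fit: ShrinkageLMM) -> str:
    lines = ["Tertile contrasts (vs lowest tertile = ref)",
             f"{'Metabolite':<10}{'T2 vs T1':>24}{'T3 vs T1':>24}"]
    for name in fit.data_.exposure_cols:
        lines.append(f"{name:<10}"
                     f"{_fmt_est(fit.summary_, name + '_T2'):>24}"
                     f"{_fmt_est(fit.summary_, name + '_T3'):>24}")
    return "\n".join(lines)


def render_tables(fits: dict[str, ShrinkageLMM],
                  descriptives: pd.DataFrame,
                  mnar: SelectionLMM | None = None) -> str:
    """Full text report: descriptives, continuous estimates, tertile
    contrasts, and the MAR vs selection-model comparison."""
    if not fits:
        raise ValueError("empty summaries")
    blocks = [render_descriptives(descriptives), render_estimates(fits)]
    if "tertile" in fits:
        blocks.append(render_tertiles(fits["tertile"]))
    if mnar is not None:
        cmp = compare_mar_mnar(fits["continuous"].summary_, mnar.summary_,
                               list(fits["continuous"].data_.exposure_cols))
        blocks.append("MAR vs selection-model (MNAR) estimates\n"
                      + cmp.to_string(float_format=lambda v: f"{v:.2f}"))
        blocks.append(
            "Dropout OR per 1% fat mass: "
            f"{mnar.dropout_or_['mean']:.2f} "
            f"({mnar.dropout_or_['ci2.5']:.2f}, "
            f"{mnar.dropout_or_['ci97.5']:.2f})")
    return "\n\n".join(blocks) + "\n"
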