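"""End-to-end pipeline: generate/read -> classify -> populations ->
standardize -> applicability -> reliability screen -> concordance tables ->
curve fits -> diagnostics, with deterministic TSV outputs and a run
manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .applicability import ReliabilityRules, applicability_table, apply_applicability
from .association import impact_table
from .cohort import (
    Device,
    PopulationLabel,
    derive_populations,
    read_cohort,
    cohort_to_frame,
    write_cohort,
    write_populations,
)
from .concordance import StratificationScheme, StratVariable, stratified_ccc_table
from .diagnostic import DEFAULT_F3F4_FT_CUTOFF, itd_analysis, presumed_prevalence
from .reliability import Criterion, screen_criterion
from .standardize import Variant, add_standardized_columns
from .synthetic import GeneratorConfig, generate_frame

logger = logging.getLogger(__name__)

_DEVICES = [Device.SWE, Device.TE_M, Device.TE_XL]


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML.

    Exactly one of ``input_path`` (cohort CSV) or ``generator`` (synthetic
    scenario) must be set. ``seed`` is mandatory whenever a bootstrap or
    simulation stage is enabled.
    """

    out_dir: str = "elastoconcord_out"
    input_path: str | None = None
    generator: GeneratorConfig | None = None
    rules: ReliabilityRules = field(default_factory=ReliabilityRules)
    standardization_variant: str = Variant.LOG_RANGE.value
    standardization_statistic: str = "mean"
    actitest_a2a3_cutoff: float = 0.52
    steatotest_s2_cutoff: float = 0.57
    fibrotest_f3f4_cutoff: float = DEFAULT_F3F4_FT_CUTOFF
    interval_cutoff_days: float = 30.0
    stiffness_cutoff_kpa: float = 9.5
    n_boot: int = 2000
    seed: int | None = None

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise PipelineError("config: set exactly one of input_path or generator")
        if self.generator is not None and self.seed is None:
            raise PipelineError("config: seed is mandatory when simulation is enabled")
        if self.seed is None:
            raise PipelineError("config: seed is mandatory (bootstrap stages enabled)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if d.get("rules") is not None and not isinstance(d["rules"], ReliabilityRules):
            d["rules"] = ReliabilityRules(**d["rules"])
        known = set(cls.__dataclass_fields__)
        extra = set(d) - known
        if extra:
            raise PipelineError(f"config: unknown keys {sorted(extra)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _write_tsv(df: pd.DataFrame, path: Path, decimals: int | None = None) -> None:
    out = df.copy()
    if decimals is not None:
        for c in out.columns:
            if pd.api.types.is_float_dtype(out[c]):
                out[c] = out[c].round(decimals)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns {stage name: output object}.

    Identical config + seed produce byte-identical tables. Any stage
    failure aborts with a :class:`PipelineError` naming the stage.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            bundle[name] = fn()
            return bundle[name]
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    def load():
        if config.generator is not None:
            frame = generate_frame(config.generator)
            write_cohort(frame, out_dir / "cohort.csv")
            return frame
        return cohort_to_frame(read_cohort(config.input_path))

    frame = stage("input", load)
    frame = stage("classify", lambda: apply_applicability(frame, config.rules))

    def populations():
        pops = derive_populations(frame)
        write_populations(pops, out_dir / "populations.csv")
        return pops

    pops = stage("populations", populations)
    frame = stage(
        "standardize",
        lambda: add_standardized_columns(
            frame, config.standardization_variant, config.standardization_statistic
        ),
    )

    def applicability_stage():
        table, ztests = applicability_table(frame, config.rules)
        _write_tsv(table, out_dir / "applicability.tsv")
        _write_tsv(ztests, out_dir / "applicability_ztests.tsv", decimals=4)
        return table, ztests

    stage("applicability", applicability_stage)

    rel = frame[frame["id"].isin(pops[PopulationLabel.SWE_RELIABILITY])]

    def screen():
        reports = {}
        for crit in Criterion:
            rep = screen_criterion(rel, crit)
            _write_tsv(rep.grid, out_dir / f"screen_{crit.value.lower()}.tsv", decimals=4)
            reports[crit.value] = rep
        return reports

    stage("reliability_screen", screen)

    conc = frame[frame["id"].isin(pops[PopulationLabel.CONCORDANCE])]
    conc_st = frame[frame["id"].isin(pops[PopulationLabel.CONCORDANCE_ST])]

    def concordance_tables():
        schemes = {
            "fibrotest_by_disease": (conc, "fibrotest", StratificationScheme(StratVariable.DISEASE)),
            "fibrotest_by_inflammation": (
                conc,
                "fibrotest",
                StratificationScheme(
                    StratVariable.INFLAMMATION, (config.actitest_a2a3_cutoff,), ("A0A1", "A2A3")
                ),
            ),
            "actitest_by_fibrosis": (
                conc,
                "actitest",
                StratificationScheme(
                    StratVariable.FIBROSIS, (config.fibrotest_f3f4_cutoff,), ("F0F1F2", "F3F4")
                ),
            ),
            "steatotest_by_fibrosis": (
                conc_st,
                "steatotest",
                StratificationScheme(
                    StratVariable.FIBROSIS, (config.fibrotest_f3f4_cutoff,), ("F0F1F2", "F3F4")
                ),
            ),
            "fibrotest_by_interval": (
                conc,
                "fibrotest",
                StratificationScheme(
                    StratVariable.INTERVAL, (config.interval_cutoff_days,), ("<=30d", ">30d")
                ),
            ),
        }
        tables = {}
        for name, (pop, ref, scheme) in schemes.items():
            t = stratified_ccc_table(pop, _DEVICES, ref, scheme)
            _write_tsv(t, out_dir / f"concordance_{name}.tsv", decimals=4)
            tables[name] = t
        return tables

    stage("concordance", concordance_tables)

    def curves():
        tables = {}
        for cov, pop in (("actitest", conc), ("steatotest", conc_st)):
            t = impact_table(pop, _DEVICES, cov, fibrosis_cutoff=config.fibrotest_f3f4_cutoff)
            _write_tsv(t, out_dir / f"curves_{cov}.tsv", decimals=4)
            tables[cov] = t
        return tables

    stage("curves", curves)

    itd_pop = frame[frame["id"].isin(pops[PopulationLabel.INTENTION_TO_DIAGNOSE])]

    def diagnostics():
        rows = []
        for dev in _DEVICES:
            res = itd_analysis(itd_pop, dev, ft_cutoff=config.fibrotest_f3f4_cutoff)
            for mode, r in res.items():
                rows.append(
                    {
                        "device": dev.value,
                        "analysis": mode,
                        "auroc": r.auroc,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "n_pos": r.n_pos,
                        "n_neg": r.n_neg,
                    }
                )
        table = pd.DataFrame(rows)
        _write_tsv(table, out_dir / "auroc_itd.tsv", decimals=4)
        prev_rows = []
        for combiner, devs in (
            ("SINGLE", [Device.SWE]),
            ("SINGLE", [Device.TE_M]),
            ("SINGLE", [Device.TE_XL]),
            ("WORST_OF_THREE", _DEVICES),
            ("CONCORDANT_ONLY", _DEVICES),
        ):
            p = presumed_prevalence(conc, devs, config.stiffness_cutoff_kpa, combiner)
            prev_rows.append(
                {
                    "combiner": combiner,
                    "devices": "+".join(d.value for d in devs),
                    "numerator": p.numerator,
                    "denominator": p.denominator,
                    "prevalence_pct": p.rate,
                    "ci_low": p.ci_low,
                    "ci_high": p.ci_high,
                }
            )
        prev = pd.DataFrame(prev_rows)
        _write_tsv(prev, out_dir / "prevalence.tsv", decimals=4)
        return {"auroc": table, "prevalence": prev}

    stage("diagnostics", diagnostics)

    def manifest():
        info = {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {
                "elastoconcord": __version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "populations": {k.value: len(v) for k, v in pops.items()},
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(info, fh, indent=2, sort_keys=True)
        return info

    stage("manifest", manifest)
    return bundle
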