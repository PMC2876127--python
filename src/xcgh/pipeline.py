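"""End-to-end orchestration: simulate -> QC -> normalize -> test -> evaluate.

Two layers:

- in-memory experiment helpers (:func:`simulate_experiment`,
  :func:`analyze_experiment`) used by the analysis scripts, the tests and
  the acceptance script — a simulated dataset can be analyzed under
  several normalization strategies without re-simulating;
- a file-based :func:`run_pipeline` over a validated :class:`RunConfig`
  (YAML), which writes every stage artifact into an output directory and
  is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import core, detect, evaluate, preprocess, simulate
from .simulate import (
    PLATFORM,
    ConfounderProbs,
    DyeBias,
    IdentityModel,
    SimulationConfig,
)

__all__ = [
    "ExperimentData",
    "ExperimentResult",
    "RunConfig",
    "simulate_experiment",
    "analyze_experiment",
    "divergence_profile_for",
    "run_pipeline",
    "load_run_config",
]

log = logging.getLogger("xcgh")


@dataclass
class ExperimentData:
    """One simulated hybridization experiment, preprocessed up to raw M/A."""

    species: str
    config: SimulationConfig
    annotation: pd.DataFrame
    truth: pd.DataFrame
    meta: dict[str, pd.DataFrame]
    design: pd.DataFrame
    scan: pd.DataFrame
    ma_raw: pd.DataFrame
    analyzable: set[str]


@dataclass
class ExperimentResult:
    normalization: str
    results: pd.DataFrame
    prior: detect.ModerationPrior
    summary: evaluate.EvaluationSummary


def simulate_experiment(
    species: str,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    min_arrays: int = 2,
) -> ExperimentData:
    """Simulate one experiment for ``species`` and preprocess to M/A."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    if species not in config.divergence_model:
        raise simulate.ConfigurationError(
            f"species {species!r} not in the divergence model "
            f"({sorted(config.divergence_model)})"
        )
    design = simulate.make_design(
        species, config.n_arrays, dye_swap_balanced=config.dye_swap_balanced
    )
    annotation, truth, meta = simulate.simulate_truth(config)
    scan = simulate.simulate_arrays(truth, design, config, species)
    scan = preprocess.apply_qc(scan)
    analyzable = preprocess.filter_min_arrays(scan, min_arrays)
    log.info(
        "%s: %d features, %d analyzable after QC", species,
        config.n_features, len(analyzable),
    )
    corrected = preprocess.background_correct_minimum(scan)
    ma_raw = preprocess.compute_ma(corrected, design)
    return ExperimentData(
        species=species, config=config, annotation=annotation, truth=truth,
        meta=meta, design=design, scan=scan, ma_raw=ma_raw,
        analyzable=analyzable,
    )


def analyze_experiment(
    data: ExperimentData,
    normalization_set: str = "conserved_1000",
    alpha: float = 0.1,
    span: float = 0.4,
    one_sided: bool = False,
) -> ExperimentResult:
    """Normalize, test and score one experiment under one strategy."""
    ma = preprocess.loess_normalize(
        data.ma_raw, normalization_set, data.annotation, span=span
    )
    results, prior = detect.run_tests(
        ma, data.analyzable, alpha=alpha, one_sided=one_sided
    )
    summary = evaluate.summarize_calls(
        results, data.annotation, data.analyzable,
        species=data.species, normalization=normalization_set,
    )
    log.info(
        "%s/%s: tp=%d fp=%d fn=%d (tp %d%%, fp %d%%)", data.species,
        normalization_set, summary.tp, summary.fp, summary.fn,
        summary.tp_pct, summary.fp_pct,
    )
    return ExperimentResult(
        normalization=normalization_set, results=results, prior=prior,
        summary=summary,
    )


def divergence_profile_for(data: ExperimentData) -> pd.DataFrame:
    """Fabricate hit tables for the experiment's species and derive the
    per-feature divergence/confounder profile."""
    if data.species == PLATFORM:
        raise ValueError("the platform species has no heterologous hit table")
    hits_het, hits_ref = simulate.simulate_hit_tables(
        data.truth, data.annotation, data.meta, data.config, data.species
    )
    return core.derive_divergence_profile(
        hits_het, hits_ref, data.annotation,
        data.meta[data.species], data.meta[PLATFORM],
    )


# ---------------------------------------------------------------------------
# file-based pipeline


_SIM_SCALAR_FIELDS = {
    f.name
    for f in dataclasses.fields(SimulationConfig)
    if f.name not in ("divergence_model", "dye_bias", "confounder_probs")
}


@dataclass
class RunConfig:
    """Validated configuration for a file-based pipeline run."""

    out_dir: str
    species: str = "simulans_like"
    normalization_set: str = "conserved_1000"
    alpha: float = 0.1
    span: float = 0.4
    min_arrays: int = 2
    one_sided: bool = False
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim_raw = dict(raw.pop("simulation", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(raw) - known
        if unknown:
            raise core.ValidationError(f"unknown config key(s): {sorted(unknown)}")
        sim_kwargs = {}
        for key, value in sim_raw.items():
            if key == "divergence_model":
                sim_kwargs[key] = {
                    sp: IdentityModel(**params) for sp, params in value.items()
                }
            elif key == "dye_bias":
                sim_kwargs[key] = DyeBias(**value)
            elif key == "confounder_probs":
                sim_kwargs[key] = ConfounderProbs(**value)
            elif key in _SIM_SCALAR_FIELDS:
                sim_kwargs[key] = value
            else:
                raise core.ValidationError(f"unknown simulation key: {key}")
        config = cls(simulation=SimulationConfig(**sim_kwargs), **raw)
        config.validate()
        return config

    def validate(self) -> None:
        if self.normalization_set not in preprocess.NORMALIZATION_SETS:
            raise core.ValidationError(
                f"normalization_set must be one of {preprocess.NORMALIZATION_SETS}"
            )
        if not 0 < self.alpha < 1:
            raise core.ValidationError("alpha must lie in (0, 1)")
        if self.min_arrays > self.simulation.n_arrays:
            raise core.ValidationError(
                f"min_arrays={self.min_arrays} exceeds n_arrays="
                f"{self.simulation.n_arrays}"
            )
        self.simulation.validate()


def load_run_config(path, seed: int | None = None) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    config = RunConfig.from_dict(raw)
    if seed is not None:
        config.simulation = dataclasses.replace(config.simulation, seed=seed)
    return config


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    Rerunning with the same config and seed reproduces every output file
    byte-identically.  Returns the output directory.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data = simulate_experiment(
        config.species, config.simulation, min_arrays=config.min_arrays
    )
    core.write_feature_annotation(data.annotation, out / "annotation.tsv")
    core.write_design(data.design, out / "design.tsv")
    core.write_scan_table(data.scan, out / "scan.tsv")
    data.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    for label, meta in data.meta.items():
        core.write_genome_meta(meta, out / f"genome_meta_{label}.tsv")

    result = analyze_experiment(
        data, config.normalization_set, alpha=config.alpha, span=config.span,
        one_sided=config.one_sided,
    )
    ma_norm = preprocess.loess_normalize(
        data.ma_raw, config.normalization_set, data.annotation, span=config.span
    )
    ma_norm.to_csv(out / "ma_normalized.tsv", sep="\t", index=False)
    result.results.to_csv(out / "test_results.tsv", sep="\t", index=False)

    summaries = [result.summary]
    curves = None
    if config.species != PLATFORM:
        profile = divergence_profile_for(data)
        profile.to_csv(out / "divergence_profile.tsv", sep="\t", index=False)
        curve = evaluate.detection_by_divergence(
            result.results, profile, data.annotation
        )
        curves = {f"{config.species}_{config.normalization_set}": curve}
        res = result.results
        fn_ids = res.loc[
            res["feature_id"].map(
                data.annotation.set_index("feature_id")["is_x"]
            ).astype(bool) & ~res["called_excess"], "feature_id",
        ]
        fp_ids = res.loc[
            ~res["feature_id"].map(
                data.annotation.set_index("feature_id")["is_x"]
            ).astype(bool) & res["called_excess"], "feature_id",
        ]
        fn_break = evaluate.classify_error_confounders(
            fn_ids, "false_negative", data.annotation, profile
        )
        fp_break = evaluate.classify_error_confounders(
            fp_ids, "false_positive", data.annotation, profile
        )
        evaluate.build_report(
            summaries, out,
            fn_breakdowns={config.species: fn_break},
            fp_breakdowns={config.species: fp_break},
            divergence_curves=curves,
        )
    else:
        evaluate.build_report(summaries, out)

    gel = detect.gel50(
        result.prior, df_typical=config.simulation.n_arrays - 1,
        n_arrays=config.simulation.n_arrays, alpha=config.alpha,
        seed=config.simulation.seed,
    )
    manifest = {
        "species": config.species,
        "normalization_set": config.normalization_set,
        "alpha": config.alpha,
        "span": config.span,
        "seed": config.simulation.seed,
        "n_features": config.simulation.n_features,
        "n_arrays": config.simulation.n_arrays,
        "n_analyzable": len(data.analyzable),
        "prior_d0": result.prior.d0,
        "prior_s0_sq": result.prior.s0_sq,
        "gel50": gel,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
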