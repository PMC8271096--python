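"""End-to-end pipeline: generate -> derive -> fit -> variables -> stats.

Each stage reads the artifacts of the previous one from the output directory
and writes its own, so stages can be rerun independently; a stage invoked
before its prerequisite raises a DependencyError naming the missing stage.
Every run is a pure function of the RunConfig (including its master seed),
and each artifact directory carries the config and its hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .derive import derive_subject
from .exceptions import DependencyError, InvalidArgumentError
from .fitting import FitGrid, default_grid, fit_cohort
from .simulate import SimulationConfig
from .stats import (fit_pattern_correlations, mlr_fit,
                    optimal_parameter_distances, pairwise_wilcoxon)
from .synthetic import (NoiseSpec, coarsen_subject, make_bold_cohort,
                        make_parcellation_hierarchy)
from .variables import cohort_variable_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run.

    The defaults describe a desk-scale run: 3 subjects, a 24-unit hierarchy
    with 2 granularity levels, one model, a 4 x 4 grid and 600 s simulations.
    """

    n_subjects: int = 3
    n_fine: int = 24
    granularities: tuple = (24, 12)
    model_kind: str = "phase"
    true_tau: float = 6.0
    true_coupling: float = 0.3
    seed: int = 0
    grid: str = "reduced"              # "default" or "reduced"
    tau_values: tuple = (0.0, 2.0, 4.0, 6.0)
    c_values: tuple = (0.1, 0.2, 0.3, 0.4)
    sim_duration: float = 600.0
    sim_transient: float = 100.0
    noise_amplitude: float = 0.3
    subject_sigma: float = 0.2
    frequency_sigma: float = 0.1
    measurement_noise: float = 0.5
    correction: str = "bonferroni"
    alpha: float = 0.05
    delta: float = 0.1
    mlr_variables: tuple = ("std[aver(eFC)]", "corr(eFC,eSC)")

    def fit_grid(self) -> FitGrid:
        if self.grid == "default":
            return default_grid()
        return FitGrid(tau_values=np.asarray(self.tau_values),
                       c_values=np.asarray(self.c_values))

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(duration=self.sim_duration,
                                transient=self.sim_transient,
                                noise_amplitude=self.noise_amplitude,
                                seed=self.seed, model_kind=self.model_kind)

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(subject_sigma=self.subject_sigma,
                         frequency_sigma=self.frequency_sigma,
                         measurement=self.measurement_noise)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        for key in ("granularities", "tau_values", "c_values",
                    "mlr_variables"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _write_config(config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    (out / "config.hash").write_text(config.digest())


def _require(path: Path, stage: str, needed_by: str) -> None:
    if not path.exists():
        raise DependencyError(
            f"{needed_by}: missing artifact {path.name}; "
            f"run the '{stage}' stage first")


def _load_cohort(config: RunConfig, out: Path):
    levels = pio.load_parcellation_hierarchy(out / "parcellation.json")
    by_id = {p.level_id: p for p in levels}
    bundles = []
    for bdir in sorted((out / "bundles").iterdir()):
        if not bdir.is_dir():
            continue
        level_id = bdir.name.split("__")[1]
        bundles.append(pio.load_bundle(bdir, by_id[level_id]))
    return levels, bundles


def stage_generate(config: RunConfig, out) -> list:
    """Synthesize the cohort at every granularity level and persist it."""
    out = Path(out)
    _write_config(config, out)
    t0 = time.time()
    levels = make_parcellation_hierarchy(
        config.n_fine, list(config.granularities), seed=config.seed)
    pio.save_parcellation_hierarchy(levels, out / "parcellation.json")
    finest = levels[0]
    ground_truth = {"model_kind": config.model_kind, "tau": config.true_tau,
                    "coupling": config.true_coupling}
    cohort = make_bold_cohort(config.n_subjects, finest, ground_truth,
                              noise_spec=config.noise_spec(),
                              seed=config.seed)
    bundles = []
    for bundle in cohort:
        for level in levels:
            coarse = coarsen_subject(bundle, level)
            bundles.append(coarse)
            pio.save_bundle(coarse, out / "bundles" /
                            f"{coarse.subject_id}__{level.level_id}")
    logger.info("generate: %d bundles (seed=%d) in %.1fs",
                len(bundles), config.seed, time.time() - t0)
    return bundles


def stage_derive(config: RunConfig, out) -> None:
    """Persist the derived model inputs (f, a, conventions) per bundle."""
    out = Path(out)
    _require(out / "bundles", "generate", "derive")
    _, bundles = _load_cohort(config, out)
    for bundle in bundles:
        network, params = derive_subject(bundle)
        payload = {"subject_id": bundle.subject_id,
                   "level_id": bundle.parcellation.level_id,
                   "mean_convention": network.mean_convention,
                   "frequencies_hz": params.frequencies.tolist(),
                   "amplitudes": params.amplitudes.tolist()}
        bdir = (out / "bundles" /
                f"{bundle.subject_id}__{bundle.parcellation.level_id}")
        (bdir / "derived.json").write_text(json.dumps(payload, indent=1))
    logger.info("derive: %d bundles", len(bundles))


def stage_fit(config: RunConfig, out) -> pd.DataFrame:
    """Grid-search every bundle; write the long-format results table."""
    out = Path(out)
    _require(out / "bundles", "generate", "fit")
    _, bundles = _load_cohort(config, out)
    t0 = time.time()
    results = fit_cohort(bundles, config.model_kind, config.fit_grid(),
                         config.sim_config())
    results.insert(0, "config_hash", config.digest())
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    logger.info("fit: %d rows in %.1fs", len(results), time.time() - t0)
    return results


def stage_variables(config: RunConfig, out) -> pd.DataFrame:
    """Compute the data-variable table for every bundle."""
    out = Path(out)
    _require(out / "bundles", "generate", "variables")
    _, bundles = _load_cohort(config, out)
    table = cohort_variable_table(bundles)
    table.insert(0, "config_hash", config.digest())
    table.to_csv(out / "variables.tsv", sep="\t", index=False)
    logger.info("variables: %d rows", len(table))
    return table


def stage_stats(config: RunConfig, out) -> dict:
    """Cross-parcellation statistics from the fit and variable tables."""
    out = Path(out)
    _require(out / "results.tsv", "fit", "stats")
    _require(out / "variables.tsv", "variables", "stats")
    results = pd.read_csv(out / "results.tsv", sep="\t")
    variables = pd.read_csv(out / "variables.tsv", sep="\t")
    functional = results[results["target"] != "esc"]
    wide = functional.pivot_table(index=["subject", "target"],
                                  columns="parcellation", values="fit")
    report = {"config_hash": config.digest(), "seed": config.seed,
              "alpha": config.alpha, "correction": config.correction}
    patterns = fit_pattern_correlations(wide, alpha=config.alpha)
    report["fit_pattern_r"] = patterns.r.to_dict()
    report["fit_pattern_p"] = patterns.p.to_dict()
    report["intra_atlas_mean"] = patterns.intra_atlas_mean
    report["inter_atlas_mean"] = patterns.inter_atlas_mean
    patterns.r.to_csv(out / "fit_pattern_r.tsv", sep="\t")
    if len(wide) >= 5 and wide.shape[1] >= 2:
        wil = pairwise_wilcoxon(wide, correction=config.correction)
        report["wilcoxon_p_corrected"] = wil.p_corrected.to_dict()
        report["wilcoxon_effect"] = wil.effect.to_dict()
        wil.p_corrected.to_csv(out / "wilcoxon_p.tsv", sep="\t")
    # optimal-parameter distances, concatenated-session optima
    conc = results[results["target"] == "concatenated"].sort_values("subject")
    optima = {parc: sub[["tau_opt", "c_opt"]].to_numpy()
              for parc, sub in conc.groupby("parcellation")}
    dist = optimal_parameter_distances(optima)
    report["optimum_distance"] = dist.to_dict()
    dist.to_csv(out / "optimum_distances.tsv", sep="\t")
    # MLR of the concatenated-session fit on selected variables
    merged = conc.merge(variables[variables["scope"] == "concatenated"],
                        on=["subject", "parcellation"])
    mlr_vars = [v for v in config.mlr_variables if v in merged.columns]
    if len(merged) > len(mlr_vars) + 1 and mlr_vars:
        try:
            mlr = mlr_fit(merged[mlr_vars], merged["fit"])
            report["mlr"] = {"r_squared": mlr.r_squared,
                             "coefficients": mlr.coefficients.to_dict(),
                             "p_values": mlr.p_values.to_dict()}
        except InvalidArgumentError as exc:
            logger.warning("joint MLR skipped: %s", exc)
    (out / "stats_report.json").write_text(
        json.dumps(report, indent=1, default=float))
    logger.info("stats: report written")
    return report


STAGES = {"generate": stage_generate, "derive": stage_derive,
          "fit": stage_fit, "variables": stage_variables,
          "stats": stage_stats}


def run_all(config: RunConfig, out) -> dict:
    """Run every stage in order and return the stats report."""
    stage_generate(config, out)
    stage_derive(config, out)
    stage_fit(config, out)
    stage_variables(config, out)
    return stage_stats(config, out)
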