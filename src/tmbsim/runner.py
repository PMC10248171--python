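"""Scenario orchestration and command-line interface.

Ties the stages into the three experiments the library exists for — caller
instability across a heterogeneous cohort, consensus-voting ensemble errors,
and the survival measurement-error bias study — plus the PAC table.  Every
scenario runs deterministically from one master seed and writes plain files
(CSV/JSON/VCF) plus a JSON run manifest (config hash, seed, library
versions, output checksums) sufficient to reproduce the outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_sim import (
    SampleSpec,
    SeqNoise,
    ValidationError,
    make_cohort,
    write_cohort_manifest,
    write_truth_csv,
    write_truth_vcf,
)
from .pac_bounds import pac_table
from .rule_caller import (
    call_sample,
    consensus_call,
    default_ensemble,
    matched_ruleset,
    snv_tuned_ruleset,
    write_calls_vcf,
)
from .survival_bias import WeibullCoxParams, attenuation_study
from .tmb_error import cohort_error_stats

__all__ = ["SCENARIOS", "ScenarioConfig", "StageError", "load_config",
           "run_scenario", "cli"]

log = logging.getLogger("tmbsim")

SCENARIOS = ("caller-instability", "ensemble", "survival-bias", "pac-table")


class StageError(RuntimeError):
    """A scenario stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ScenarioConfig:
    scenario: str
    seed: int = 0
    outdir: Path = Path("runs")
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if not isinstance(self.params, dict):
            raise ValidationError("params must be a mapping")


def load_config(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = ScenarioConfig(
        scenario=raw.get("scenario", ""),
        seed=int(raw.get("seed", 0)),
        outdir=Path(raw.get("outdir", "runs")),
        params=raw.get("params", {}) or {},
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _base_spec(params: dict) -> SampleSpec:
    noise_kwargs = params.get("seq_noise", {})
    spec_kwargs = {k: v for k, v in params.items()
                   if k in ("n_variants", "composition", "region_size_mb",
                            "vaf_range", "n_background")}
    if "composition" in spec_kwargs:
        spec_kwargs["composition"] = tuple(spec_kwargs["composition"])
    if "vaf_range" in spec_kwargs:
        spec_kwargs["vaf_range"] = tuple(spec_kwargs["vaf_range"])
    return SampleSpec(seq_noise=SeqNoise(**noise_kwargs), **spec_kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: ScenarioConfig) -> str:
    canon = json.dumps({"scenario": cfg.scenario, "seed": cfg.seed,
                        "params": cfg.params}, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# scenario stages
# ---------------------------------------------------------------------------

def _run_caller_instability(cfg: ScenarioConfig, outdir: Path) -> list[Path]:
    p = cfg.params
    n_samples = int(p.get("n_samples", 10))
    base = _base_spec(p)
    ruleset = snv_tuned_ruleset() if p.get("ruleset", "snv_tuned") == \
        "snv_tuned" else matched_ruleset()
    outputs = []
    summary = {}
    for mode in ("heterogeneous", "homogeneous"):
        cohort = make_cohort(n_samples, mode, base, master_seed=cfg.seed)
        results = [call_sample(s, ruleset) for s in cohort]
        stats = cohort_error_stats(results, base.region_size_mb)
        path = outdir / f"instability_{mode}.csv"
        stats.to_csv(path)
        outputs.append(path)
        summary[mode] = {"cv_fpr_percent": stats.cv_fpr,
                         "cv_fnr_percent": stats.cv_fnr}
        log.info("%s cohort: CV(FPR)=%.2f%% CV(FNR)=%.2f%%", mode,
                 stats.cv_fpr, stats.cv_fnr)
    manifest_path = outdir / "cohort_manifest.json"
    cohort = make_cohort(n_samples, "heterogeneous", base,
                         master_seed=cfg.seed)
    write_cohort_manifest(cohort, manifest_path)
    outputs.append(manifest_path)
    vcf_path = outdir / "truth_S00.vcf"
    write_truth_vcf(cohort[0], vcf_path)
    outputs.append(vcf_path)
    summary_path = outdir / "instability_summary.json"
    summary["cv_fnr_ratio_het_over_hom"] = (
        summary["heterogeneous"]["cv_fnr_percent"]
        / summary["homogeneous"]["cv_fnr_percent"])
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    outputs.append(summary_path)
    return outputs


def _run_ensemble(cfg: ScenarioConfig, outdir: Path) -> list[Path]:
    p = cfg.params
    n_samples = int(p.get("n_samples", 15))
    min_votes = int(p.get("min_votes", 2))
    base = _base_spec(p)
    ens = default_ensemble(min_votes=min_votes)
    cohort = make_cohort(n_samples, p.get("composition_mode", "heterogeneous"),
                         base, master_seed=cfg.seed)
    consensus = [consensus_call(s, ens) for s in cohort]
    stats = cohort_error_stats(consensus, base.region_size_mb)
    outputs = []
    table_path = outdir / "ensemble_errors.csv"
    stats.to_csv(table_path)
    outputs.append(table_path)
    per_caller = {}
    for rs in ens.rulesets:
        caller_stats = cohort_error_stats(
            [call_sample(s, rs) for s in cohort], base.region_size_mb)
        per_caller[rs.name] = {"cv_fpr_percent": caller_stats.cv_fpr,
                               "cv_fnr_percent": caller_stats.cv_fnr,
                               "mean_fnr": caller_stats.mean_fnr}
    summary_path = outdir / "ensemble_summary.json"
    with open(summary_path, "w") as fh:
        json.dump({"min_votes": min_votes,
                   "consensus": {"cv_fpr_percent": stats.cv_fpr,
                                 "cv_fnr_percent": stats.cv_fnr,
                                 "mean_fnr": stats.mean_fnr},
                   "per_caller": per_caller}, fh, indent=2)
        fh.write("\n")
    outputs.append(summary_path)
    vcf_path = outdir / "consensus_calls_S00.vcf"
    write_calls_vcf(consensus[0], base.region_length, vcf_path)
    outputs.append(vcf_path)
    return outputs


def _run_survival_bias(cfg: ScenarioConfig, outdir: Path) -> list[Path]:
    p = cfg.params
    params = WeibullCoxParams(
        lam=float(p.get("lam", 1.5)),
        beta_z=tuple(p.get("beta_z", (0.5, -0.5))),
        beta_m=float(p.get("beta_m", 0.3)),
        tmb_mean=float(p.get("tmb_mean", 10.0)),
        tmb_sd=float(p.get("tmb_sd", 2.0)),
    )
    sigma_grid = [float(s) for s in p.get("sigma_grid", (0.0, 1.0, 2.0))]
    n_subjects = int(p.get("n_subjects", 1000))
    n_reps = int(p.get("n_reps", 30))
    censoring = float(p.get("censoring_rate", 0.3))
    rng = np.random.default_rng(cfg.seed)
    report = attenuation_study(params, sigma_grid, n_subjects, n_reps, rng,
                               censoring_rate=censoring)
    csv_path = outdir / "bias_report.csv"
    json_path = outdir / "bias_report.json"
    report.to_csv(csv_path)
    report.to_json(json_path)
    return [csv_path, json_path]


def _run_pac_table(cfg: ScenarioConfig, outdir: Path) -> list[Path]:
    p = cfg.params
    table = pac_table(tuple(p.get("eps_values", (0.01, 0.05, 0.1, 0.2))),
                      tuple(p.get("delta_values", (0.01, 0.05, 0.1))))
    path = outdir / "pac_table.csv"
    table.to_csv(path, index=False, float_format="%.6g")
    return [path]


_STAGES = {
    "caller-instability": _run_caller_instability,
    "ensemble": _run_ensemble,
    "survival-bias": _run_survival_bias,
    "pac-table": _run_pac_table,
}


def run_scenario(config: ScenarioConfig) -> dict:
    """Run one scenario end to end; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = _STAGES[config.scenario]
    try:
        outputs = stage(config, outdir)
    except Exception as exc:  # noqa: BLE001 - named-stage contract
        raise StageError(config.scenario, exc) from exc
    manifest = {
        "scenario": config.scenario,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "versions": {
            "tmbsim": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _common(scenario: str, seed: int, outdir: str, params: dict) -> None:
    cfg = ScenarioConfig(scenario=scenario, seed=seed, outdir=Path(outdir),
                         params=params)
    try:
        manifest = run_scenario(cfg)
    except (StageError, ValidationError) as exc:
        raise click.ClickException(str(exc)) from exc
    click.echo(json.dumps(manifest, indent=2))


@click.group()
@click.option("--verbose", is_flag=True, help="Enable info logging.")
def cli(verbose: bool) -> None:
    """Synthetic TMB measurement-error study pipeline."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--samples", default=10, show_default=True)
@click.option("--mode", default="heterogeneous", show_default=True,
              type=click.Choice(["heterogeneous", "homogeneous"]))
@click.option("--seed", default=0, show_default=True)
@click.option("--outdir", default="runs/simulate", show_default=True)
def simulate(samples: int, mode: str, seed: int, outdir: str) -> None:
    """Generate a synthetic cohort: truth VCF/CSV per sample + manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(samples, mode, SampleSpec(), master_seed=seed)
    for s in cohort:
        write_truth_vcf(s, out / f"truth_{s.sample_id}.vcf")
        write_truth_csv(s, out / f"truth_{s.sample_id}.csv")
    write_cohort_manifest(cohort, out / "cohort_manifest.json")
    click.echo(f"wrote {samples} samples to {out}")


@cli.command(name="call")
@click.option("--seed", default=0, show_default=True)
@click.option("--outdir", default="runs/call", show_default=True)
@click.option("--samples", default=10, show_default=True)
def call_cmd(seed: int, outdir: str, samples: int) -> None:
    """Caller-instability experiment (per-sample FPR/FNR + CV footer)."""
    _common("caller-instability", seed, outdir, {"n_samples": samples})


@cli.command()
@click.option("--seed", default=0, show_default=True)
@click.option("--outdir", default="runs/ensemble", show_default=True)
@click.option("--samples", default=15, show_default=True)
@click.option("--min-votes", default=2, show_default=True)
def ensemble(seed: int, outdir: str, samples: int, min_votes: int) -> None:
    """Consensus-voting ensemble experiment."""
    _common("ensemble", seed, outdir,
            {"n_samples": samples, "min_votes": min_votes})


@cli.command(name="survival-bias")
@click.option("--seed", default=0, show_default=True)
@click.option("--outdir", default="runs/survival", show_default=True)
@click.option("--subjects", default=1000, show_default=True)
@click.option("--reps", default=30, show_default=True)
def survival_bias_cmd(seed: int, outdir: str, subjects: int,
                      reps: int) -> None:
    """Measurement-error attenuation study over an error-SD grid."""
    _common("survival-bias", seed, outdir,
            {"n_subjects": subjects, "n_reps": reps})


@cli.command(name="pac-table")
@click.option("--seed", default=0, show_default=True)
@click.option("--outdir", default="runs/pac", show_default=True)
def pac_table_cmd(seed: int, outdir: str) -> None:
    """PAC sample-complexity table over an (eps, delta) grid."""
    _common("pac-table", seed, outdir, {})


@cli.command()
@click.option("--config", "config_path", required=True,
              type=click.Path(exists=True), help="YAML scenario config.")
@click.option("--seed", default=None, type=int,
              help="Override the config seed.")
@click.option("--outdir", default=None, help="Override the config outdir.")
def run(config_path: str, seed: int | None, outdir: str | None) -> None:
    """Run a full scenario from a YAML config."""
    try:
        cfg = load_config(config_path)
    except ValidationError as exc:
        raise click.ClickException(str(exc)) from exc
    if seed is not None:
        cfg.seed = seed
    if outdir is not None:
        cfg.outdir = Path(outdir)
    try:
        manifest = run_scenario(cfg)
    except (StageError, ValidationError) as exc:
        raise click.ClickException(str(exc)) from exc
    click.echo(json.dumps(manifest, indent=2))
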