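"""Factorial simulation-study orchestration and command-line interface.

Runs the full methods x N x K x rho x replications grid: for every triple
(condition, method, replication) a truth bundle is generated (or reloaded),
the method is fitted, and the estimates are persisted as JSON next to the
truth CSVs.  Completed triples are detected and skipped on rerun, so a
study can be resumed, and the artifact directory alone suffices to rebuild
every recovery-table cell.  Every triple draws its seeds from the master
seed deterministically, so replications can run in any order.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import click
import numpy as np
import pandas as pd
import yaml

from .bayesian_samplers import (
    PosteriorSummary,
    SamplerConfig,
    run_gibbs,
    run_hwg,
    run_mh,
)
from .evaluation import assemble_recovery_table, condition_cells, render_recovery_table
from .mml_baem import EMConfig, fit_baem
from .synthetic_data import (
    StudyCondition,
    TruthBundle,
    generate_dataset,
    read_bundle,
    write_bundle,
)

logger = logging.getLogger(__name__)

METHODS = ("gibbs", "hwg", "mh_true", "mh_aic", "mh_cor", "bm", "baem")

__all__ = [
    "StudyConfig",
    "run_study",
    "run_recovery_cells",
    "evaluate_study",
    "fit_one",
    "cli",
    "METHODS",
    "default_study_config",
]


@dataclass
class StudyConfig:
    conditions: list[StudyCondition]
    methods: Sequence[str] = METHODS
    n_replications: int = 10
    sampler_config: SamplerConfig = field(default_factory=SamplerConfig)
    em_config: EMConfig = field(default_factory=EMConfig)
    master_seed: int = 0
    output_dir: Path = Path("study_out")
    aic_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 0.91, 0.1), 1))
    aic_replications: int = 3  # the AIC arm is 10x the cost of the others

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def default_study_config(**overrides) -> StudyConfig:
    """The full 2 x 2 x 3 factorial with ten replications."""
    conditions = [
        StudyCondition(n, k, r)
        for n in (500, 1000)
        for k in (20, 40)
        for r in (0.2, 0.5, 0.8)
    ]
    return StudyConfig(conditions=conditions, **overrides)


def _triple_seed(master_seed: int, condition: StudyCondition, rep: int, method: str) -> int:
    key = f"{master_seed}|{condition.label()}|{rep}|{method}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def fit_one(
    method: str,
    bundle: TruthBundle,
    sampler_config: SamplerConfig,
    em_config: EMConfig,
    aic_grid: Sequence[float] = (),
) -> dict:
    """Fit a single method on one dataset; returns a JSON-ready estimate
    dict with at least ``alpha``, ``thresholds`` and ``rho``."""
    Y, design, cond = bundle.Y, bundle.design, bundle.condition
    if method == "gibbs":
        return run_gibbs(Y, design, sampler_config).to_dict()
    if method == "hwg":
        return run_hwg(Y, design, sampler_config).to_dict()
    if method == "bm":
        return run_mh(Y, design, replace(sampler_config, rho_mode="sampled")).to_dict()
    if method == "mh_true":
        return run_mh(Y, design, sampler_config, criterion="TRUE", true_rho=cond.rho).to_dict()
    if method == "mh_cor":
        return run_mh(Y, design, sampler_config, criterion="COR").to_dict()
    if method == "mh_aic":
        grid = np.asarray(aic_grid if len(aic_grid) else np.arange(0.0, 0.91, 0.1))
        return run_mh(Y, design, sampler_config, criterion="AIC", rho_grid=grid).to_dict()
    if method == "baem":
        state = fit_baem(Y, design, em_config)
        return {
            "method": "baem",
            "alpha": state.params.alpha.tolist(),
            "thresholds": state.params.thresholds_matrix().tolist(),
            "rho": state.rho,
            "marginal_loglik": state.marginal_loglik,
            "aic": state.aic,
            "iterations": state.iteration,
            "converged": state.converged,
        }
    raise ValueError(f"unknown method {method!r}")


def run_recovery_cells(
    condition: StudyCondition,
    method: str,
    n_replications: int,
    sampler_config: Optional[SamplerConfig] = None,
    em_config: Optional[EMConfig] = None,
    aic_grid: Sequence[float] = (),
    master_seed: int = 0,
) -> dict:
    """In-memory recovery cells for one (condition, method): generate the
    replications, fit, and return ``{parameter_class: RecoveryCell}``."""
    sampler_config = sampler_config or SamplerConfig()
    em_config = em_config or EMConfig()
    condition = replace(condition, seed=master_seed)
    truths, estimates = [], []
    for rep in range(n_replications):
        bundle = generate_dataset(condition, rep)
        scfg = replace(
            sampler_config, seed=_triple_seed(master_seed, condition, rep, method)
        )
        est = fit_one(method, bundle, scfg, em_config, aic_grid)
        truths.append(_truth_dict(bundle))
        estimates.append(est)
    cells = condition_cells(condition, method, truths, estimates)
    return {c.parameter_class: c for c in cells}


def _truth_dict(bundle: TruthBundle) -> dict:
    return {
        "alpha": bundle.params.alpha,
        "thresholds": bundle.params.thresholds_matrix(),
        "rho": bundle.condition.rho,
    }


def run_study(config: StudyConfig) -> tuple[pd.DataFrame, int]:
    """Execute (or resume) the factorial study.

    Returns the long-format recovery table and the number of failed
    triples; failures are logged and their cells recorded as missing.
    """
    n_failures = 0
    for condition in config.conditions:
        condition = replace(condition, seed=config.master_seed)
        cond_dir = config.output_dir / condition.label()
        for rep in range(config.n_replications):
            rep_dir = cond_dir / f"rep{rep:02d}"
            if (rep_dir / "condition.json").exists():
                bundle = read_bundle(rep_dir)
            else:
                bundle = generate_dataset(condition, rep)
                write_bundle(rep_dir, bundle, rep)
            for method in config.methods:
                if method == "mh_aic" and rep >= config.aic_replications:
                    continue
                est_path = rep_dir / f"est_{method}.json"
                if est_path.exists():
                    continue
                seed = _triple_seed(config.master_seed, condition, rep, method)
                scfg = replace(config.sampler_config, seed=seed)
                t0 = time.perf_counter()
                try:
                    est = fit_one(method, bundle, scfg, config.em_config, config.aic_grid)
                except Exception:
                    logger.exception(
                        "fit failed: %s rep %d method %s", condition.label(), rep, method
                    )
                    n_failures += 1
                    continue
                est_path.write_text(json.dumps(est, indent=2))
                logger.info(
                    "%s rep %d %s done in %.1fs",
                    condition.label(),
                    rep,
                    method,
                    time.perf_counter() - t0,
                )
    table = evaluate_study(config)
    return table, n_failures


def evaluate_study(config: StudyConfig) -> pd.DataFrame:
    """Rebuild the recovery table from the persisted artifact directory
    without refitting anything."""
    cells = []
    for condition in config.conditions:
        condition = replace(condition, seed=config.master_seed)
        cond_dir = config.output_dir / condition.label()
        for method in config.methods:
            truths, estimates = [], []
            for rep in range(config.n_replications):
                rep_dir = cond_dir / f"rep{rep:02d}"
                est_path = rep_dir / f"est_{method}.json"
                if not est_path.exists():
                    continue
                bundle = read_bundle(rep_dir)
                truths.append(_truth_dict(bundle))
                estimates.append(json.loads(est_path.read_text()))
            if truths:
                cells.extend(condition_cells(condition, method, truths, estimates))
    table = assemble_recovery_table(cells)
    table.to_csv(config.output_dir / "recovery_table.csv", index=False)
    (config.output_dir / "recovery_table.txt").write_text(render_recovery_table(table))
    return table


def _config_from_yaml(path: str | Path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text())
    conditions = [StudyCondition(**c) for c in raw.pop("conditions")]
    sampler = SamplerConfig(**raw.pop("sampler_config", {}))
    em = EMConfig(**raw.pop("em_config", {}))
    return StudyConfig(conditions=conditions, sampler_config=sampler, em_config=em, **raw)


# ---------------------------------------------------------------------------
# Command-line interface
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log per-triple progress.")
def cli(verbose: bool) -> None:
    """Multi-unidimensional graded response model: simulation, estimation
    and recovery evaluation."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@cli.command()
@click.option("--n", type=int, required=True, help="Persons.")
@click.option("--k", type=int, required=True, help="Items (split over 2 subscales).")
@click.option("--rho", type=float, required=True, help="Intertrait correlation.")
@click.option("--categories", type=int, default=3, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--rep", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def simulate(n, k, rho, categories, seed, rep, out) -> None:
    """Write one truth bundle (responses, item parameters, traits)."""
    condition = StudyCondition(n, k, rho, n_categories=categories, seed=seed)
    bundle = generate_dataset(condition, rep)
    write_bundle(out, bundle, rep)
    click.echo(f"wrote {condition.label()} rep {rep} to {out}")


@cli.command()
@click.option("--method", type=click.Choice(METHODS), required=True)
@click.option("--data", "data_dir", type=click.Path(exists=True), required=True)
@click.option("--iterations", type=int, default=10_000, show_default=True)
@click.option("--burnin", type=int, default=5_000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--link", type=click.Choice(["probit", "logistic"]), default="probit",
              show_default=True, help="Response function (EM engine only).")
@click.option("--out", type=click.Path(), required=True)
def fit(method, data_dir, iterations, burnin, seed, link, out) -> None:
    """Fit one method on a stored truth bundle; write the estimate JSON."""
    bundle = read_bundle(data_dir)
    scfg = SamplerConfig(n_iterations=iterations, burn_in=burnin, seed=seed)
    emcfg = EMConfig(link=link)
    est = fit_one(method, bundle, scfg, emcfg)
    Path(out).parent.mkdir(parents=True, exist_ok=True)
    Path(out).write_text(json.dumps(est, indent=2))
    click.echo(f"wrote {method} estimates to {out}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              help="YAML study config (overrides the flags below).")
@click.option("--n", "n_list", type=int, multiple=True, default=(500, 1000))
@click.option("--k", "k_list", type=int, multiple=True, default=(20, 40))
@click.option("--rho", "rho_list", type=float, multiple=True, default=(0.2, 0.5, 0.8))
@click.option("--method", "methods", type=click.Choice(METHODS), multiple=True,
              default=METHODS)
@click.option("--reps", type=int, default=10, show_default=True)
@click.option("--iterations", type=int, default=10_000, show_default=True)
@click.option("--burnin", type=int, default=5_000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), default="study_out", show_default=True)
@click.pass_context
def study(ctx, config_path, n_list, k_list, rho_list, methods, reps,
          iterations, burnin, seed, out) -> None:
    """Run (or resume) the full factorial recovery study."""
    if config_path:
        config = _config_from_yaml(config_path)
    else:
        conditions = [
            StudyCondition(n, k, r) for n in n_list for k in k_list for r in rho_list
        ]
        config = StudyConfig(
            conditions=conditions,
            methods=methods,
            n_replications=reps,
            sampler_config=SamplerConfig(n_iterations=iterations, burn_in=burnin),
            master_seed=seed,
            output_dir=Path(out),
        )
    config.output_dir.mkdir(parents=True, exist_ok=True)
    table, n_failures = run_study(config)
    click.echo(render_recovery_table(table))
    if n_failures:
        click.echo(f"{n_failures} triples failed; their cells are missing", err=True)
        ctx.exit(1)


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", type=click.Path(exists=True), default="study_out",
              show_default=True, help="Study artifact directory.")
def evaluate(config_path, out) -> None:
    """Rebuild the recovery table from persisted estimates (no refitting)."""
    if config_path:
        config = _config_from_yaml(config_path)
        config.output_dir = Path(out)
    else:
        config = default_study_config(output_dir=Path(out))
    table = evaluate_study(config)
    click.echo(render_recovery_table(table))


@cli.command()
@click.option("--summary", "summary_path", type=click.Path(exists=True), required=True)
def diagnose(summary_path) -> None:
    """Chain diagnostics report (ESS, Geweke z, acceptance rates) for a
    stored posterior summary."""
    try:
        s = PosteriorSummary.from_json(summary_path)
    except TypeError as exc:
        raise click.ClickException(
            f"{summary_path} is not an MCMC posterior summary (EM estimates "
            "carry no chain diagnostics)"
        ) from exc
    click.echo(f"method: {s.method}   draws: {s.n_draws}   seed: {s.seed}")
    click.echo(
        f"alpha ESS: min {s.alpha_ess.min():.0f} / median {np.median(s.alpha_ess):.0f}"
    )
    click.echo(
        "thresholds ESS: min "
        f"{s.thresholds_ess.min():.0f} / median {np.median(s.thresholds_ess):.0f}"
    )
    click.echo(
        f"max |Geweke z|: alpha {np.abs(s.alpha_geweke).max():.2f}, "
        f"thresholds {np.abs(s.thresholds_geweke).max():.2f}"
    )
    if not s.rho_fixed:
        click.echo(f"rho: {s.rho:.3f} (ESS {s.rho_ess:.0f}, Geweke z {s.rho_geweke:.2f})")
    for block, rate in s.acceptance_rates.items():
        if isinstance(rate, list):
            click.echo(f"acceptance[{block}]: mean {np.mean(rate):.2f}")
        else:
            click.echo(f"acceptance[{block}]: {rate:.2f}")


if __name__ == "__main__":
    cli()
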