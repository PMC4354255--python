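"""Config-driven orchestration of the full analysis.

Stages run in the order of the original workflow: control-survival QC and
replicate exclusion, day-bias diagnostics, phenomenological type tests per
community module (a module = prey x amphipod x parasitism x fish combination
across the density ladder), the between-module mechanistic fit, one
within-module fit per prey species with a simplified (intercept-only) attack
rate, bootstrap envelopes, and partial-consumption statistics.  Failures are
logged and independent later stages still run; the bootstrap depends on its
fit having succeeded.

Every output is a CSV (plus a plain-text log) and is reproducible from the
configuration and seed alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import design, fit as frfit, partial_feeding, simulate, typetest

__all__ = ["RunConfig", "RunResult", "run_analysis"]

MODULE_COLS = ["prey_species", "predator_species", "parasitised", "fish_present"]


@dataclass
class RunConfig:
    """One analysis run: input mode, stage switches, model options, seed."""

    mode: str = "synthetic"  # "synthetic" or "csv"
    scenario: object = None  # SimulationScenario, path, or None (default scenario)
    trials_path: str | None = None
    controls_path: str | None = None
    redraw_excluded: bool = False
    do_typetest: bool = True
    do_fit: bool = True
    do_bootstrap: bool = True
    do_partials: bool = True
    n_boot: int = 1500
    alpha: float = 0.05
    t: float = 1.0
    seed: int | None = None
    outdir: str = "results"

    def __post_init__(self):
        if self.mode not in ("synthetic", "csv"):
            raise ValueError(f"mode must be 'synthetic' or 'csv', got {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires an explicit seed")
        if self.mode == "csv" and not (self.trials_path and self.controls_path):
            raise ValueError("csv mode requires trials_path and controls_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class RunResult:
    outdir: Path
    outputs: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _logger(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"frmodules.run.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.propagate = False
    return logger


def _save(df: pd.DataFrame, outdir: Path, name: str, outputs: dict):
    path = outdir / name
    df.to_csv(path, index=False)
    outputs[name] = path
    return path


def run_analysis(config: RunConfig) -> RunResult:
    """Execute the configured stages and write their CSV outputs + log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _logger(outdir)
    result = RunResult(outdir=outdir)

    def fail(stage, exc):
        log.error("stage %s failed: %s", stage, exc)
        result.errors.append((stage, str(exc)))

    # --- data -------------------------------------------------------------
    try:
        if config.mode == "synthetic":
            scenario = config.scenario
            if scenario is None:
                scenario = simulate.study_design_scenario(seed=config.seed)
            elif isinstance(scenario, (str, Path)):
                scenario = simulate.load_scenario(scenario)
            if scenario.seed != config.seed and config.seed is not None:
                scenario = dataclasses.replace(scenario, seed=config.seed)
            trials, controls = simulate.simulate_dataset(
                scenario, redraw=config.redraw_excluded
            )
            log.info(
                "simulated %d trial pots and %d control pots (seed=%s, model=%s)",
                len(trials), len(controls), scenario.seed, scenario.observation_model,
            )
            design.write_records(trials, outdir / "trials.csv")
            design.write_controls(controls, outdir / "controls.csv")
            result.outputs["trials.csv"] = outdir / "trials.csv"
            result.outputs["controls.csv"] = outdir / "controls.csv"
        else:
            trials = design.read_records(config.trials_path)
            controls = design.read_controls(config.controls_path)
            log.info(
                "loaded %d trial pots and %d control pots", len(trials), len(controls)
            )
    except Exception as exc:  # no data, nothing else can run
        fail("data", exc)
        return result

    # --- QC ---------------------------------------------------------------
    kept = trials
    try:
        qc = design.control_survival_qc(controls)
        log.info(
            "control survival %.2f%% (threshold %.2f%%): %s",
            100 * qc.overall_survival, 100 * qc.threshold,
            "pass" if qc.passed else "FAIL",
        )
        _save(qc.table, outdir, "qc_controls.csv", result.outputs)
        result.summary["control_survival"] = qc.overall_survival

        kept, excluded = design.filter_replicates(trials)
        counts = (
            excluded["exclusion_reason"].value_counts().to_dict() if len(excluded) else {}
        )
        log.info("excluded %d of %d replicates: %s", len(excluded), len(trials), counts)
        _save(excluded, outdir, "exclusions.csv", result.outputs)
        result.summary["n_excluded"] = len(excluded)
    except Exception as exc:
        fail("qc", exc)

    # --- day bias ---------------------------------------------------------
    try:
        rows = []
        for key, grp in kept.groupby(MODULE_COLS):
            diag = design.day_bias_diagnostic(grp)
            rows.append(
                dict(zip(MODULE_COLS, key))
                | {"rho": diag.rho, "p": diag.p, "n": diag.n, "method": diag.method}
            )
        day_bias = pd.DataFrame(rows)
        _save(day_bias, outdir, "day_bias.csv", result.outputs)
        n_trend = int((day_bias["p"] < config.alpha).sum())
        log.info("day-bias diagnostic: %d/%d modules with p < %.2f",
                 n_trend, len(day_bias), config.alpha)
    except Exception as exc:
        fail("day_bias", exc)

    # --- type test ----------------------------------------------------------
    if config.do_typetest:
        try:
            rows = []
            for key, grp in kept.groupby(MODULE_COLS):
                res = typetest.classify_module(grp, alpha=config.alpha, t=config.t)
                row = dict(zip(MODULE_COLS, key))
                row.update(
                    {
                        "b0": res.logistic.coef[0],
                        "b1": res.logistic.coef[1],
                        "b2": res.logistic.coef[2],
                        "p1": res.logistic.pvalues[1],
                        "p2": res.logistic.pvalues[2],
                        "classification": res.classification,
                        "resolved_type": res.resolved_type,
                        "aic_I": None,
                        "aic_II": None,
                        "aic_III": None,
                    }
                )
                if res.aic_table is not None:
                    aics = res.aic_table.set_index("variant")["AIC"]
                    for v in ("I", "II", "III"):
                        row[f"aic_{v}"] = round(aics.get(v, float("nan")), 1)
                rows.append(row)
            tt = pd.DataFrame(rows)
            _save(tt, outdir, "type_test.csv", result.outputs)
            n2 = int((tt["resolved_type"] == "TypeII").sum())
            log.info("type test: %d/%d modules resolved Type II", n2, len(tt))
            result.summary["n_type2_modules"] = n2
            result.summary["n_modules"] = len(tt)
        except Exception as exc:
            fail("type_test", exc)

    # --- mechanistic fits ---------------------------------------------------
    fits = {}
    if config.do_fit:
        try:
            between = frfit.fit_fr(kept, frfit.between_module_spec(), t=config.t)
            _save(
                frfit.contrast_table(between), outdir,
                "fit_between_modules.csv", result.outputs,
            )
            log.info(
                "between-module fit: logLik=%.2f AIC=%.1f converged=%s",
                between.loglik, between.aic, between.converged,
            )
            fits["between"] = between
        except Exception as exc:
            fail("fit_between", exc)
        for prey, grp in kept.groupby("prey_species"):
            try:
                res = frfit.fit_fr(grp, frfit.within_module_spec(), t=config.t)
                _save(
                    frfit.contrast_table(res), outdir,
                    f"fit_{prey}.csv", result.outputs,
                )
                log.info(
                    "within-module fit %s: logLik=%.2f AIC=%.1f converged=%s",
                    prey, res.loglik, res.aic, res.converged,
                )
                fits[prey] = res
            except Exception as exc:
                fail(f"fit_{prey}", exc)

    # --- bootstrap envelopes -------------------------------------------------
    if config.do_bootstrap and config.do_fit:
        for prey, grp in kept.groupby("prey_species"):
            if prey not in fits:
                log.warning("skipping bootstrap for %s: no converged fit", prey)
                continue
            try:
                env = frfit.bootstrap_fr(
                    grp,
                    frfit.within_module_spec(),
                    n_boot=config.n_boot,
                    seed=config.seed,
                    t=config.t,
                    base_fit=fits[prey],
                )
                tables = []
                for predator in design.PREDATOR_SPECIES:
                    cell_env = dataclasses.replace(
                        env, cell={"predator_species": predator}
                    )
                    tab = frfit.predict_curve_ci(fits[prey], cell_env)
                    tab.insert(0, "predator_species", predator)
                    tables.append(tab)
                _save(
                    pd.concat(tables, ignore_index=True), outdir,
                    f"envelope_{prey}.csv", result.outputs,
                )
                log.info(
                    "bootstrap %s: %d/%d refits kept", prey, env.n_kept, env.n_boot
                )
            except Exception as exc:
                fail(f"bootstrap_{prey}", exc)

    # --- partial consumption --------------------------------------------------
    if config.do_partials:
        try:
            part = partial_feeding.partial_consumption_analysis(kept)
            _save(part.proportions, outdir, "partial_proportions.csv", result.outputs)
            _save(part.tests, outdir, "partial_tests.csv", result.outputs)
            if part.skipped:
                log.warning("partial consumption: no pot with >= 2 kills; tests skipped")
            else:
                log.info("partial consumption: %d eligible pots", len(part.observations))
        except Exception as exc:
            fail("partials", exc)

    log.info("run complete: %d outputs, %d stage failures",
             len(result.outputs), len(result.errors))
    return result
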