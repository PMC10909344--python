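"""Replicate experiments: paired full/control/increased/decreased runs.

One *run* is a complete life cycle (founders, infection, pairing,
reproduction, offspring infection, pooling) followed by three
capture-history sets drawn from the *same* population — a control set
(bias 1.0), an increased-capture set (bias drawn from U(1.1, 1.9)) and a
decreased-capture set (bias from U(0.1, 0.9)) — each with its own CJS
fit, plus the three outcome metrics evaluated on the truth and on every
sampled set.

An *experiment* repeats this ``n_runs`` times while perturbing the
parameter that drives the outcome of interest:

``fitness``
    infection penalty ~ U(0, 1) per run (prediction weight at default);
``relative_risk`` / ``allele_change``
    genotype prediction weight ~ U(0, 1) per run (penalty at default).

The resulting table (one row per run) feeds the statistical battery in
:mod:`capturebias.stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from . import population as pop_mod
from .cjs import CJSFit, fit_cjs
from .config import ScenarioConfig, stage_rng
from .metrics import MetricSet
from .sampling import build_capture_histories
from .stats import (
    delta_p_group_test,
    residual_bias_diagnostic,
    sma_fit_and_test,
    variance_test,
)

__all__ = ["RunResult", "run_single", "run_experiment", "summarize",
           "headline_slopes", "HEADLINE_SLOPES", "OUTCOMES", "SAMPLED_VARIANTS"]

logger = logging.getLogger(__name__)

OUTCOMES = ("fitness", "relative_risk", "allele_change")
SAMPLED_VARIANTS = ("control", "increased", "decreased")

#: Which metric column each outcome's slope analysis uses.
OUTCOME_METRIC = {
    "fitness": "corrected",
    "relative_risk": "rr",
    "allele_change": "dfreq",
}

_METRIC_FIELDS = {
    "raw": "repro_diff_raw",
    "corrected": "repro_diff_corrected",
    "rr": "relative_risk",
    "dfreq": "allele_freq_change",
}


@dataclass
class RunResult:
    """Everything recorded for one complete run."""

    run_index: int
    perturbed_parameter: str
    perturbed_value: float
    bias_low: float
    bias_high: float
    metric_sets: dict[str, MetricSet]  # full / control / increased / decreased
    fits: dict[str, CJSFit]            # control / increased / decreased
    population_checksum: int

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {
            "run": self.run_index,
            "perturbed_parameter": self.perturbed_parameter,
            "perturbed_value": self.perturbed_value,
            "bias_low": self.bias_low,
            "bias_high": self.bias_high,
            "population_checksum": self.population_checksum,
        }
        for variant, ms in self.metric_sets.items():
            for short, fld in _METRIC_FIELDS.items():
                row[f"{short}_{variant}"] = getattr(ms, fld)
        for variant, fit in self.fits.items():
            row[f"delta_p_{variant}"] = fit.delta_p
            row[f"p_infected_{variant}"] = fit.p_infected
            row[f"p_uninfected_{variant}"] = fit.p_uninfected
            row[f"phi_{variant}"] = fit.phi_hat
            row[f"converged_{variant}"] = float(fit.converged)
        return row


def _checksum(pop: pd.DataFrame) -> int:
    h = pd.util.hash_pandas_object(
        pop[["id", "geno", "infected", "generation"]], index=False
    )
    return int(h.to_numpy().sum() % np.uint64(2**63))


def run_single(
    config: ScenarioConfig,
    run_index: int = 0,
    perturbed_parameter: str = "",
    fit_detection: bool = True,
) -> RunResult:
    """One complete run of the model under ``config``.

    All randomness derives from ``config.seed`` keyed by ``run_index``
    and stage, so a given (seed, run_index) pair is exactly replayable.
    ``fit_detection=False`` skips the three CJS fits (the metrics do not
    depend on them).
    """
    seed = config.seed
    parents = pop_mod.make_founders(config, stage_rng(seed, run_index, "founders"))
    parents = pop_mod.apply_infection(parents, config, stage_rng(seed, run_index, "infect_parents"))
    pairs = pop_mod.pair_parents(parents, stage_rng(seed, run_index, "pairing"))
    offspring = pop_mod.reproduce(parents, pairs, config, stage_rng(seed, run_index, "reproduction"))
    if len(offspring):
        offspring = pop_mod.apply_infection(
            offspring, config, stage_rng(seed, run_index, "infect_offspring")
        )
    pooled = pop_mod.pool_generations(parents, offspring)

    rng_bias = stage_rng(seed, run_index, "bias_draws")
    bias_low = float(rng_bias.uniform(*config.bias_low_range))
    bias_high = float(rng_bias.uniform(*config.bias_high_range))
    bias_of = {"control": 1.0, "increased": bias_high, "decreased": bias_low}

    metric_sets = {
        "full": metrics_mod.compute_metric_set(
            parents, offspring, pooled, config.scheme, "full"
        )
    }
    fits: dict[str, CJSFit] = {}
    control_roster: set | None = None
    for variant in SAMPLED_VARIANTS:
        rng = stage_rng(seed, run_index, f"sample_{variant}")
        history = build_capture_histories(pooled, config, bias_of[variant], rng)
        if variant == "control":
            control_roster = set(
                history.individuals.loc[
                    history.detected_any()
                    & (history.individuals["generation"] == "parent"),
                    "id",
                ].tolist()
            )
        metric_sets[variant] = metrics_mod.compute_metric_set(
            parents, offspring, pooled, config.scheme, variant,
            history=history,
            require_parent_detected=config.require_parent_detected,
            # biased variants reuse the control roster: the marked-parent
            # list comes from the unbiased reference sampling
            parent_roster=None if variant == "control" else control_roster,
        )
        if fit_detection:
            fit = fit_cjs(history)
            if not fit.converged:
                logger.warning("run %d %s: CJS fit did not converge", run_index, variant)
            fits[variant] = fit

    return RunResult(
        run_index=run_index,
        perturbed_parameter=perturbed_parameter,
        perturbed_value=(
            config.effective_penalty if perturbed_parameter == "infection_penalty"
            else config.genotype_prediction_value
        ),
        bias_low=bias_low,
        bias_high=bias_high,
        metric_sets=metric_sets,
        fits=fits,
        population_checksum=_checksum(pooled),
    )


def run_experiment(
    outcome: str,
    scheme: str | None = None,
    config: ScenarioConfig | None = None,
    fit_detection: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Run ``config.n_runs`` replicates for one outcome of interest.

    Returns the experiment table, one row per run with all four metric
    variants and the three CJS fits.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    config = config or ScenarioConfig()
    if scheme is not None:
        config = config.replace(scheme=scheme)

    rows = []
    for i in range(config.n_runs):
        draw = float(stage_rng(config.seed, i, "perturb").uniform(0.0, 1.0))
        if outcome == "fitness":
            cfg_run = config.replace(infection_penalty=draw, penalty_is_loss=False)
            pname = "infection_penalty"
        else:
            cfg_run = config.replace(genotype_prediction_value=draw)
            pname = "genotype_prediction_value"
        result = run_single(cfg_run, run_index=i, perturbed_parameter=pname,
                            fit_detection=fit_detection)
        rows.append(result.to_row())
        if progress and (i + 1) % 20 == 0:
            logger.info("%s/%s: %d/%d runs done", outcome, config.scheme, i + 1, config.n_runs)
    table = pd.DataFrame(rows)
    table.attrs["outcome"] = outcome
    table.attrs["scheme"] = config.scheme
    return table


#: The study's headline across-run SMA slopes.  Each entry maps a
#: descriptive name to (experiment table, metric, sampled variant,
#: regression reference).  Reproductive-success comparisons for biased
#: samples are paired against the control sample; everything else is
#: judged against the full-population truth.
HEADLINE_SLOPES = {
    "fitness_raw_control": ("fitness", "raw", "control", "full"),
    "fitness_corrected_control": ("fitness", "corrected", "control", "full"),
    "fitness_corrected_increased": ("fitness", "corrected", "increased", "control"),
    "fitness_corrected_decreased": ("fitness", "corrected", "decreased", "control"),
    "rr_het_control": ("het", "rr", "control", "full"),
    "rr_het_increased": ("het", "rr", "increased", "full"),
    "rr_het_decreased": ("het", "rr", "decreased", "full"),
    "rr_allele_control": ("allele", "rr", "control", "full"),
    "rr_allele_increased": ("allele", "rr", "increased", "full"),
    "rr_allele_decreased": ("allele", "rr", "decreased", "full"),
    "allele_change_het_control": ("het", "dfreq", "control", "full"),
    "allele_change_allele_control": ("allele", "dfreq", "control", "full"),
}


def headline_slopes(tables: dict[str, pd.DataFrame]) -> dict:
    """The twelve headline SMA slope fits.

    ``tables`` maps ``"fitness"`` (penalty-perturbed), ``"het"`` and
    ``"allele"`` (prediction-weight-perturbed, per scheme) to experiment
    tables from :func:`run_experiment`.  Returns a dict of
    :class:`~capturebias.stats.SlopeTestResult` keyed as in
    :data:`HEADLINE_SLOPES`.
    """
    out = {}
    for name, (tab_key, metric, variant, ref) in HEADLINE_SLOPES.items():
        table = tables[tab_key]
        out[name] = sma_fit_and_test(
            table[f"{metric}_{ref}"].to_numpy(),
            table[f"{metric}_{variant}"].to_numpy(),
            test_slope=1.0,
        )
    return out


def _slope_row(table: pd.DataFrame, metric: str, variant: str,
               reference: str = "full") -> dict:
    res = sma_fit_and_test(
        table[f"{metric}_{reference}"].to_numpy(),
        table[f"{metric}_{variant}"].to_numpy(),
        test_slope=1.0,
    )
    return {
        "metric": metric, "variant": variant, "reference": reference,
        "test": "sma_slope_vs_1",
        "estimate": res.slope_hat, "stat": res.f_stat, "df": res.n - 2,
        "p_value": res.p_value, "ci_low": res.ci_low, "ci_high": res.ci_high,
        "n": res.n,
    }


def summarize(table: pd.DataFrame, outcome: str | None = None) -> pd.DataFrame:
    """The full statistical battery over an experiment table.

    For each sampled variant: the SMA slope test against 1 (sampled vs
    full metric; for the fitness outcome both raw and corrected), the
    Fligner variance test against the full values, and the residual vs
    |delta_p| diagnostic.  Plus Welch t-tests of the CJS detection
    difference, control against each biased variant.  Raw p-values are
    reported; the family-wise threshold for this battery is 0.005.
    """
    outcome = outcome or table.attrs.get("outcome")
    if outcome not in OUTCOMES:
        raise ValueError("summarize needs the outcome (table.attrs or argument)")
    metric = OUTCOME_METRIC[outcome]
    metrics = ("raw", "corrected") if outcome == "fitness" else (metric,)
    needed = [f"{m}_{v}" for m in metrics for v in ("full",) + SAMPLED_VARIANTS]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"experiment table lacks columns: {missing}")

    rows = []
    for m in metrics:
        for variant in SAMPLED_VARIANTS:
            # reproductive-success comparisons are paired within a run:
            # the biased samples are judged against the control sample
            # drawn from the same population, the control against truth
            ref = "control" if (outcome == "fitness" and variant != "control") else "full"
            rows.append(_slope_row(table, m, variant, reference=ref))
    for variant in SAMPLED_VARIANTS:
        x = table[f"{metric}_full"].to_numpy()
        y = table[f"{metric}_{variant}"].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        n_missing = int((~ok).sum())
        if n_missing:
            logger.info("%s %s: %d runs with undefined metric removed", outcome, variant, n_missing)
        stat, p = variance_test(y[ok], x[ok])
        rows.append({
            "metric": metric, "variant": variant, "test": "fligner_vs_full",
            "estimate": float("nan"), "stat": stat, "df": 1, "p_value": p,
            "ci_low": float("nan"), "ci_high": float("nan"), "n": int(ok.sum()),
        })
    if "delta_p_control" in table.columns:
        for variant in ("increased", "decreased"):
            t, df, p = delta_p_group_test(
                table["delta_p_control"].to_numpy(), table[f"delta_p_{variant}"].to_numpy()
            )
            rows.append({
                "metric": "delta_p", "variant": variant, "test": "welch_t_vs_control",
                "estimate": float("nan"), "stat": t, "df": df, "p_value": p,
                "ci_low": float("nan"), "ci_high": float("nan"), "n": len(table),
            })
        for variant in SAMPLED_VARIANTS:
            slope, p, r2 = residual_bias_diagnostic(
                table[f"{metric}_full"].to_numpy(),
                table[f"{metric}_{variant}"].to_numpy(),
                np.abs(table[f"delta_p_{variant}"].to_numpy()),
            )
            rows.append({
                "metric": metric, "variant": variant, "test": "residual_vs_abs_delta_p",
                "estimate": slope, "stat": float("nan"), "df": len(table) - 2,
                "p_value": p, "ci_low": float("nan"), "ci_high": float("nan"),
                "n": len(table), "adj_r2": r2,
            })
    out = pd.DataFrame(rows)
    out.insert(0, "outcome", outcome)
    return out
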