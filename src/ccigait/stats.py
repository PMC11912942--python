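"""Condition summaries, percent-change contrasts and the mixed-model ladder.

Trial-level CCI values (one per limb-trial, pairing and method) are
aggregated to condition cells — (pairing, method, population, environment,
speed) — as mean and sample SD over limb-trials. Descriptive contrasts are
computed from cell means: the environment contrast averages the three
speed-level cell means within each environment and reports the percent
change of Wet relative to Dry; speed contrasts average cell means over
whichever factors the question marginalizes (population, and environment
when both environments are pooled) and report the percent change between two
speed levels.

Inference uses a ladder of eight strictly nested linear mixed-effects
models with a random intercept per participant, fit by maximum likelihood
(ML rather than REML, so information criteria are comparable across fixed-
effect structures):

    1. CCI ~ 1
    2.     + Environment
    3.     + Population
    4.     + Speed
    5.     + Environment:Population
    6.     + Environment:Speed
    7.     + Population:Speed
    8.     + Environment:Population:Speed

Each addition is assessed by a likelihood-ratio chi-square test against the
previous model; the selected model is the most complex whose own addition
is significant at the chosen alpha. Limbs are treated as repeated
observations within participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import chi2

from .synthetic import ENVIRONMENTS, POPULATIONS, SPEEDS

SUMMARY_KEYS = ["pairing", "method", "population", "environment", "speed"]

LADDER_FORMULAS: tuple[str, ...] = (
    "trial_value ~ 1",
    "trial_value ~ environment",
    "trial_value ~ environment + population",
    "trial_value ~ environment + population + speed",
    "trial_value ~ environment + population + speed + environment:population",
    "trial_value ~ environment + population + speed + environment:population"
    " + environment:speed",
    "trial_value ~ environment + population + speed + environment:population"
    " + environment:speed + population:speed",
    "trial_value ~ environment + population + speed + environment:population"
    " + environment:speed + population:speed + environment:population:speed",
)


@dataclass(frozen=True)
class ContrastResult:
    """A descriptive percent change between two levels of one factor."""

    contrast_id: str
    factor: str
    averaging_scope: str
    baseline_level: str
    comparison_level: str
    baseline_mean: float
    comparison_mean: float

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.comparison_mean - self.baseline_mean) / self.baseline_mean


@dataclass(frozen=True)
class ModelLadderResult:
    """Fit table of the nested ladder and the selected model."""

    table: pd.DataFrame  # formula, k_fixed, loglik, aic, bic, p_value, converged
    selected_index: int  # 0-based row of the selected model
    alpha: float

    @property
    def selected_model(self) -> str:
        return str(self.table["formula"].iloc[self.selected_index])


def summarize_conditions(cci_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean, sample SD and limb-trial count of trial CCI values."""
    if len(cci_table) == 0:
        raise ValueError("empty CCI table")
    grouped = cci_table.groupby(SUMMARY_KEYS, observed=True)["trial_value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_limbs="count")
    out["sd"] = out["sd"].fillna(0.0)  # single-observation cells
    return out.reset_index()


def _cell_means(
    summary: pd.DataFrame, pairing: str, method: str, **levels: str
) -> pd.DataFrame:
    sel = (summary["pairing"] == pairing) & (summary["method"] == method)
    for col, val in levels.items():
        if val is not None:
            sel &= summary[col] == val
    return summary[sel]


def _require_cells(cells: pd.DataFrame, expected: int, what: str) -> None:
    if len(cells) != expected:
        raise ValueError(f"expected {expected} cells for {what}, found {len(cells)}")


def environment_contrast(
    summary: pd.DataFrame, pairing: str, method: str, population: str
) -> ContrastResult:
    """Percent change of Wet vs Dry, averaging cell means over the 3 speeds."""
    cells = _cell_means(summary, pairing, method, population=population)
    _require_cells(cells, 6, f"{pairing}/{method}/{population}")
    env_means = cells.groupby("environment", observed=True)["mean"].mean()
    return ContrastResult(
        contrast_id=f"{pairing}|{method}|{population}|Wet_vs_Dry",
        factor="environment",
        averaging_scope="speed",
        baseline_level="Dry",
        comparison_level="Wet",
        baseline_mean=float(env_means["Dry"]),
        comparison_mean=float(env_means["Wet"]),
    )


def speed_contrast(
    summary: pd.DataFrame,
    pairing: str,
    method: str,
    baseline_speed: str,
    comparison_speed: str,
    environment: str | None = None,
    population: str | None = None,
) -> ContrastResult:
    """Percent change between two speed levels.

    Cell means are averaged over populations when ``population`` is None and
    over environments when ``environment`` is None (the marginalization used
    by the narrative condition comparisons).
    """
    averaged = [f for f, v in (("population", population), ("environment", environment)) if v is None]
    n_per_speed = (2 if population is None else 1) * (2 if environment is None else 1)
    cells = _cell_means(
        summary, pairing, method, environment=environment, population=population
    )
    _require_cells(cells, 3 * n_per_speed, f"{pairing}/{method} speed cells")
    speed_means = cells.groupby("speed", observed=True)["mean"].mean()
    scope = "+".join(averaged) if averaged else "none"
    return ContrastResult(
        contrast_id=(
            f"{pairing}|{method}|env={environment or 'all'}|pop={population or 'all'}"
            f"|{comparison_speed}_vs_{baseline_speed}"
        ),
        factor="speed",
        averaging_scope=scope,
        baseline_level=baseline_speed,
        comparison_level=comparison_speed,
        baseline_mean=float(speed_means[baseline_speed]),
        comparison_mean=float(speed_means[comparison_speed]),
    )


def _prepare_model_frame(cci_table: pd.DataFrame) -> pd.DataFrame:
    df = cci_table.copy()
    df["environment"] = pd.Categorical(df["environment"], categories=ENVIRONMENTS)
    df["population"] = pd.Categorical(df["population"], categories=POPULATIONS)
    df["speed"] = pd.Categorical(df["speed"], categories=SPEEDS)
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants for a random intercept")
    for col, levels in (
        ("environment", ENVIRONMENTS),
        ("population", POPULATIONS),
        ("speed", SPEEDS),
    ):
        observed = set(df[col].dropna().unique())
        if observed != set(levels):
            raise ValueError(f"factor {col} missing levels: {set(levels) - observed}")
    return df


def _fit_mixed(model) -> tuple:
    """ML-fit a MixedLM, falling back across optimizers.

    Boundary fits (random-effect variance -> 0) can make some optimizers
    fail outright or report an infinite likelihood; the first optimizer
    producing a finite log-likelihood wins.
    """
    last_exc: Exception | None = None
    for method in ("powell", "lbfgs", "cg", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=False, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            continue
        if np.isfinite(result.llf):
            return result, bool(getattr(result, "converged", True))
    if last_exc is not None and "result" not in locals():
        raise last_exc
    return result, False


def fit_model_ladder(
    cci_table: pd.DataFrame, alpha: float = 0.05, depth: int = len(LADDER_FORMULAS)
) -> ModelLadderResult:
    """Fit the nested random-intercept ladder by ML and select a model.

    ``cci_table`` must hold one (pairing, method) stratum with columns
    ``trial_value``, ``participant_id``, ``environment``, ``population`` and
    ``speed``. ``depth`` truncates the ladder (useful for targeted
    likelihood-ratio tests such as the environment addition alone). Singular
    or non-converged fits are reported in the ``converged`` column, not
    raised.
    """
    df = _prepare_model_frame(cci_table)
    rows = []
    prev_llf, prev_kfe = None, None
    for formula in LADDER_FORMULAS[:depth]:
        model = smf.mixedlm(formula, df, groups=df["participant_id"])
        result, converged = _fit_mixed(model)
        # boundary estimate of the random-intercept variance = singular fit;
        # reported, not fatal
        singular = float(result.cov_re.iloc[0, 0]) < 1e-10
        llf = float(result.llf)
        k_fe = int(model.k_fe)
        if prev_llf is None:
            p_value = np.nan
        else:
            stat = max(0.0, 2.0 * (llf - prev_llf))
            p_value = float(chi2.sf(stat, df=k_fe - prev_kfe))
        rows.append(
            {
                "formula": formula,
                "k_fixed": k_fe,
                "loglik": llf,
                "aic": float(result.aic),
                "bic": float(result.bic),
                "p_value": p_value,
                "converged": converged,
                "singular": singular,
            }
        )
        prev_llf, prev_kfe = llf, k_fe
    table = pd.DataFrame(rows)
    significant = np.flatnonzero(table["p_value"].to_numpy() < alpha)
    selected = int(significant.max()) if significant.size else 0
    return ModelLadderResult(table=table, selected_index=selected, alpha=alpha)


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    """Tabulate contrast results (one row per contrast)."""
    return pd.DataFrame(
        {
            "contrast_id": [c.contrast_id for c in contrasts],
            "factor": [c.factor for c in contrasts],
            "averaging_scope": [c.averaging_scope for c in contrasts],
            "baseline_level": [c.baseline_level for c in contrasts],
            "comparison_level": [c.comparison_level for c in contrasts],
            "baseline_mean": [c.baseline_mean for c in contrasts],
            "comparison_mean": [c.comparison_mean for c in contrasts],
            "percent_change": [c.percent_change for c in contrasts],
        }
    )
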