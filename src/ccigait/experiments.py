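"""Validation experiments: parameter recovery, detection fidelity, calibration.

Self-contained simulation studies that exercise the whole chain and measure
how well it recovers what the generator injected. Problem sizes are desk
scale (a few participants, 8-20 strides per trial) — the package's own
choice of experiment size; the generator defaults themselves stay at study
scale.
"""

from __future__ import annotations

import numpy as np

from .pipeline import analyze_cohort, segment_trial
from .stats import environment_contrast, fit_model_ladder, summarize_conditions
from .synthetic import (
    ENVIRONMENTS,
    SPEEDS,
    SimulationConfig,
    TrialCondition,
    config_variant,
    simulate_cohort,
    simulate_trial,
)


def _sub_seeds(seed: int, tag: int, n: int) -> np.ndarray:
    """Deterministic 31-bit config seeds derived from one master seed."""
    return (
        np.random.SeedSequence([int(seed), int(tag)]).generate_state(n) & 0x7FFFFFFF
    ).astype(int)


def _small_cohort(seed: int, **overrides) -> SimulationConfig:
    base = dict(
        n_participants_td=3,
        n_participants_cp=2,
        limbs=("left",),
        strides_per_trial=8,
        seed=int(seed),
    )
    base.update(overrides)
    return config_variant(SimulationConfig(), **base)


def recovery_experiment(
    seed: int, env_amplitude_factor: float = 0.6
) -> dict[str, float]:
    """Full-chain recovery of an injected Wet amplitude attenuation.

    Simulates a cohort whose Wet trials are attenuated by
    ``env_amplitude_factor``, runs raw -> envelope -> segmentation ->
    Unnithan CCI -> environment contrast, and returns the recovered percent
    change per population. An attenuation of r should appear as a
    (r - 1) * 100 percent change.
    """
    config = _small_cohort(
        seed,
        n_participants_td=6,
        n_participants_cp=5,
        strides_per_trial=15,
        env_amplitude_factor=env_amplitude_factor,
    )
    table = analyze_cohort(
        simulate_cohort(config), methods=("unnithan",), pairings=("RF/ST",)
    )
    summary = summarize_conditions(table)
    return {
        pop: environment_contrast(summary, "RF/ST", "unnithan", pop).percent_change
        for pop in ("TD", "CP")
    }


def segmentation_experiment(seed: int, n_trials: int = 50) -> float:
    """Fraction of ground-truth initial contacts matched within ±30 ms.

    Trials are drawn across conditions at default simulator noise.
    """
    seeds = _sub_seeds(seed, 5, n_trials)
    matched = total = 0
    for i in range(n_trials):
        config = config_variant(
            SimulationConfig(), strides_per_trial=20, seed=int(seeds[i])
        )
        condition = TrialCondition(
            "P01",
            "left",
            "TD" if i % 2 else "CP",
            ENVIRONMENTS[i % 2],
            SPEEDS[i % 3],
        )
        trial = simulate_trial(config, condition, np.random.default_rng(int(seeds[i])))
        detected = segment_trial(trial).initial_contact_times_s
        for ic in trial.true_initial_contacts_s:
            total += 1
            matched += bool(np.min(np.abs(detected - ic)) <= 0.030)
    return matched / total


def _environment_pvalue(config: SimulationConfig) -> float:
    """LRT p-value of adding Environment to the intercept-only model."""
    table = analyze_cohort(
        simulate_cohort(config), methods=("unnithan",), pairings=("RF/ST",)
    )
    result = fit_model_ladder(table, depth=2)
    return float(result.table["p_value"].iloc[1])


def environment_type1_experiment(seed: int, n_replicates: int = 200) -> float:
    """Type-I error of the Environment addition on effect-free cohorts.

    The null cohorts carry no environment, speed or population effects
    (all amplitude factors 1, equal co-activation baselines); participant
    offsets remain, so the random intercept is live. Returns the fraction
    of replicates with p < 0.05.
    """
    seeds = _sub_seeds(seed, 11, n_replicates)
    null_kwargs = dict(
        env_amplitude_factor=1.0,
        speed_amplitude_factors={"Slow": 1.0, "Normal": 1.0, "Fast": 1.0},
        coactivation_baseline={"TD": 0.05, "CP": 0.05},
    )
    rejections = sum(
        _environment_pvalue(_small_cohort(s, **null_kwargs)) < 0.05 for s in seeds
    )
    return rejections / n_replicates


def environment_power_experiment(
    seed: int, n_replicates: int = 60, env_amplitude_factor: float = 0.6
) -> float:
    """Power of the Environment addition under a large injected Wet effect."""
    seeds = _sub_seeds(seed, 13, n_replicates)
    rejections = sum(
        _environment_pvalue(
            _small_cohort(s, env_amplitude_factor=env_amplitude_factor)
        )
        < 0.05
        for s in seeds
    )
    return rejections / n_replicates


def quadrature_agreement_experiment() -> float:
    """Worst relative disagreement between the 101-point trapezoid and a
    100,000-point Riemann sum of the common-area integral on default
    simulator waveforms (all pairings x conditions)."""
    from .cci import cci_unnithan
    from .segmentation import PHASE_GRID
    from .synthetic import make_activation_profile

    config = SimulationConfig()
    fine = (np.arange(100_000) + 0.5) / 100_000
    worst = 0.0
    for pop in ("TD", "CP"):
        for env in ENVIRONMENTS:
            for speed in SPEEDS:
                condition = TrialCondition("P01", "left", pop, env, speed)
                for m1, m2 in (("RF", "ST"), ("TA", "MG")):
                    p1 = make_activation_profile(m1, config, condition)
                    p2 = make_activation_profile(m2, config, condition)
                    coarse = cci_unnithan(p1(PHASE_GRID / 100), p2(PHASE_GRID / 100))
                    oracle = float(np.minimum(p1(fine), p2(fine)).mean() * 100.0)
                    worst = max(worst, abs(coarse - oracle) / oracle)
    return worst
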