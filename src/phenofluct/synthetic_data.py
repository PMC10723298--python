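"""Synthetic clone-fluctuation, replicate and reversion datasets.

The generators emulate the fluctuation experiment the analysis modules
expect: 60 single-cell clones expanded ~20 generations in attached
culture, assayed for 24 h suspension survival at passages 1, 3 and 6,
alongside 11 bulk-population replicates as a noise floor and a reversion
time course of an adapted all-resistant population. Three generative
models are available:

``two_state``
    Clone survival variation comes only from the two-state switching
    composition (plus plating/counting noise) — the null the fluctuation
    analysis rejects.
``heterogeneous_gamma``
    Each clone carries a heritable effective suspension growth rate
    gamma_c; the resistant fraction is fixed at its steady-state value.
``combined``
    Both sources together (the default study condition).

Every dataset is fully reproducible from its seed, and a design manifest
captures all parameters alongside the CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .fluctuation_stats import CloneSurvivalTable, make_clone_table
from .growth_metrics import ReversionCurve
from .heterogeneity_inference import GrowthRateDistribution
from .switching_model import (
    AssayParams,
    ModelError,
    SwitchingParams,
    UndefinedSteadyStateError,
    advance_compositions,
    apply_counting_noise,
    expected_survival_fraction,
    plate_resistant,
    rates_from_fraction_and_memory,
    simulate_clone_compositions,
    survival_components,
)

__all__ = [
    "ExperimentDesign",
    "generate_clone_experiment",
    "generate_population_replicates",
    "generate_reversion_experiment",
    "design_to_dict",
]

Model = Literal["two_state", "heterogeneous_gamma", "combined"]


def _default_switching() -> SwitchingParams:
    # steady-state resistant fraction 0.76, resistant-state memory 10.5 divisions
    return rates_from_fraction_and_memory(0.76, 10.5)


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic clone-fluctuation experiment.

    Defaults reproduce the study conditions: 60 clones, 20 generations of
    initial expansion, assays at passages 1/3/6 with ~3.3 generations of
    attached growth per passage (10-fold expansion per passage), counting
    noise from 500-cell counts, resistant doubling time 100 h in a 24 h
    assay.

    ``redraw_gamma_each_passage`` controls whether a clone's effective
    growth rate persists between assay passages (False) or is drawn anew
    at each assay (True, the default — the near-zero observed
    passage-to-passage correlation argues against long-lived clone
    states).
    """

    n_clones: int = 60
    assay_passages: tuple[int, ...] = (1, 3, 6)
    expansion_generations_initial: int = 20
    generations_per_passage: float = 3.3
    model: Model = "combined"
    switching: SwitchingParams = field(default_factory=_default_switching)
    gamma_dist: GrowthRateDistribution = field(
        default_factory=GrowthRateDistribution
    )
    assay: AssayParams = field(default_factory=AssayParams)
    redraw_gamma_each_passage: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ModelError(f"n_clones must be >= 1; got {self.n_clones!r}")
        passages = tuple(self.assay_passages)
        if len(passages) == 0 or any(
            b <= a for a, b in zip(passages, passages[1:])
        ):
            raise ModelError(
                f"assay_passages must be strictly increasing; got {passages!r}"
            )
        if self.model not in ("two_state", "heterogeneous_gamma", "combined"):
            raise ModelError(f"unknown model {self.model!r}")
        if self.expansion_generations_initial < 0:
            raise ModelError("expansion_generations_initial must be >= 0")
        if self.generations_per_passage <= 0:
            raise ModelError("generations_per_passage must be > 0")


def _draw_calibrated_gamma(
    dist: GrowthRateDistribution, T: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Clone-level growth rates whose survival multiplier is mean-calibrated.

    For the normal family the draw mean is shifted down by T*sigma^2/2 so
    that E[exp(gamma_c*T)] equals exp(mean_gamma*T): the synthetic mean
    survival then matches the deterministic survival relation while the
    survival CV sqrt(exp((T*sigma)^2)-1) is unchanged. The lognormal
    family is drawn as-is (no elementary calibration exists).
    """
    if dist.family == "normal":
        sigma = dist.cv_gamma * dist.mean_gamma
        mu = dist.mean_gamma - T * sigma * sigma / 2.0
        return mu + sigma * rng.standard_normal(n)
    return dist.draw(n, rng)


def generate_clone_experiment(design: ExperimentDesign) -> CloneSurvivalTable:
    """Simulate the clone-fluctuation experiment defined by ``design``.

    Each clone is expanded from a single founder (steady-state draw),
    assayed with plating and counting noise at each assay passage, and
    grown ``round(generations_per_passage * Δpassage)`` further
    generations between assays. Live counts are rounded to whole cells;
    survival fractions are live/plated.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_clones
    passages = tuple(design.assay_passages)
    assay = design.assay
    plated = assay.plated_count
    track_composition = design.model in ("two_state", "combined")
    track_gamma = design.model in ("heterogeneous_gamma", "combined")

    if track_composition:
        _, n_s, n_r = simulate_clone_compositions(
            design.switching,
            design.expansion_generations_initial,
            n,
            founder="steady_state",
            seed=rng,
        )
    else:
        f_star = design.switching.steady_state_f

    gamma: np.ndarray | float = assay.gamma
    if track_gamma:
        gamma = _draw_calibrated_gamma(design.gamma_dist, assay.T_suspension, n, rng)

    frames = []
    clone_ids = np.array([f"clone_{i:03d}" for i in range(n)])
    prev_passage = passages[0]
    for j, passage in enumerate(passages):
        if j > 0:
            extra = round(design.generations_per_passage * (passage - prev_passage))
            if track_composition:
                n_s, n_r = advance_compositions(
                    design.switching, n_s, n_r, extra, rng
                )
            if track_gamma and design.redraw_gamma_each_passage:
                gamma = _draw_calibrated_gamma(
                    design.gamma_dist, assay.T_suspension, n, rng
                )
        if track_composition:
            k = plate_resistant(n_r, n_s, plated, rng)
        else:
            k = rng.binomial(plated, f_star, size=n)
        f_plated = k / plated
        live, dead = survival_components(f_plated, assay, gamma=gamma)
        live_obs = apply_counting_noise(live, dead, assay.count_depth, rng)
        live_count = np.rint(live_obs * plated).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "clone_id": clone_ids,
                    "passage": passage,
                    "plated_count": plated,
                    "live_count": live_count,
                }
            )
        )
        prev_passage = passage
    return make_clone_table(pd.concat(frames, ignore_index=True))


def generate_population_replicates(
    n: int = 11,
    base_fraction: float = 0.9,
    noise_cv: float = 0.1,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Bulk-population replicate survival fractions (the noise floor).

    Multiplicative Gaussian noise of the stated CV around
    ``base_fraction``, truncated at zero.
    """
    if n < 1:
        raise ModelError(f"n must be >= 1; got {n!r}")
    if noise_cv < 0:
        raise ModelError(f"noise_cv must be >= 0; got {noise_cv!r}")
    rng = np.random.default_rng(seed)
    values = base_fraction * (1.0 + noise_cv * rng.standard_normal(n))
    return np.clip(values, 0.0, None)


def generate_reversion_experiment(
    switching: SwitchingParams,
    n_passages: int = 10,
    generations_per_passage: float = 3.3,
    assay: AssayParams | None = None,
    seed: Optional[int] = None,
) -> ReversionCurve:
    """Reversion time course of an adapted all-resistant population.

    Deterministic mean-field propagation of the resistant fraction
    (demographic noise is negligible at the >=1e6-cell population sizes
    this emulates): starting from r=1, deviations from the steady state
    decay per generation by ``lambda = 1 - p_sr - p_rs``, and at each
    passage the population is assayed via the deterministic survival
    relation. ``seed`` is accepted for interface symmetry and unused.
    """
    del seed  # mean-field: deterministic
    if n_passages < 0:
        raise ModelError(f"n_passages must be >= 0; got {n_passages!r}")
    if generations_per_passage <= 0:
        raise ModelError("generations_per_passage must be > 0")
    if assay is None:
        assay = AssayParams()
    lam = switching.relaxation_factor
    if switching.p_sr + switching.p_rs == 0:
        raise UndefinedSteadyStateError(
            "both switching rates are zero: no baseline to revert to"
        )
    f_star = switching.steady_state_f
    gens, survivals = [], []
    for k in range(n_passages + 1):
        g = k * generations_per_passage
        if lam >= 0:
            r = f_star + (1.0 - f_star) * lam**g
        else:
            # oscillatory regime: step whole generations
            r = f_star + (1.0 - f_star) * lam ** round(g)
        gens.append(g)
        survivals.append(
            expected_survival_fraction(
                r, assay.T_suspension, assay.T_d_resistant, assay.escape_fraction
            )
        )
    baseline = expected_survival_fraction(
        f_star, assay.T_suspension, assay.T_d_resistant, assay.escape_fraction
    )
    return ReversionCurve(
        cumulative_generations=tuple(gens),
        survival_fractions=tuple(survivals),
        baseline_sensitive_fraction=baseline,
    )


def design_to_dict(design: ExperimentDesign) -> dict:
    """JSON-ready manifest of an experiment design (all parameters + seed)."""
    return {
        "n_clones": design.n_clones,
        "assay_passages": list(design.assay_passages),
        "expansion_generations_initial": design.expansion_generations_initial,
        "generations_per_passage": design.generations_per_passage,
        "model": design.model,
        "switching": {
            "p_sr": design.switching.p_sr,
            "p_rs": design.switching.p_rs,
            "memory_generations": design.switching.memory_generations,
            "steady_state_f": design.switching.steady_state_f,
        },
        "gamma_dist": {
            "family": design.gamma_dist.family,
            "mean_gamma": design.gamma_dist.mean_gamma,
            "cv_gamma": design.gamma_dist.cv_gamma,
        },
        "assay": {
            "T_suspension": design.assay.T_suspension,
            "T_d_resistant": design.assay.T_d_resistant,
            "escape_fraction": design.assay.escape_fraction,
            "count_depth": design.assay.count_depth,
            "plated_count": design.assay.plated_count,
        },
        "redraw_gamma_each_passage": design.redraw_gamma_each_passage,
        "seed": design.seed,
    }
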