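"""Model-predicted clone-to-clone fluctuations and growth-rate-CV inference.

Two competing explanations of interclonal variability in suspension
survival are quantified here.

1. Two-state reversible switching. Each clone is expanded from a single
   founder; per-division switching decorrelates the clone's resistant
   fraction from the founder state at rate ``(1 - p_sr - p_rs)`` per
   generation, and averaging over the exponentially growing number of
   cells suppresses demographic noise. The interclonal CV of survival
   predicted by the fully specified generative model is computed by
   Monte Carlo (:func:`predicted_cv_two_state`) and, for small clone
   expansions, exactly by dynamic-programming enumeration over all
   composition outcomes (:func:`exact_two_state_survival_cv`) — the
   independent oracle for the simulator.

2. Heritable growth-rate heterogeneity. Each clone carries its own
   effective suspension growth rate ``gamma_c`` drawn from a normal or
   lognormal distribution; survival is ``f * exp(gamma_c * T)`` with f
   fixed. For the normal family the survival CV has the closed form
   ``sqrt(exp((T*sigma)^2) - 1)`` with ``sigma = cv_gamma * mean_gamma``,
   which is strictly increasing in ``cv_gamma`` and hence invertible:
   given an observed interclonal CV, the required growth-rate CV is
   ``sqrt(ln(1 + CV^2)) / (T * mean_gamma)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np
from scipy import stats

from .switching_model import (
    AssayParams,
    ModelError,
    SwitchingParams,
    simulate_clone_compositions,
    steady_state_fraction,
    survival_components,
)

__all__ = [
    "GrowthRateDistribution",
    "CVPrediction",
    "InferenceResult",
    "BracketingError",
    "predicted_cv_two_state",
    "exact_composition_distribution",
    "exact_two_state_survival_cv",
    "fold_difference",
    "cv_survival_given_cv_gamma",
    "infer_growth_rate_cv",
]

Family = Literal["normal", "lognormal"]
Founder = Literal["S", "R", "steady_state"]


class BracketingError(RuntimeError):
    """Bisection could not bracket the target CV."""


@dataclass(frozen=True)
class GrowthRateDistribution:
    """Clone-level distribution of the effective suspension growth rate.

    ``cv_gamma`` is the dimensionless CV of gamma across clones; with the
    normal family a large CV places substantial mass at negative rates
    (net cell death in suspension), which is biologically meaningful.
    """

    family: Family = "normal"
    mean_gamma: float = math.log(2.0) / 100.0
    cv_gamma: float = 1.45

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ModelError(f"unknown family {self.family!r}")
        if self.mean_gamma <= 0:
            raise ModelError(f"mean_gamma must be > 0; got {self.mean_gamma!r}")
        if self.cv_gamma < 0:
            raise ModelError(f"cv_gamma must be >= 0; got {self.cv_gamma!r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n clone-level growth rates."""
        return _draw_gamma(self.family, self.mean_gamma, self.cv_gamma,
                           rng.standard_normal(n))


def _draw_gamma(family: str, mean: float, cv: float, z: np.ndarray) -> np.ndarray:
    """Map standard-normal draws to growth rates (common-random-number core)."""
    if cv == 0:
        return np.full_like(z, mean)
    if family == "normal":
        return mean + cv * mean * z
    # lognormal parameterised by its mean and CV
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - s2 / 2.0
    return np.exp(mu + math.sqrt(s2) * z)


@dataclass(frozen=True)
class CVPrediction:
    """Monte-Carlo model prediction of the interclonal survival CV."""

    model_label: str
    predicted_cv: float
    n_clones_simulated: int
    mc_standard_error: float
    seed: Optional[int]
    parameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class InferenceResult:
    """Growth-rate CV inferred from a target interclonal survival CV."""

    cv_gamma_hat: float
    target_cv: float
    achieved_cv: float
    method: Literal["closed_form", "monte_carlo_bisection"]
    family: Family
    iterations: int


# ---------------------------------------------------------------------------
# Two-state model prediction
# ---------------------------------------------------------------------------


def _jackknife_cv_se(x: np.ndarray) -> float:
    """Leave-one-out jackknife standard error of the sample CV (closed form
    in the running sums, O(n))."""
    n = x.size
    if n < 3:
        return math.nan
    s, q = x.sum(), np.square(x).sum()
    mean_i = (s - x) / (n - 1)
    # unbiased leave-one-out variance from the complementary sums
    var_i = (q - x * x - (n - 1) * mean_i * mean_i) / (n - 2)
    var_i = np.clip(var_i, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_i = np.sqrt(var_i) / mean_i
    cv_bar = cv_i.mean()
    return float(math.sqrt((n - 1) / n * np.square(cv_i - cv_bar).sum()))


def predicted_cv_two_state(
    params: SwitchingParams,
    expansion_generations: int,
    assay: AssayParams | None = None,
    n_clones: int = 10_000,
    seed: Union[int, np.random.Generator, None] = None,
    founder: Founder = "steady_state",
) -> CVPrediction:
    """Interclonal survival CV predicted by the two-state switching model.

    Simulates ``n_clones`` single-cell-founded clones through
    ``expansion_generations`` generations of attached growth, scores each
    clone's survival deterministically from its full composition
    (``survival = expected_survival_fraction(f_clone)``; no plating
    subsampling, no counting noise — model-intrinsic fluctuation only) and
    returns the CV across clones with a jackknife Monte-Carlo standard
    error.
    """
    if assay is None:
        assay = AssayParams(count_depth=None)
    _, n_s, n_r = simulate_clone_compositions(
        params, expansion_generations, n_clones, founder=founder, seed=seed
    )
    f_clone = n_r / (n_s + n_r)
    live, _ = survival_components(f_clone, assay)
    mean = live.mean()
    if mean <= 0:
        raise ModelError("mean predicted survival is zero: CV undefined")
    cv = float(live.std(ddof=1) / mean)
    return CVPrediction(
        model_label="two_state",
        predicted_cv=cv,
        n_clones_simulated=int(n_clones),
        mc_standard_error=_jackknife_cv_se(live),
        seed=seed if isinstance(seed, int) else None,
        parameters={
            "p_sr": params.p_sr,
            "p_rs": params.p_rs,
            "expansion_generations": int(expansion_generations),
            "T_suspension": assay.T_suspension,
            "T_d_resistant": assay.T_d_resistant,
            "escape_fraction": assay.escape_fraction,
            "founder": founder,
        },
    )


def exact_composition_distribution(
    params: SwitchingParams,
    generations: int,
    founder: Founder = "steady_state",
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the clone resistant count after ``generations``
    generations, by dynamic programming over all switching outcomes.

    The state after g generations is the resistant count r among
    ``N = 2**g`` cells; the transition from r (with s = N/2 - r parents...)
    convolves ``Bin(2r, 1-p_rs)`` with ``Bin(2s, p_sr)``. Intended for
    small g (cost grows as 4**g); serves as the brute-force oracle for the
    Monte-Carlo simulator.

    Returns
    -------
    (fractions, probabilities)
        ``fractions[k] = k / 2**generations`` for k = 0..2**generations.
    """
    if generations < 0:
        raise ModelError("generations must be >= 0")
    if generations > 10:
        raise ModelError(
            "exact enumeration is exponential in generations; use <= 10"
        )

    def evolve(dist0: np.ndarray) -> np.ndarray:
        dist = dist0
        total = dist.size - 1  # current population size
        for _ in range(int(generations)):
            new_total = 2 * total
            new = np.zeros(new_total + 1)
            support = np.arange(new_total + 1)
            for r, pr in enumerate(dist):
                if pr == 0.0:
                    continue
                s = total - r
                pmf_r = stats.binom.pmf(np.arange(2 * r + 1), 2 * r, 1.0 - params.p_rs)
                pmf_s = stats.binom.pmf(np.arange(2 * s + 1), 2 * s, params.p_sr)
                conv = np.convolve(pmf_r, pmf_s)
                new[: conv.size] += pr * conv
            dist, total = new, new_total
        return dist

    if founder == "S":
        dist = evolve(np.array([1.0, 0.0]))
    elif founder == "R":
        dist = evolve(np.array([0.0, 1.0]))
    elif founder == "steady_state":
        f = steady_state_fraction(params.p_sr, params.p_rs)
        dist = (1.0 - f) * evolve(np.array([1.0, 0.0])) + f * evolve(
            np.array([0.0, 1.0])
        )
    else:
        raise ModelError(f"unknown founder state {founder!r}")
    n_final = dist.size - 1
    return np.arange(n_final + 1) / n_final, dist


def exact_two_state_survival_cv(
    params: SwitchingParams,
    generations: int,
    assay: AssayParams | None = None,
    founder: Founder = "steady_state",
) -> float:
    """Exact interclonal survival CV for small clone expansions, from the
    enumerated composition distribution (noise off)."""
    if assay is None:
        assay = AssayParams(count_depth=None)
    fractions, probs = exact_composition_distribution(params, generations, founder)
    live, _ = survival_components(fractions, assay)
    mean = float(np.dot(probs, live))
    if mean <= 0:
        raise ModelError("mean survival is zero: CV undefined")
    var = float(np.dot(probs, np.square(live - mean)))
    return math.sqrt(max(var, 0.0)) / mean


def fold_difference(observed_cv: float, predicted_cv: float) -> float:
    """Observed-over-predicted CV ratio (the paper-style "N-fold less")."""
    if predicted_cv <= 0:
        raise ZeroDivisionError(
            "predicted CV is zero: the fold difference is effectively "
            "infinite; report it as such rather than as a number"
        )
    return observed_cv / predicted_cv


# ---------------------------------------------------------------------------
# Growth-rate heterogeneity
# ---------------------------------------------------------------------------


def cv_survival_given_cv_gamma(
    dist: GrowthRateDistribution,
    assay: AssayParams | None = None,
    f: float = 0.76,
    method: Literal["closed_form", "monte_carlo"] = "closed_form",
    n_draws: int = 100_000,
    seed: Optional[int] = None,
) -> float:
    """Interclonal survival CV implied by clone-level growth-rate spread.

    Clone survival is ``s_c = f * exp(gamma_c * T)`` with fixed f, so the
    CV of s does not depend on f. For the normal family the closed form is
    ``sqrt(exp((T*sigma)^2) - 1)``, sigma = cv_gamma * mean_gamma; the
    lognormal family has no elementary closed form and requires
    ``method="monte_carlo"``.
    """
    if assay is None:
        assay = AssayParams(count_depth=None)
    if dist.cv_gamma == 0:
        return 0.0
    T = assay.T_suspension
    if method == "closed_form":
        if dist.family != "normal":
            raise ModelError(
                f"closed form is available for the normal family only; "
                f"got {dist.family!r} (use method='monte_carlo')"
            )
        sigma = dist.cv_gamma * dist.mean_gamma
        return math.sqrt(math.expm1((T * sigma) ** 2))
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        s = f * np.exp(dist.draw(n_draws, rng) * T)
        return float(s.std(ddof=1) / s.mean())
    raise ModelError(f"unknown method {method!r}")


def infer_growth_rate_cv(
    target_cv: float,
    family: Family = "normal",
    assay: AssayParams | None = None,
    f: float = 0.76,
    method: Literal["closed_form", "monte_carlo_bisection"] = "closed_form",
    tol: float = 1e-3,
    n_draws: int = 100_000,
    seed: Optional[int] = None,
    max_iter: int = 200,
) -> InferenceResult:
    """Growth-rate CV required to reproduce an observed interclonal CV.

    ``closed_form`` (normal family only) inverts the forward map exactly:
    ``cv_gamma = sqrt(ln(1 + target_cv^2)) / (T * mean_gamma)``.
    ``monte_carlo_bisection`` bisects the Monte-Carlo forward map using
    common random numbers across iterations until
    ``|achieved - target| <= tol``.
    """
    if target_cv < 0:
        raise ModelError(f"target CV must be >= 0; got {target_cv!r}")
    if assay is None:
        assay = AssayParams(count_depth=None)
    T = assay.T_suspension
    mean_gamma = assay.gamma
    if target_cv == 0:
        return InferenceResult(0.0, 0.0, 0.0, method, family, 0)

    if method == "closed_form":
        if family != "normal":
            raise ModelError(
                "closed-form inversion is available for the normal family only"
            )
        cv_gamma = math.sqrt(math.log1p(target_cv**2)) / (T * mean_gamma)
        achieved = cv_survival_given_cv_gamma(
            GrowthRateDistribution("normal", mean_gamma, cv_gamma), assay, f
        )
        return InferenceResult(cv_gamma, target_cv, achieved, method, family, 0)

    if method != "monte_carlo_bisection":
        raise ModelError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_draws)  # common random numbers

    def forward(cv: float) -> float:
        s = f * np.exp(_draw_gamma(family, mean_gamma, cv, z) * T)
        return float(s.std(ddof=1) / s.mean())

    lo, f_lo = 0.0, 0.0
    hi = 1.0
    iterations = 0
    while forward(hi) < target_cv:
        hi *= 2.0
        iterations += 1
        if hi > 1e6:
            raise BracketingError(
                f"could not bracket target CV {target_cv} with cv_gamma up to "
                f"{hi:g} ({family} family, T={T} h, mean_gamma={mean_gamma:g}/h)"
            )
    achieved = forward(hi)
    mid = hi
    while iterations < max_iter:
        mid = 0.5 * (lo + hi)
        achieved = forward(mid)
        iterations += 1
        if abs(achieved - target_cv) <= tol:
            break
        if achieved < target_cv:
            lo = mid
        else:
            hi = mid
    else:
        raise BracketingError(
            f"bisection did not converge to |achieved-target| <= {tol} in "
            f"{max_iter} iterations (last achieved {achieved:.5f})"
        )
    return InferenceResult(mid, target_cv, achieved, method, family, iterations)
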