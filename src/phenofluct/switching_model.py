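"""Two-state reversible phenotype-switching model of anoikis resistance.

Cells occupy one of two heritable phenotypic states: anoikis-sensitive
(S) or anoikis-resistant (R). During attached growth both states divide
at the same rate (fitness-neutral switching); at every division each
daughter cell independently switches state, S→R with probability
``p_sr`` and R→S with probability ``p_rs``.  Residence in the resistant
state is therefore geometric with mean ``1/p_rs`` divisions — the
"transient heritability" or memory of the state — and the long-run
resistant fraction under unperturbed growth is

    f = p_sr / (p_sr + p_rs).

In a suspension (low-attachment) survival assay of duration ``T``,
resistant cells proliferate exponentially at rate ``gamma = ln2 / T_d``
(``T_d`` = resistant doubling time in suspension) while sensitive cells
die, save for an optional escape fraction that survives without growing.
The expected surviving fraction relative to the number plated is

    S = f * exp(gamma * T) + escape * (1 - f)

which may exceed 1 when resistant growth outweighs sensitive death.

Clone expansions are simulated as a synchronous Galton–Watson branching
process with per-division switching, implemented by binomial thinning on
state counts so that cost is linear in the number of generations rather
than in the number of cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np

__all__ = [
    "LN2",
    "ModelError",
    "UndefinedSteadyStateError",
    "DegenerateModelError",
    "InfeasibleParameterError",
    "SamplingError",
    "SwitchingParams",
    "AssayParams",
    "CloneComposition",
    "AssayOutcome",
    "steady_state_fraction",
    "growth_rate_from_doubling_time",
    "resistant_fraction_from_survival",
    "expected_survival_fraction",
    "rates_from_fraction_and_memory",
    "rates_from_fraction_and_relaxation",
    "simulate_clone_composition",
    "simulate_clone_compositions",
    "advance_compositions",
    "plate_resistant",
    "simulate_suspension_assay",
]

LN2 = math.log(2.0)

FounderState = Literal["S", "R", "steady_state"]


class ModelError(ValueError):
    """Base class for switching-model parameter and sampling errors."""


class UndefinedSteadyStateError(ModelError):
    """Both switching rates are zero: no unique steady state exists."""


class DegenerateModelError(ModelError):
    """A requested model has a degenerate (absorbing) state structure."""


class InfeasibleParameterError(ModelError):
    """The requested parameter combination implies an impossible value."""


class SamplingError(ModelError):
    """A sampling request exceeds the available population."""


def _as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwitchingParams:
    """Per-division state-transition probabilities.

    Attributes
    ----------
    p_sr : float
        Probability per division that a sensitive daughter becomes resistant.
    p_rs : float
        Probability per division that a resistant daughter becomes sensitive.
    """

    p_sr: float
    p_rs: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_sr <= 1.0):
            raise InfeasibleParameterError(
                f"p_sr must lie in [0, 1]; got {self.p_sr!r}"
            )
        if not (0.0 <= self.p_rs <= 1.0):
            raise InfeasibleParameterError(
                f"p_rs must lie in [0, 1]; got {self.p_rs!r}"
            )

    @property
    def memory_generations(self) -> float:
        """Mean residence time of the resistant state, 1/p_rs divisions."""
        if self.p_rs == 0.0:
            return math.inf
        return 1.0 / self.p_rs

    @property
    def steady_state_f(self) -> float:
        """Long-run resistant fraction p_sr / (p_sr + p_rs)."""
        return steady_state_fraction(self.p_sr, self.p_rs)

    @property
    def relaxation_factor(self) -> float:
        """Per-generation decay factor 1 - p_sr - p_rs of deviations from
        the steady-state resistant fraction."""
        return 1.0 - self.p_sr - self.p_rs


@dataclass(frozen=True)
class AssayParams:
    """Suspension-survival assay configuration.

    Attributes
    ----------
    T_suspension : float
        Assay duration in hours (24 h by default).
    T_d_resistant : float
        Doubling time of resistant cells in suspension, hours.
    escape_fraction : float
        Fraction of sensitive cells still alive at assay end without growing.
    count_depth : int or None
        Cells counted per viability measurement; ``None`` disables counting
        noise. Default 500, a typical hemocytometer-scale count.
    plated_count : int
        Cells plated per assay well.
    """

    T_suspension: float = 24.0
    T_d_resistant: float = 100.0
    escape_fraction: float = 0.0
    count_depth: Optional[int] = 500
    plated_count: int = 1000

    def __post_init__(self) -> None:
        if self.T_suspension <= 0:
            raise ModelError(f"T_suspension must be > 0; got {self.T_suspension!r}")
        if self.T_d_resistant <= 0:
            raise ModelError(f"T_d_resistant must be > 0; got {self.T_d_resistant!r}")
        if not (0.0 <= self.escape_fraction <= 1.0):
            raise ModelError(
                f"escape_fraction must lie in [0, 1]; got {self.escape_fraction!r}"
            )
        if self.count_depth is not None and self.count_depth < 1:
            raise ModelError(f"count_depth must be >= 1; got {self.count_depth!r}")
        if self.plated_count < 1:
            raise ModelError(f"plated_count must be >= 1; got {self.plated_count!r}")

    @property
    def gamma(self) -> float:
        """Effective suspension growth rate of resistant cells, ln2/T_d per hour."""
        return growth_rate_from_doubling_time(self.T_d_resistant)


@dataclass(frozen=True)
class CloneComposition:
    """State composition of a clonally expanded population."""

    n_sensitive: int
    n_resistant: int
    generations_expanded: int
    founder_state: Literal["S", "R"]

    def __post_init__(self) -> None:
        if self.n_sensitive < 0 or self.n_resistant < 0:
            raise ModelError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_sensitive + self.n_resistant

    @property
    def resistant_fraction(self) -> float:
        if self.total == 0:
            return math.nan
        return self.n_resistant / self.total


@dataclass(frozen=True)
class AssayOutcome:
    """Result of one suspension-survival assay.

    ``live_at_end`` may exceed ``plated`` (net growth of resistant cells);
    ``survival_fraction`` = live_at_end / plated accordingly may exceed 1.
    """

    plated: int
    live_at_end: float
    survival_fraction: float
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# Analytic relations
# ---------------------------------------------------------------------------


def steady_state_fraction(p_sr: float, p_rs: float) -> float:
    """Long-run resistant fraction under fitness-neutral reversible switching.

    Parameters must satisfy ``p_sr + p_rs > 0``; with both rates zero the
    chain has two absorbing states and no unique stationary fraction.
    """
    if p_sr < 0 or p_rs < 0:
        raise InfeasibleParameterError("switching probabilities must be >= 0")
    if p_sr + p_rs == 0:
        raise UndefinedSteadyStateError(
            "both switching rates are zero: steady-state fraction undefined"
        )
    return p_sr / (p_sr + p_rs)


def growth_rate_from_doubling_time(T_d: float) -> float:
    """Exponential growth rate gamma = ln2 / T_d (per hour)."""
    if T_d <= 0:
        raise ModelError(f"doubling time must be > 0; got {T_d!r}")
    return LN2 / T_d


def expected_survival_fraction(
    f: float,
    T: float = 24.0,
    T_d: float = 100.0,
    escape_fraction: float = 0.0,
) -> float:
    """Expected 24 h suspension surviving fraction for resistant fraction ``f``.

    Returns ``f * exp(gamma*T) + escape_fraction * (1 - f)`` with
    ``gamma = ln2/T_d``. The exact inverse of
    :func:`resistant_fraction_from_survival`.
    """
    f = float(f)
    if not (0.0 <= f <= 1.0):
        raise ModelError(f"resistant fraction must lie in [0, 1]; got {f!r}")
    if T <= 0:
        raise ModelError(f"assay duration must be > 0; got {T!r}")
    gamma = growth_rate_from_doubling_time(T_d)
    return f * math.exp(gamma * T) + escape_fraction * (1.0 - f)


def resistant_fraction_from_survival(
    mean_survival: float,
    T: float = 24.0,
    T_d: float = 100.0,
    escape_fraction: float = 0.0,
) -> float:
    """Resistant fraction implied by a mean suspension surviving fraction.

    Solves ``f * exp(gamma*T) + escape * (1 - f) = mean_survival`` for f.
    With ``escape_fraction = 0`` this reduces to ``mean_survival * exp(-gamma*T)``.

    Raises
    ------
    InfeasibleParameterError
        If the implied f falls outside [0, 1].
    """
    if mean_survival < 0:
        raise ModelError(f"mean survival must be >= 0; got {mean_survival!r}")
    if T <= 0:
        raise ModelError(f"assay duration must be > 0; got {T!r}")
    gamma = growth_rate_from_doubling_time(T_d)
    growth = math.exp(gamma * T)
    denom = growth - escape_fraction
    if denom <= 0:
        raise InfeasibleParameterError(
            f"exp(gamma*T)={growth:.4g} must exceed escape_fraction="
            f"{escape_fraction:.4g} for the survival relation to be invertible"
        )
    f = (mean_survival - escape_fraction) / denom
    if not (0.0 <= f <= 1.0):
        raise InfeasibleParameterError(
            f"survival {mean_survival!r} with T={T!r} h, T_d={T_d!r} h, "
            f"escape={escape_fraction!r} implies resistant fraction {f:.4g} "
            "outside [0, 1]"
        )
    return f


def rates_from_fraction_and_memory(
    f: float, memory_generations: float
) -> SwitchingParams:
    """Switching rates from the steady-state resistant fraction and the
    mean resistant-state residence time (in divisions).

    ``p_rs = 1/memory_generations`` and ``p_sr = f*p_rs/(1-f)``, so that
    ``steady_state_fraction(p_sr, p_rs) == f`` exactly.
    """
    if not (0.0 < f < 1.0):
        raise DegenerateModelError(
            f"steady-state fraction must lie strictly in (0, 1); got {f!r}"
        )
    if memory_generations < 1:
        raise ModelError(
            f"memory_generations must be >= 1; got {memory_generations!r}"
        )
    p_rs = 1.0 / memory_generations
    p_sr = f * p_rs / (1.0 - f)
    if p_sr > 1.0:
        raise InfeasibleParameterError(
            f"f={f!r} with memory {memory_generations!r} generations implies "
            f"p_sr={p_sr:.4g} > 1: not a probability"
        )
    return SwitchingParams(p_sr=p_sr, p_rs=p_rs)


def rates_from_fraction_and_relaxation(
    f: float, relaxation_generations: float
) -> SwitchingParams:
    """Switching rates from the steady-state fraction and the population
    relaxation timescale ``1/(p_sr + p_rs)`` in generations.

    Alternative parameterisation for when a measured "memory" reflects how
    fast the population-level resistant fraction relaxes to steady state
    (the reversion-curve timescale) rather than single-cell state
    residence time.
    """
    if not (0.0 < f < 1.0):
        raise DegenerateModelError(
            f"steady-state fraction must lie strictly in (0, 1); got {f!r}"
        )
    if relaxation_generations < 1:
        raise ModelError(
            f"relaxation_generations must be >= 1; got {relaxation_generations!r}"
        )
    rate = 1.0 / relaxation_generations
    p_sr = f * rate
    p_rs = (1.0 - f) * rate
    return SwitchingParams(p_sr=p_sr, p_rs=p_rs)


# ---------------------------------------------------------------------------
# Stochastic simulators
# ---------------------------------------------------------------------------


_MAX_GENERATIONS = 60  # int64 cell counts; 2^60 is the hard ceiling


def _draw_founders(
    params: SwitchingParams,
    founder: FounderState,
    n_clones: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder resistant indicator per clone (0 = S, 1 = R)."""
    if founder == "S":
        return np.zeros(n_clones, dtype=np.int64)
    if founder == "R":
        return np.ones(n_clones, dtype=np.int64)
    if founder == "steady_state":
        f = params.steady_state_f  # raises if both rates are zero
        return rng.binomial(1, f, size=n_clones).astype(np.int64)
    raise ModelError(f"unknown founder state {founder!r}")


def simulate_clone_compositions(
    params: SwitchingParams,
    generations: int,
    n_clones: int,
    founder: FounderState = "steady_state",
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised clone expansion for ``n_clones`` independent clones.

    Each clone starts from a single founder cell and doubles synchronously
    for ``generations`` generations; every daughter switches state
    independently. State counts are propagated by binomial thinning
    (``n_R' ~ Bin(2 n_R, 1-p_rs) + Bin(2 n_S, p_sr)``), which is
    distributionally identical to per-cell simulation.

    Returns
    -------
    (founders, n_sensitive, n_resistant) : int64 arrays of length n_clones
        Founder resistant indicators and final state counts;
        ``n_sensitive + n_resistant == 2**generations`` for every clone.
    """
    if generations < 0:
        raise ModelError(f"generations must be >= 0; got {generations!r}")
    if generations > _MAX_GENERATIONS:
        raise ModelError(
            f"generations={generations} exceeds the int64-safe ceiling "
            f"({_MAX_GENERATIONS})"
        )
    if n_clones < 1:
        raise ModelError(f"n_clones must be >= 1; got {n_clones!r}")
    rng = _as_rng(seed)
    founders = _draw_founders(params, founder, n_clones, rng)
    n_s, n_r = advance_compositions(
        params, 1 - founders, founders.copy(), generations, rng
    )
    return founders, n_s, n_r


def advance_compositions(
    params: SwitchingParams,
    n_sensitive: np.ndarray,
    n_resistant: np.ndarray,
    generations: int,
    rng: Union[int, np.random.Generator, None] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate existing clone compositions through further generations of
    synchronous doubling with per-division switching (binomial thinning)."""
    if generations < 0:
        raise ModelError(f"generations must be >= 0; got {generations!r}")
    rng = _as_rng(rng)
    n_r = np.asarray(n_resistant, dtype=np.int64)
    n_s = np.asarray(n_sensitive, dtype=np.int64)
    max_total = int((n_r + n_s).max(initial=0))
    if max_total > 0 and math.log2(max_total) + generations >= _MAX_GENERATIONS:
        raise ModelError(
            f"advancing by {generations} generations would overflow the "
            f"int64-safe population ceiling (2^{_MAX_GENERATIONS})"
        )
    for _ in range(int(generations)):
        total = n_s + n_r
        n_r = (
            rng.binomial(2 * n_r, 1.0 - params.p_rs)
            + rng.binomial(2 * n_s, params.p_sr)
        ).astype(np.int64)
        n_s = 2 * total - n_r
    return n_s, n_r


_HYPERGEOM_LIMIT = 10**8  # above this, binomial plating is indistinguishable


def plate_resistant(
    n_resistant: np.ndarray,
    n_sensitive: np.ndarray,
    plated: int,
    rng: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Resistant cells among ``plated`` cells drawn from each clone.

    Hypergeometric sampling without replacement; clones larger than 1e8
    cells use the binomial approximation (sampling fraction is then
    negligible and the two distributions agree).
    """
    rng = _as_rng(rng)
    n_r = np.asarray(n_resistant, dtype=np.int64)
    n_s = np.asarray(n_sensitive, dtype=np.int64)
    total = n_r + n_s
    if np.any(total < plated):
        raise SamplingError(
            f"plated_count={plated} exceeds at least one clone size "
            f"(min {int(total.min())})"
        )
    small = total <= _HYPERGEOM_LIMIT
    k = np.empty(total.shape, dtype=np.int64)
    if small.any():
        k[small] = rng.hypergeometric(n_r[small], n_s[small], plated)
    if (~small).any():
        k[~small] = rng.binomial(plated, n_r[~small] / total[~small])
    return k


def simulate_clone_composition(
    params: SwitchingParams,
    generations: int,
    founder: FounderState = "steady_state",
    seed: Union[int, np.random.Generator, None] = None,
) -> CloneComposition:
    """Expand a single clone from one founder cell; see
    :func:`simulate_clone_compositions` for the generative model."""
    founders, n_s, n_r = simulate_clone_compositions(
        params, generations, 1, founder=founder, seed=seed
    )
    return CloneComposition(
        n_sensitive=int(n_s[0]),
        n_resistant=int(n_r[0]),
        generations_expanded=int(generations),
        founder_state="R" if founders[0] else "S",
    )


def survival_components(
    f_plated: np.ndarray | float,
    assay: AssayParams,
    gamma: np.ndarray | float | None = None,
):
    """Live and dead cells at assay end, per plated cell.

    Sensitive cells: a fraction ``escape`` is alive (ungrown), the rest are
    dead. Resistant cells: net exponential change ``exp(gamma*T)``; when
    gamma < 0 the net loss is booked as dead cells.
    """
    g = assay.gamma if gamma is None else gamma
    growth = np.exp(np.asarray(g, dtype=float) * assay.T_suspension)
    f = np.asarray(f_plated, dtype=float)
    e = assay.escape_fraction
    live = f * growth + e * (1.0 - f)
    dead = (1.0 - e) * (1.0 - f) + f * np.clip(1.0 - growth, 0.0, None)
    return live, dead


def apply_counting_noise(
    live: np.ndarray | float,
    dead: np.ndarray | float,
    count_depth: Optional[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Noisy live-cell estimate from counting ``count_depth`` cells.

    The live fraction among all end-of-assay cells (live + dead) is
    estimated by a binomial count and rescaled to total cells; with
    ``count_depth=None`` the exact value is returned.
    """
    live = np.asarray(live, dtype=float)
    if count_depth is None:
        return live
    dead = np.asarray(dead, dtype=float)
    total = live + dead
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, live / np.where(total > 0, total, 1.0), 0.0)
    k = rng.binomial(count_depth, np.clip(p, 0.0, 1.0))
    return k / count_depth * total


def simulate_suspension_assay(
    comp: CloneComposition,
    assay: AssayParams,
    seed: Union[int, np.random.Generator, None] = None,
    gamma: Optional[float] = None,
) -> AssayOutcome:
    """Plate cells from a clone and score 24 h suspension survival.

    ``assay.plated_count`` cells are drawn hypergeometrically from the
    clone (the draw is exhaustive, hence deterministic, when the clone is
    plated in full). Expected survival follows
    :func:`expected_survival_fraction` applied to the plated resistant
    fraction; no state switching occurs during the assay. Counting noise
    is binomial subsampling at ``assay.count_depth`` followed by rescaling.

    ``gamma`` overrides the assay-level resistant growth rate, supporting
    clone-specific effective growth rates in the heterogeneity model.
    """
    total = comp.total
    if total <= 0:
        raise ModelError("clone composition is empty")
    plated = assay.plated_count
    if plated > total:
        raise SamplingError(
            f"plated_count={plated} exceeds the clone size {total}"
        )
    rng = _as_rng(seed)
    k = int(
        plate_resistant(
            np.array([comp.n_resistant]), np.array([comp.n_sensitive]), plated, rng
        )[0]
    )
    f_p = k / plated
    live, dead = survival_components(f_p, assay, gamma=gamma)
    live_obs = float(apply_counting_noise(live, dead, assay.count_depth, rng))
    return AssayOutcome(
        plated=plated,
        live_at_end=live_obs * plated,
        survival_fraction=live_obs,
        seed=seed if isinstance(seed, int) else None,
    )
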