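"""Descriptive and inferential statistics for clone suspension-survival tables.

The experimental unit is a clone × passage record: cells plated into
low-attachment suspension and live cells counted 24 h later. Survival
fractions are live/plated and deliberately not capped at 1 — values above
1 encode net growth of resistant cells. The fluctuation statistic is the
interclonal coefficient of variation (CV = SD/mean, sample SD with n−1
denominator) with a percentile-bootstrap 95% confidence interval obtained
by resampling clones with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TableValidationError",
    "InsufficientDataError",
    "CloneSurvivalTable",
    "FluctuationSummary",
    "PassageCorrelation",
    "make_clone_table",
    "load_clone_table",
    "write_clone_table",
    "interclonal_summary",
    "replicate_cv",
    "passage_correlation",
    "classify_anoikis",
]

REQUIRED_COLUMNS = ("clone_id", "passage", "plated_count", "live_count")
FRACTION_TOLERANCE = 1e-6


class TableValidationError(ValueError):
    """A clone-survival table violates the schema or its invariants."""


class InsufficientDataError(ValueError):
    """Too few records for the requested statistic."""


@dataclass(frozen=True)
class CloneSurvivalTable:
    """Validated clone × passage survival records.

    ``records`` columns: clone_id, passage, plated_count, live_count,
    survival_fraction (always recomputed as live/plated).
    """

    records: pd.DataFrame

    @property
    def passages(self) -> list[int]:
        return sorted(self.records["passage"].unique().tolist())

    @property
    def n_clones(self) -> int:
        return int(self.records["clone_id"].nunique())

    def at_passage(self, passage: int) -> pd.DataFrame:
        return self.records[self.records["passage"] == passage]


@dataclass(frozen=True)
class FluctuationSummary:
    """Interclonal survival statistics at one assay passage."""

    passage: int
    n: int
    mean: float
    sd: float
    cv: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "passage": self.passage,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "cv": self.cv,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PassageCorrelation:
    """OLS regression of clone survival at one passage on another."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int


def make_clone_table(df: pd.DataFrame) -> CloneSurvivalTable:
    """Validate a raw records frame and return a :class:`CloneSurvivalTable`.

    Survival fractions are recomputed from counts; a provided
    ``survival_fraction`` column is cross-checked against live/plated to
    within 1e-6. Row numbers in error messages refer to CSV line numbers
    (header = line 1).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise TableValidationError("table contains no records")

    df = df.reset_index(drop=True)
    lines = df.index + 2  # CSV line numbers, header on line 1

    for col in ("passage", "plated_count", "live_count"):
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            bad = lines[~df[col].apply(lambda v: isinstance(v, (int, float, np.number)))
                        | df[col].isna()].tolist()
            raise TableValidationError(
                f"column {col!r} has non-numeric or missing values "
                f"(lines {bad or 'unknown'})"
            )

    bad = lines[df["plated_count"] < 1].tolist()
    if bad:
        raise TableValidationError(f"plated_count < 1 at lines {bad}")
    bad = lines[df["live_count"] < 0].tolist()
    if bad:
        raise TableValidationError(f"negative live_count at lines {bad}")

    dup_mask = df.duplicated(subset=["clone_id", "passage"], keep=False)
    if dup_mask.any():
        pairs = df.loc[dup_mask, ["clone_id", "passage"]].drop_duplicates()
        raise TableValidationError(
            "duplicated (clone_id, passage) pairs "
            f"{list(map(tuple, pairs.itertuples(index=False)))} "
            f"at lines {lines[dup_mask].tolist()}"
        )

    computed = df["live_count"] / df["plated_count"]
    if "survival_fraction" in df.columns:
        diff = (df["survival_fraction"] - computed).abs()
        bad = lines[diff > FRACTION_TOLERANCE].tolist()
        if bad:
            raise TableValidationError(
                "survival_fraction column disagrees with live_count/plated_count "
                f"beyond {FRACTION_TOLERANCE} at lines {bad}"
            )
    out = df.copy()
    out["passage"] = out["passage"].astype(int)
    out["survival_fraction"] = computed
    return CloneSurvivalTable(records=out)


def load_clone_table(path) -> CloneSurvivalTable:
    """Read and validate a clone-survival CSV.

    Schema (header required): ``clone_id,passage,plated_count,live_count``
    with an optional ``survival_fraction`` column; UTF-8, comma-separated.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TableValidationError(f"empty or malformed CSV: {path}") from exc
    return make_clone_table(df)


def write_clone_table(table: CloneSurvivalTable, path) -> None:
    """Write a clone-survival table as CSV in the canonical schema."""
    cols = ["clone_id", "passage", "plated_count", "live_count", "survival_fraction"]
    table.records[cols].to_csv(path, index=False)


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean <= 0:
        raise InsufficientDataError("CV undefined: mean is not positive")
    return float(values.std(ddof=1) / mean)


def interclonal_summary(
    table: CloneSurvivalTable,
    passage: int,
    n_bootstrap: int = 10_000,
    seed: Optional[int] = None,
) -> FluctuationSummary:
    """Mean, SD and CV of clone survival at one passage, with a percentile
    bootstrap 95% CI on the CV (clones resampled with replacement)."""
    values = table.at_passage(passage)["survival_fraction"].to_numpy(dtype=float)
    n = len(values)
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 clones at passage {passage}; found {n}"
        )
    mean = float(values.mean())
    if mean <= 0:
        raise InsufficientDataError(
            f"CV undefined at passage {passage}: mean survival is not positive"
        )
    sd = float(values.std(ddof=1))
    cv = sd / mean

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    samples = values[idx]
    bmeans = samples.mean(axis=1)
    bsds = samples.std(axis=1, ddof=1)
    valid = bmeans > 0
    if not valid.any():
        raise InsufficientDataError("all bootstrap resamples have zero mean")
    bcv = bsds[valid] / bmeans[valid]
    ci_low, ci_high = np.percentile(bcv, [2.5, 97.5])
    return FluctuationSummary(
        passage=int(passage),
        n=n,
        mean=mean,
        sd=sd,
        cv=cv,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_bootstrap=int(n_bootstrap),
        seed=seed,
    )


def replicate_cv(values: Union[Sequence[float], np.ndarray]) -> float:
    """Sample CV of bulk-population replicate survival fractions.

    Serves as the measurement/biological noise floor against which the
    interclonal CV is compared.
    """
    arr = np.asarray(list(values) if isinstance(values, Iterable) else values,
                     dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"need >= 2 replicates; got {arr.size}")
    return _cv(arr)


def passage_correlation(
    table: CloneSurvivalTable, passage_a: int, passage_b: int
) -> PassageCorrelation:
    """OLS of clone survival at ``passage_b`` on survival at ``passage_a``.

    Clones are paired by ``clone_id``; clones missing at either passage are
    dropped pairwise with a warning. Returns slope, intercept, Pearson r
    and the two-sided p-value for slope != 0.
    """
    a = table.at_passage(passage_a)[["clone_id", "survival_fraction"]]
    b = table.at_passage(passage_b)[["clone_id", "survival_fraction"]]
    merged = a.merge(b, on="clone_id", suffixes=("_a", "_b"))
    n = len(merged)
    n_union = len(set(a["clone_id"]) | set(b["clone_id"]))
    if n < n_union:
        warnings.warn(
            f"{n_union - n} clone(s) missing at passage {passage_a} or "
            f"{passage_b}; dropped pairwise",
            stacklevel=2,
        )
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 clones present at both passages; found {n}"
        )
    x = merged["survival_fraction_a"].to_numpy(dtype=float)
    y = merged["survival_fraction_b"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InsufficientDataError(
            f"survival at passage {passage_a} is constant: regression undefined"
        )
    if np.ptp(y) == 0:
        # Constant response: zero slope, zero correlation, no evidence.
        return PassageCorrelation(
            slope=0.0, intercept=float(y[0]), r=0.0, p=1.0, n=n
        )
    res = stats.linregress(x, y)
    return PassageCorrelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=n,
    )


def classify_anoikis(survival_fraction: float) -> str:
    """Classify 24 h suspension survival: ``resistant`` iff >= 100% of the
    plated cells are alive, else ``sensitive``."""
    if survival_fraction < 0:
        raise ValueError(
            f"survival fraction must be >= 0; got {survival_fraction!r}"
        )
    return "resistant" if survival_fraction >= 1.0 else "sensitive"
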