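"""Region summaries, separation ratios, alarm-band derivation and the alarm
classifier.

Screw-track measurements are labeled by tissue region: ``spongy`` (probe tip
well above the cortical wall), ``alarm`` (tip within one detection depth of
the wall) and ``compact`` (tip at or past the wall). Four ratios quantify
how well a pattern factor separates the regions:

* ratio1 = (mean_spongy - mean_alarm) / mean_spongy
* ratio2 = (mean_alarm - mean_compact) / mean_alarm
* ratio3 = (min_spongy - max_alarm) / min_spongy
* ratio4 = (min_alarm - max_compact) / min_alarm

Ratios 1-2 compare region averages; ratios 3-4 compare region extremes, so a
negative value flags overlapping regions and is surfaced, never clipped.
The factor with the best joint separation across all four ratios defines the
alarm band: the [min, max] interval of that factor inside the alarm region,
rounded half-up to integer counts. A reading inside the band triggers the
alarm; above it the tip is still in spongy bone, below it the wall has been
reached.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateBandError,
    IncompleteLabelingError,
    InsufficientDataError,
    InvalidParameterError,
)
from .spectra import FACTOR_NAMES

logger = logging.getLogger(__name__)

REGIONS = ("spongy", "alarm", "compact")
RATIO_NAMES = ("ratio1", "ratio2", "ratio3", "ratio4")
ALPHA = 0.05


@dataclass(frozen=True)
class RegionSummary:
    """Per-region, per-factor mean/min/max table.

    ``table`` has a (region, factor) MultiIndex and columns mean/min/max.
    Unknown extremes may be NaN (e.g. a summary reconstructed from published
    aggregates); the min <= mean <= max invariant is enforced on known cells.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("mean", "min", "max"):
            if col not in t.columns:
                raise InvalidParameterError(f"summary missing column {col}")
        bad = (t["min"] > t["mean"]) | (t["mean"] > t["max"])
        if bool(bad.fillna(False).any()):
            raise InvalidParameterError("summary violates min <= mean <= max")

    def value(self, region: str, factor: str, stat: str) -> float:
        return float(self.table.loc[(region, factor), stat])

    @classmethod
    def from_nested(cls, values: dict) -> "RegionSummary":
        """Build from {region: {factor: {"mean": .., "min": .., "max": ..}}};
        missing stats become NaN."""
        rows = {}
        for region, factors in values.items():
            for factor, stats_ in factors.items():
                rows[(region, factor)] = {
                    "mean": stats_.get("mean", np.nan),
                    "min": stats_.get("min", np.nan),
                    "max": stats_.get("max", np.nan),
                }
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index = pd.MultiIndex.from_tuples(table.index, names=["region", "factor"])
        return cls(table)


@dataclass(frozen=True)
class RatioTable:
    """Separation ratios as fractions: rows ratio1..ratio4, columns factors.

    ``valid`` marks cells whose denominator was positive; invalid cells hold
    NaN. Negative (overlap) cells stay negative.
    """

    fractions: pd.DataFrame
    valid: pd.DataFrame

    def as_percent(self, ndigits: int = 2) -> pd.DataFrame:
        return (self.fractions * 100.0).round(ndigits)


@dataclass(frozen=True)
class AlarmBand:
    factor: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise DegenerateBandError(
                f"alarm band degenerate: lower {self.lower} >= upper {self.upper}"
            )

    def contains(self, value: float, slack: float = 0.0) -> bool:
        return (self.lower - slack) <= value <= (self.upper + slack)


@dataclass(frozen=True)
class SelectionResult:
    factor: str
    ranking: pd.DataFrame  # per-factor ranks per ratio plus rank_sum


@dataclass(frozen=True)
class GroupSeparationReport:
    """Per-factor p-values of the between-region omnibus test."""

    pvalues: pd.Series
    alpha: float = ALPHA

    @property
    def passed(self) -> pd.Series:
        return self.pvalues < self.alpha

    @property
    def all_passed(self) -> bool:
        return bool(self.passed.all())


def _check_series(series: pd.DataFrame, min_per_region: int = 1) -> None:
    missing = [r for r in REGIONS if r not in set(series["region"])]
    if missing:
        raise IncompleteLabelingError(f"series missing region(s): {missing}")
    counts = series["region"].value_counts()
    if int(counts.min()) < min_per_region:
        raise InsufficientDataError(
            f"need >= {min_per_region} records per region, got {counts.to_dict()}"
        )


def summarize_regions(series: pd.DataFrame) -> RegionSummary:
    """Mean/min/max of every pattern factor within each labeled region.

    ``series`` is a labeled factor table with columns ``region`` and the
    factor names (mu_s_reduced, peak, area, slope).
    """
    _check_series(series)
    rows = {}
    for region, grp in series.groupby("region"):
        for factor in FACTOR_NAMES:
            v = grp[factor].to_numpy(dtype=float)
            rows[(region, factor)] = {
                "mean": v.mean(),
                "min": v.min(),
                "max": v.max(),
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["region", "factor"])
    return RegionSummary(table)


def _ratio(numer_minuend: float, numer_subtrahend: float, denom: float) -> float:
    if denom == 0:
        raise InvalidParameterError("ratio denominator is zero")
    return (numer_minuend - numer_subtrahend) / denom


def ratio1(mean_spongy: float, mean_alarm: float) -> float:
    """(mean_spongy - mean_alarm) / mean_spongy."""
    return _ratio(mean_spongy, mean_alarm, mean_spongy)


def ratio2(mean_alarm: float, mean_compact: float) -> float:
    """(mean_alarm - mean_compact) / mean_alarm."""
    return _ratio(mean_alarm, mean_compact, mean_alarm)


def ratio3(min_spongy: float, max_alarm: float) -> float:
    """(min_spongy - max_alarm) / min_spongy; negative flags region overlap."""
    return _ratio(min_spongy, max_alarm, min_spongy)


def ratio4(min_alarm: float, max_compact: float) -> float:
    """(min_alarm - max_compact) / min_alarm; negative flags region overlap."""
    return _ratio(min_alarm, max_compact, min_alarm)


def compute_ratios(summary: RegionSummary) -> RatioTable:
    """All four ratios for every factor in the summary.

    Cells whose denominator is not positive are marked invalid (NaN) — a
    nonpositive denominator flips the ratio's sign semantics and carries no
    separation meaning.
    """
    spec = {
        "ratio1": (("spongy", "mean"), ("alarm", "mean"), ("spongy", "mean")),
        "ratio2": (("alarm", "mean"), ("compact", "mean"), ("alarm", "mean")),
        "ratio3": (("spongy", "min"), ("alarm", "max"), ("spongy", "min")),
        "ratio4": (("alarm", "min"), ("compact", "max"), ("alarm", "min")),
    }
    frac = pd.DataFrame(index=list(RATIO_NAMES), columns=list(FACTOR_NAMES), dtype=float)
    valid = pd.DataFrame(
        False, index=list(RATIO_NAMES), columns=list(FACTOR_NAMES)
    )
    for rname, ((r_a, s_a), (r_b, s_b), (r_d, s_d)) in spec.items():
        for factor in FACTOR_NAMES:
            a = summary.value(r_a, factor, s_a)
            b = summary.value(r_b, factor, s_b)
            d = summary.value(r_d, factor, s_d)
            if not (np.isfinite(a) and np.isfinite(b)) or not d > 0:
                frac.loc[rname, factor] = np.nan
                continue
            val = (a - b) / d
            frac.loc[rname, factor] = val
            valid.loc[rname, factor] = True
            if val < 0:
                logger.warning(
                    "%s for %s is negative (%.2f%%): regions overlap",
                    rname,
                    factor,
                    100 * val,
                )
    return RatioTable(frac, valid)


def select_alarm_factor(ratios: RatioTable) -> SelectionResult:
    """Pick the pattern factor with the best joint separation.

    Two-stage logic collapsed into one rank composite: within each ratio,
    factors are ranked by descending ratio value (rank 1 = best separation);
    invalid cells rank last. The factor with the smallest rank sum across
    ratio1..ratio4 wins; ties break deterministically by factor name.
    """
    if ratios.fractions.isna().all(axis=None):
        raise InvalidParameterError("ratio table has no valid cells")
    ranking = pd.DataFrame(index=list(ratios.fractions.columns), dtype=float)
    nfac = len(ratios.fractions.columns)
    for rname in ratios.fractions.index:
        row = ratios.fractions.loc[rname]
        # descending rank; NaN (invalid) forced to worst rank
        r = row.rank(ascending=False, method="min", na_option="bottom")
        r[row.isna()] = nfac
        ranking[rname] = r
    ranking["rank_sum"] = ranking.sum(axis=1)
    winner = min(
        ranking.index, key=lambda f: (float(ranking.loc[f, "rank_sum"]), str(f))
    )
    return SelectionResult(factor=str(winner), ranking=ranking)


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


def alarm_band(summary: RegionSummary, factor: str) -> AlarmBand:
    """Alarm band = [min, max] of ``factor`` within the alarm region, with
    endpoints rounded half-up to integers (count-scaled factors)."""
    lo = summary.value("alarm", factor, "min")
    hi = summary.value("alarm", factor, "max")
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise InvalidParameterError(f"summary lacks alarm extremes for {factor}")
    return AlarmBand(factor=factor, lower=round_half_up(lo), upper=round_half_up(hi))


def classify_point(value: float, band: AlarmBand) -> str:
    """Three-way partition of the factor axis: above the band the tip is in
    spongy bone, inside it the alarm fires, below it the wall is reached.
    Band endpoints belong to the alarm region."""
    if value > band.upper:
        return "spongy"
    if value < band.lower:
        return "compact"
    return "alarm"


def group_separation(
    series: pd.DataFrame, method: str = "kruskal", alpha: float = ALPHA
) -> GroupSeparationReport:
    """Between-region omnibus test per factor.

    Default is the Kruskal-Wallis rank test (no normality assumption);
    ``method="anova"`` switches to one-way ANOVA.
    """
    _check_series(series, min_per_region=2)
    pvals = {}
    for factor in FACTOR_NAMES:
        groups = [
            series.loc[series["region"] == r, factor].to_numpy(dtype=float)
            for r in REGIONS
        ]
        if method == "kruskal":
            try:
                res = stats.kruskal(*groups)
                p = float(res.pvalue)
            except ValueError:  # all values identical across groups
                p = 1.0
        elif method == "anova":
            res = stats.f_oneway(*groups)
            p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        else:
            raise InvalidParameterError(f"unknown test method {method!r}")
        pvals[factor] = p
    return GroupSeparationReport(pd.Series(pvals), alpha=alpha)
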