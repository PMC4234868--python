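"""Bundled porcine-vertebra reference values.

These are the published region aggregates of the porcine pedicle-screw
insertion study this package's defaults are calibrated to: per-region means
of the four pattern factors, and the region extremes used for the
extremes-based ratios. Extremes that were not published (spongy max,
compact min) are NaN. The shipped default alarm band (89783, 129872 area
counts) derives from the alarm-region area extremes of this table.

Known internal inconsistencies of the published ratio cells (they do not all
match the ratio formulas applied to the published aggregates) are recorded
in ``INCONSISTENT_PUBLISHED_RATIOS`` and surfaced as warnings by
``check_published_ratios``; the formula values are authoritative everywhere
in this package.
"""

from __future__ import annotations

import logging

import numpy as np

from .thresholds import RegionSummary, compute_ratios

logger = logging.getLogger(__name__)

#: Region means of the four pattern factors (area/peak/slope on spectrometer
#: count scale; slope on the x1000 reporting scale; mu_s' in cm^-1).
VERTEBRA_SUMMARY = RegionSummary.from_nested(
    {
        "spongy": {
            "mu_s_reduced": {"mean": 16.91, "min": 16.33, "max": np.nan},
            "peak": {"mean": 881.86, "min": 825.0, "max": np.nan},
            "area": {"mean": 185213.61, "min": 170300.3, "max": np.nan},
            "slope": {"mean": 15.64, "min": 4.87, "max": np.nan},
        },
        "alarm": {
            "mu_s_reduced": {"mean": 14.71, "min": 14.6, "max": 15.51},
            "peak": {"mean": 638.5, "min": 597.0, "max": 649.33},
            "area": {"mean": 106896.1, "min": 89782.84, "max": 129871.7},
            "slope": {"mean": 3.07, "min": 2.43, "max": 4.18},
        },
        "compact": {
            "mu_s_reduced": {"mean": 12.78, "min": np.nan, "max": 13.12},
            "peak": {"mean": 463.91, "min": np.nan, "max": 503.33},
            "area": {"mean": 72472.75, "min": np.nan, "max": 80788.38},
            "slope": {"mean": 1.81, "min": np.nan, "max": 2.21},
        },
    }
)

#: Published ratio percentages (rows ratio1..4) for cross-checking.
PUBLISHED_RATIO_PERCENT = {
    "ratio1": {"mu_s_reduced": 13.01, "peak": 38.11, "area": 42.28, "slope": 45.65},
    "ratio2": {"mu_s_reduced": 13.12, "peak": 27.34, "area": 32.2, "slope": 41.02},
    "ratio3": {"mu_s_reduced": 5.02, "peak": 21.29, "area": 23.74, "slope": 14.18},
    "ratio4": {"mu_s_reduced": 10.14, "peak": 15.69, "area": 10.02, "slope": 9.21},
}

#: Cells whose published percentage disagrees with the ratio formula applied
#: to the published aggregates by more than rounding (> 0.05 points).
INCONSISTENT_PUBLISHED_RATIOS = (
    ("ratio1", "peak"),   # published 38.11, formula gives 27.60
    ("ratio1", "slope"),  # published 45.65, formula gives 80.37
    ("ratio4", "slope"),  # published 9.21, formula gives 9.05
)


def check_published_ratios(tolerance_percent: float = 0.05) -> list[tuple[str, str, float, float]]:
    """Compare formula ratios on the bundled summary with the published
    percentages; returns and warn-logs the disagreeing cells as
    (ratio, factor, computed_percent, published_percent)."""
    computed = compute_ratios(VERTEBRA_SUMMARY).as_percent(2)
    mismatches = []
    for rname, cols in PUBLISHED_RATIO_PERCENT.items():
        for factor, published in cols.items():
            got = float(computed.loc[rname, factor])
            if abs(got - published) > tolerance_percent:
                mismatches.append((rname, factor, got, published))
                logger.warning(
                    "published %s for %s (%.2f%%) inconsistent with its "
                    "formula on the published aggregates (%.2f%%)",
                    rname,
                    factor,
                    published,
                    got,
                )
    return mismatches
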