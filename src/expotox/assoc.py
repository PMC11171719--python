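"""Exposure–indicator association accounting.

Quarterly case tabulation for each clinical indicator (total cases, positive
cases, cases attributed to PM2.5-type exposure), the percentage of positive
cases associated with exposure, the Pearson correlation between per-bin
positivity rate and mean exposure, and the identification rule that labels
an indicator positive-, negative- or not-associated by the magnitude and
sign of that correlation.  Not-associated indicators have their attributed
counts suppressed (rendered as an en dash) in the output table.

``REFERENCE_QUARTERLY_TABLE`` holds a published quarterly association
tabulation between PM2.5 and five cardiorespiratory indicators (CKMB, LDH,
CRP, CYFRA21-1 and neuron-specific enolase) from a hospital examination
cohort; it is used to validate the tabulation arithmetic and the
identification rule against known output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import HealthTable

MISSING = "–"   # en dash marker for suppressed/undefined cells


class Identification(enum.Enum):
    POSITIVE = "positive-associated"
    NEGATIVE = "negative-associated"
    NOT_ASSOCIATED = "not-associated"


@dataclass
class QuarterCounts:
    """Case counts for one indicator in one calendar quarter."""

    quarter: int
    total: int
    positive: int
    associated: int | None

    def __post_init__(self):
        if not 1 <= self.quarter <= 4:
            raise ValueError("quarter must be 1..4")
        if self.associated is not None:
            if not 0 <= self.associated <= self.positive <= self.total:
                raise ValueError("require associated <= positive <= total")
        elif self.positive > self.total:
            raise ValueError("require positive <= total")


def percent_associated(counts: QuarterCounts) -> float | None:
    """100 * associated / positive, rounded half-up to 2 decimals.

    Undefined (returns None, rendered as the en dash) when there are no
    positive cases or the associated count is suppressed.
    """
    if counts.positive == 0 or counts.associated is None:
        return None
    pct = Decimal(100 * counts.associated) / Decimal(counts.positive)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def identify(r: float, threshold: float = 0.3) -> Identification:
    """|r| >= threshold identifies the indicator as exposure-associated,
    with the direction given by the sign of r."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) >= threshold:
        return (Identification.POSITIVE if r > 0
                else Identification.NEGATIVE)
    return Identification.NOT_ASSOCIATED


@dataclass
class AssociationRow:
    """One indicator's quarterly accounting plus its correlation with
    exposure and the resulting identification."""

    indicator: str
    quarters: list[QuarterCounts]
    r: float
    threshold: float = 0.3

    @property
    def identified(self) -> Identification:
        return identify(self.r, self.threshold)

    @property
    def percents(self) -> list[float | None]:
        return [percent_associated(q) for q in self.quarters]

    def render(self) -> dict:
        """Table cells; attributed counts and percents of a not-associated
        indicator are suppressed with the en dash marker."""
        suppress = self.identified is Identification.NOT_ASSOCIATED
        row = {"indicator": self.indicator, "r": self.r,
               "identified": self.identified.value}
        for q in self.quarters:
            tag = f"q{q.quarter}"
            row[f"total_{tag}"] = q.total
            row[f"positive_{tag}"] = q.positive
            pct = percent_associated(q)
            if suppress or q.associated is None:
                row[f"associated_{tag}"] = MISSING
                row[f"percent_{tag}"] = MISSING
            else:
                row[f"associated_{tag}"] = q.associated
                row[f"percent_{tag}"] = MISSING if pct is None else pct
        return row


def attribute_exposure(exposure, predicted_positive,
                       quantile: float = 0.75) -> np.ndarray:
    """Exposure-attribution flag per record: model-positive AND trailing
    window-mean exposure above the given quantile of the exposure
    distribution."""
    exposure = np.asarray(exposure, dtype=float)
    pred = np.asarray(predicted_positive).astype(bool)
    cut = np.quantile(exposure, quantile)
    return pred & (exposure > cut)


def tabulate(table: HealthTable, indicator: str, flags, year: int
             ) -> list[QuarterCounts]:
    """Count totals / positives / exposure-attributed cases per calendar
    quarter of ``year``.  All records must fall inside the year; quarter
    totals sum to the number of records."""
    dates = pd.DatetimeIndex(table.timestamps)
    if ((dates.year != year)).any():
        raise ValueError(f"records outside year {year}")
    pos = table.labels[indicator].to_numpy().astype(bool)
    flags = np.asarray(flags).astype(bool)
    quarters = dates.quarter
    out = []
    for q in (1, 2, 3, 4):
        sel = quarters == q
        out.append(QuarterCounts(
            quarter=q,
            total=int(sel.sum()),
            positive=int((sel & pos).sum()),
            associated=int((sel & pos & flags).sum()),
        ))
    return out


def indicator_correlation(positivity, exposure, timestamps=None,
                          freq: str = "W") -> float:
    """Pearson correlation between per-bin positivity rate and per-bin mean
    exposure (default bin: week).  Requires at least 3 bins and non-constant
    binned series."""
    pos = np.asarray(positivity, dtype=float)
    exp_ = np.asarray(exposure, dtype=float)
    if timestamps is None:
        raise ValueError("timestamps are required for binning")
    df = pd.DataFrame({"pos": pos, "exp": exp_},
                      index=pd.DatetimeIndex(timestamps))
    binned = df.resample(freq).mean().dropna()
    if len(binned) < 3:
        raise ValueError("need at least 3 bins with data")
    if binned["pos"].std() == 0 or binned["exp"].std() == 0:
        raise ValueError("constant binned series; correlation undefined")
    r, _ = stats.pearsonr(binned["pos"], binned["exp"])
    return float(r)


def association_table(rows: list[AssociationRow]) -> pd.DataFrame:
    """Assemble rendered rows into the quarterly association table."""
    return pd.DataFrame([row.render() for row in rows]).set_index("indicator")


# ---------------------------------------------------------------------------
# published reference tabulation (hospital examination cohort, PM2.5)

REFERENCE_QUARTERLY_TABLE: dict[str, dict] = {
    "CKMB": {
        "total": (3055, 2460, 3484, 3585),
        "positive": (283, 270, 210, 241),
        "associated": (23, 17, 12, 18),
        "printed_percent": (8.12, 6.30, 5.71, 7.47),
        "r": 0.435,
    },
    "LDH": {
        "total": (2845, 3081, 4215, 3284),
        "positive": (674, 589, 592, 584),
        "associated": (55, 35, 31, 46),
        "printed_percent": (8.17, 5.94, 5.24, 7.88),
        "r": 0.254,
    },
    "CRP": {
        "total": (9675, 6842, 9485, 8641),
        "positive": (3845, 2575, 4082, 3028),
        "associated": (280, 88, 135, 226),
        "printed_percent": (7.28, 3.42, 3.30, 7.46),
        "r": 0.481,
    },
    "CYFRA21-1": {
        "total": (4851, 5254, 5580, 4251),
        "positive": (668, 1548, 1589, 621),
        "associated": (59, 95, 100, 52),
        "printed_percent": (8.83, 6.14, 6.92, 8.37),
        "r": -0.597,
    },
    "NSE": {
        "total": (3055, 3515, 2544, 2612),
        "positive": (311, 432, 189, 205),
        "associated": (None, None, None, None),
        "printed_percent": (None, None, None, None),
        "r": 0.062,
    },
}

# (indicator, quarter index) cells where the published percent disagrees
# with half-up rounding of 100*associated/positive (mixed rounding in the
# source); excluded from exact-reproduction checks.
REFERENCE_AMBIGUOUS_CELLS: frozenset[tuple[str, int]] = frozenset({
    ("CKMB", 0), ("LDH", 0), ("CRP", 2), ("CYFRA21-1", 2),
})


def reference_rows(threshold: float = 0.3) -> list[AssociationRow]:
    """The reference tabulation as :class:`AssociationRow` objects."""
    rows = []
    for name, d in REFERENCE_QUARTERLY_TABLE.items():
        quarters = [
            QuarterCounts(quarter=q + 1, total=d["total"][q],
                          positive=d["positive"][q],
                          associated=d["associated"][q])
            for q in range(4)
        ]
        rows.append(AssociationRow(indicator=name, quarters=quarters,
                                   r=d["r"], threshold=threshold))
    return rows
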