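"""CTC count kinetics versus radiographic response.

Counts from a blood draw (typically 3 mL) are normalized to a 7.5 mL basis,
the change ratio at each follow-up draw is computed relative to the baseline
(day-0) draw,

    ΔCTC(%) = 100 * (CTC_i − CTC_0) / CTC_0,

each draw is paired to the nearest-in-time RECIST assessment, and the PD vs
PR change rates are compared with a two-sample Student's t-test (pooled
variance by default, Welch by flag).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")
REPORTING_VOLUME_ML = 7.5
DEFAULT_PAIRING_WINDOW_DAYS = 45


def normalize_count(raw_count: float, volume_ml: float) -> float:
    """Scale a raw count to cells per 7.5 mL of blood."""
    if volume_ml <= 0:
        raise ValueError(f"blood volume must be positive, got {volume_ml}")
    if raw_count < 0:
        raise ValueError(f"raw count must be non-negative, got {raw_count}")
    return raw_count * REPORTING_VOLUME_ML / volume_ml


@dataclasses.dataclass(frozen=True)
class CTCDraw:
    day: int
    raw_count: float
    volume_ml: float

    @property
    def count_75(self) -> float:
        return normalize_count(self.raw_count, self.volume_ml)


@dataclasses.dataclass(frozen=True)
class ResponseAssessment:
    patient_id: str
    day: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in RECIST_CATEGORIES:
            raise ValueError(
                f"category must be one of {RECIST_CATEGORIES}, got {self.category!r}"
            )


class CTCTimeSeries:
    """Dated CTC counts for one patient, anchored at a day-0 baseline draw."""

    def __init__(self, patient_id: str, draws: Sequence[CTCDraw]) -> None:
        self.patient_id = patient_id
        self.draws = sorted(draws, key=lambda d: d.day)
        days = [d.day for d in self.draws]
        if len(set(days)) != len(days):
            raise ValueError(f"patient {patient_id}: duplicate draw days {days}")
        if not self.draws or self.draws[0].day != 0:
            raise ValueError(f"patient {patient_id}: baseline draw at day 0 is required")

    @classmethod
    def from_counts(cls, patient_id: str,
                    counts: Iterable[tuple[int, float, float]]) -> "CTCTimeSeries":
        """Build from (day, raw_count, volume_ml) triples."""
        return cls(patient_id, [CTCDraw(d, c, v) for d, c, v in counts])

    @property
    def baseline(self) -> CTCDraw:
        return self.draws[0]

    @property
    def days(self) -> list[int]:
        return [d.day for d in self.draws]

    def draw_at(self, day: int) -> CTCDraw:
        for d in self.draws:
            if d.day == day:
                return d
        raise KeyError(f"patient {self.patient_id}: no draw at day {day}")


@dataclasses.dataclass
class DeltaCTC:
    patient_id: str
    day: int
    value: float                      # percent change from baseline
    matched_response: str | None = None


def ctc_change_ratio(series: CTCTimeSeries, day_i: int) -> DeltaCTC:
    """Percent change of the day-``day_i`` count relative to baseline.

    The ratio is volume-invariant (raw and per-7.5 mL counts give the same
    value).  A zero baseline makes the ratio undefined and is an error; batch
    helpers skip such series with a warning instead.
    """
    c0 = series.baseline.count_75
    if c0 <= 0:
        raise ValueError(
            f"patient {series.patient_id}: baseline count is 0, ΔCTC undefined"
        )
    ci = series.draw_at(day_i).count_75
    return DeltaCTC(series.patient_id, day_i, 100.0 * (ci - c0) / c0)


def change_series(series: CTCTimeSeries) -> list[DeltaCTC]:
    """ΔCTC for every follow-up draw; empty (with a warning) if baseline is 0."""
    if series.baseline.count_75 <= 0:
        logger.warning(
            "patient %s excluded from ΔCTC analysis: baseline count is 0",
            series.patient_id,
        )
        return []
    return [ctc_change_ratio(series, d.day) for d in series.draws[1:]]


def pair_delta_with_response(
    deltas: Sequence[DeltaCTC],
    assessments: Sequence[ResponseAssessment],
    max_gap_days: int = DEFAULT_PAIRING_WINDOW_DAYS,
) -> list[DeltaCTC]:
    """Attach to each ΔCTC the nearest-in-time assessment within the window.

    Ties (equidistant scans) resolve to the earlier scan.  Draws with no scan
    within ``max_gap_days`` stay unpaired (``matched_response`` is None) and
    are excluded from group comparisons.
    """
    by_patient: dict[str, list[ResponseAssessment]] = {}
    for a in assessments:
        by_patient.setdefault(a.patient_id, []).append(a)
    out = []
    for d in deltas:
        best = None
        for a in sorted(by_patient.get(d.patient_id, []), key=lambda a: a.day):
            gap = abs(a.day - d.day)
            if gap <= max_gap_days and (best is None or gap < abs(best.day - d.day)):
                best = a
        out.append(dataclasses.replace(
            d, matched_response=best.category if best else None))
    return out


@dataclasses.dataclass
class GroupComparison:
    statistic: float
    p_value: float
    group_means: dict[str, float]
    group_n: dict[str, int]
    welch: bool


def compare_response_groups(
    deltas: Sequence[DeltaCTC],
    groups: tuple[str, str] = ("PD", "PR"),
    welch: bool = False,
) -> GroupComparison:
    """Two-sample two-sided t-test of ΔCTC between two response groups.

    Classical pooled-variance Student's t by default; set ``welch=True`` for
    the unequal-variance form.  Unpaired deltas are ignored.
    """
    a_name, b_name = groups
    a = [d.value for d in deltas if d.matched_response == a_name]
    b = [d.value for d in deltas if d.matched_response == b_name]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"both groups need >= 2 observations, got {a_name}: {len(a)}, "
            f"{b_name}: {len(b)}"
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_means={a_name: float(np.mean(a)), b_name: float(np.mean(b))},
        group_n={a_name: len(a), b_name: len(b)},
        welch=welch,
    )
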