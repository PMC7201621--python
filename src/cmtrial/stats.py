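"""Group summaries and pairwise tests shaped like a trial outcome table.

Conventions follow the original analysis software's defaults: two-sided
Student's t with pooled variance for continuous variables (Welch available
by flag), Pearson chi-square without continuity correction for proportions,
alpha = 0.05, no multiple-testing adjustment, and both intention-to-treat
and per-protocol populations. ``reconstruct_counts`` inverts printed
percentages back to integer numerators so published proportions can be
re-tested exactly.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    AmbiguityError,
    DataIntegrityError,
    DegenerateInputError,
    InvalidInputError,
)
from .protocol import Arm, round_half_away

__all__ = [
    "PairwiseResult",
    "TrialReport",
    "t_test_independent",
    "chi_square_test",
    "reconstruct_counts",
    "build_report",
    "ALPHA",
]

ALPHA = 0.05

#: Continuous dosing variables summarized per arm (column names in the
#: prescriptions table).
DOSING_VARIABLES = ("main_bolus_volume", "test_bolus_volume", "flow_rate", "idr", "til")
#: Continuous quality variables (columns in the quality table).
QUALITY_VARIABLES = ("overall_hu", "noise", "cnr", "snr")
#: Patient-level proportions (boolean columns in the quality table;
#: good_excellent is derived from the Likert score).
PROPORTION_VARIABLES = ("in_window", "diagnostic", "good_excellent")
SEGMENT_PROPORTION_VARIABLES = (
    "seg_in_window",
    "seg_diagnostic",
    "seg_good_excellent",
)

_ARM_ORDER = (Arm.BW.value, Arm.LBW.value, Arm.CO.value)


@dataclass(frozen=True)
class PairwiseResult:
    """One two-sample comparison at alpha = 0.05."""

    variable: str
    arms: tuple[str, str]
    statistic: float
    p_value: float
    test: str  # "t" or "chi2"

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidInputError(f"p-value {self.p_value} outside [0, 1]")


def t_test_independent(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variable: str = "",
    arms: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> PairwiseResult:
    """Two-sided independent-samples t test (pooled variance by default).

    Degenerate inputs: if the pooled variance is zero and the means are
    equal the samples are indistinguishable (t = 0, p = 1 by convention);
    zero variance with unequal means admits no t statistic and raises.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return PairwiseResult(variable, arms, 0.0, 1.0, "t")
        raise DegenerateInputError(
            "zero variance in both samples with unequal means"
        )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return PairwiseResult(
        variable, arms, float(res.statistic), float(res.pvalue), "t"
    )


def chi_square_test(
    contingency: Sequence[Sequence[float]],
    variable: str = "",
    arms: tuple[str, str] = ("a", "b"),
) -> PairwiseResult:
    """Pearson chi-square on an r x c table, no continuity correction.

    statistic = sum (O - E)^2 / E with E the product-of-margins
    expectations, df = (r-1)(c-1). A zero row or column margin leaves some
    expected counts undefined and raises.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise InvalidInputError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise InvalidInputError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateInputError("zero marginal in contingency table")
    expected = np.outer(row, col) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(statistic, df))
    return PairwiseResult(variable, arms, statistic, p, "chi2")


def reconstruct_counts(percent: float, n: int, decimals: int = 1) -> int:
    """Invert a printed percentage to its integer numerator.

    Returns the unique k in [0, n] whose exact percentage rounds (half away
    from zero) to ``percent`` at the printed precision and lies closest to
    it; raises if no k rounds correctly or two candidates tie.
    """
    if n <= 0:
        raise InvalidInputError("denominator must be positive")
    if not 0 <= percent <= 100:
        raise InvalidInputError("percent must lie in [0, 100]")
    candidates = [
        k
        for k in range(n + 1)
        if round_half_away(100.0 * k / n, decimals) == round_half_away(percent, decimals)
    ]
    if not candidates:
        raise InvalidInputError(
            f"no count k/{n} rounds to {percent}% at {decimals} decimals"
        )
    distances = [abs(k / n - percent / 100.0) for k in candidates]
    best = min(distances)
    winners = [k for k, d in zip(candidates, distances) if d == best]
    if len(winners) > 1:
        raise AmbiguityError(
            f"{percent}% of {n} is ambiguous: candidates {winners}"
        )
    return winners[0]


@dataclass
class TrialReport:
    """Group-level summaries and all pairwise comparisons for one
    analysis population."""

    population: str  # "itt" or "pp"
    n_per_arm: dict[str, int]
    continuous: dict[str, dict[str, dict[str, float]]]  # var -> arm -> stats
    proportions: dict[str, dict[str, dict[str, float]]]  # var -> arm -> counts
    pairwise: list[PairwiseResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["pairwise"] = [
            {**asdict(p), "significant": p.significant} for p in self.pairwise
        ]
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def pairwise_lookup(self, variable: str, arm_a: str, arm_b: str) -> PairwiseResult:
        key = {arm_a, arm_b}
        for p in self.pairwise:
            if p.variable == variable and set(p.arms) == key:
                return p
        raise KeyError(f"no pairwise result for {variable} between {arm_a}/{arm_b}")


def _continuous_summary(values: np.ndarray) -> dict[str, float]:
    return {
        "n": int(values.size),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def build_report(
    quality: pd.DataFrame,
    prescriptions: pd.DataFrame,
    allocations: pd.DataFrame,
    population: str = "itt",
    deviation_flags: Optional[Mapping[str, bool]] = None,
    segment_counts: Optional[pd.DataFrame] = None,
) -> TrialReport:
    """Assemble the full outcome report for one analysis population.

    ``quality``, ``prescriptions`` and ``allocations`` are joined on
    ``patient_id``; ids missing from either side raise
    :class:`DataIntegrityError`. ``population`` "pp" drops patients whose
    ``deviation_flags`` entry is true. ``segment_counts``, if given, is a
    per-arm table with columns ``arm, n_segments, n_in_window,
    n_diagnostic, n_good_excellent`` (as produced by pooling
    :func:`cmtrial.quality.per_segment_summaries` per arm) and adds the
    per-segment proportion block.
    """
    population = population.lower()
    if population not in ("itt", "pp"):
        raise InvalidInputError(f"unknown analysis population {population!r}")

    alloc = allocations.set_index("patient_id")
    rx = prescriptions.set_index("patient_id")
    qual = quality.set_index("patient_id")

    orphans = sorted(
        set(qual.index).symmetric_difference(alloc.index)
        | set(qual.index).symmetric_difference(rx.index)
    )
    if orphans:
        raise DataIntegrityError(f"tables do not join cleanly; orphan ids {orphans}")
    for name, frame in (("allocations", alloc), ("quality", qual), ("rx", rx)):
        if frame.index.duplicated().any():
            dupes = sorted(frame.index[frame.index.duplicated()])
            raise DataIntegrityError(f"duplicate patient ids in {name}: {dupes}")

    joined = qual.join(rx.drop(columns=["arm"], errors="ignore")).join(
        alloc[["arm"]]
    )
    if population == "pp":
        flags = deviation_flags or {}
        keep = [pid for pid in joined.index if not flags.get(pid, False)]
        joined = joined.loc[keep]
    joined = joined.reset_index()
    joined["good_excellent"] = joined["likert"] >= 3

    arms = [a for a in _ARM_ORDER if a in set(joined["arm"])]
    n_per_arm = {arm: int((joined["arm"] == arm).sum()) for arm in arms}

    continuous: dict[str, dict[str, dict[str, float]]] = {}
    for var in DOSING_VARIABLES + QUALITY_VARIABLES:
        continuous[var] = {
            arm: _continuous_summary(
                joined.loc[joined["arm"] == arm, var].to_numpy(dtype=float)
            )
            for arm in arms
        }

    proportions: dict[str, dict[str, dict[str, float]]] = {}
    for var in PROPORTION_VARIABLES:
        proportions[var] = {}
        for arm in arms:
            sub = joined.loc[joined["arm"] == arm, var].astype(bool)
            num, den = int(sub.sum()), int(sub.size)
            proportions[var][arm] = {
                "numerator": num,
                "denominator": den,
                "percent": 100.0 * num / den if den else math.nan,
            }
    if segment_counts is not None:
        seg = segment_counts.set_index("arm")
        for var, col in zip(
            SEGMENT_PROPORTION_VARIABLES,
            ("n_in_window", "n_diagnostic", "n_good_excellent"),
        ):
            proportions[var] = {}
            for arm in arms:
                num = int(seg.loc[arm, col])
                den = int(seg.loc[arm, "n_segments"])
                proportions[var][arm] = {
                    "numerator": num,
                    "denominator": den,
                    "percent": 100.0 * num / den if den else math.nan,
                }

    pairwise: list[PairwiseResult] = []
    for var in DOSING_VARIABLES + QUALITY_VARIABLES:
        for arm_a, arm_b in itertools.combinations(arms, 2):
            pairwise.append(
                t_test_independent(
                    joined.loc[joined["arm"] == arm_a, var].to_numpy(dtype=float),
                    joined.loc[joined["arm"] == arm_b, var].to_numpy(dtype=float),
                    variable=var,
                    arms=(arm_a, arm_b),
                )
            )
    for var in proportions:
        for arm_a, arm_b in itertools.combinations(arms, 2):
            pa, pb = proportions[var][arm_a], proportions[var][arm_b]
            table = [
                [pa["numerator"], pa["denominator"] - pa["numerator"]],
                [pb["numerator"], pb["denominator"] - pb["numerator"]],
            ]
            try:
                pairwise.append(
                    chi_square_test(table, variable=var, arms=(arm_a, arm_b))
                )
            except DegenerateInputError:
                # all-yes or all-no in both arms: no contrast to test
                pairwise.append(
                    PairwiseResult(var, (arm_a, arm_b), 0.0, 1.0, "chi2")
                )

    return TrialReport(
        population=population,
        n_per_arm=n_per_arm,
        continuous=continuous,
        proportions=proportions,
        pairwise=pairwise,
    )
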