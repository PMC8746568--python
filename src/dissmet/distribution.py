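"""Tissue-distribution differencing and behavioral summary statistics.

Presence/absence of each metabolite across six biological matrices
(plasma, urine, feces, liver, kidney, brain) is compared between the sham
control and disease-model groups; set differences flag metabolites whose
in vivo distribution changed, including blood-brain-barrier penetrance
(brain = matrix code 6).

The behavioral side covers the novel-object recognition index
RI = T_novel / (T_familiar + T_novel) and a pooled-variance two-sample
t-test computed from summary statistics (mean, SD, n), with Welch's
approximation available behind a flag and Bonferroni adjustment for
families of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

__all__ = [
    "MATRIX_NAMES",
    "MATRIX_CODES",
    "BRAIN",
    "DistributionRecord",
    "DifferentialResult",
    "differential_report",
    "bbb_penetrance",
    "recognition_index",
    "GroupSummary",
    "pooled_t_test",
    "bonferroni",
]

#: Biological matrix codes used in the distribution table.
MATRIX_NAMES: Mapping[int, str] = {
    1: "plasma",
    2: "urine",
    3: "feces",
    4: "liver",
    5: "kidney",
    6: "brain",
}
MATRIX_CODES: Mapping[str, int] = {name: code for code, name in MATRIX_NAMES.items()}
BRAIN = 6


def _check_codes(codes: Iterable[int], context: str) -> frozenset[int]:
    out = frozenset(codes)
    for c in out:
        if c not in MATRIX_NAMES:
            raise ValueError(f"{context}: unknown matrix code {c!r} (valid: 1-6)")
    return out


@dataclass(frozen=True)
class DistributionRecord:
    """Per-metabolite matrix sets for the two study groups.

    Each set is the union over that metabolite's polarity rows: detection
    in either ionization mode counts as detection.
    """

    metabolite_id: str
    sham: frozenset[int]
    model: frozenset[int]

    def __post_init__(self):
        object.__setattr__(self, "sham", _check_codes(self.sham, self.metabolite_id))
        object.__setattr__(self, "model", _check_codes(self.model, self.metabolite_id))


@dataclass(frozen=True)
class DifferentialResult:
    metabolite_id: str
    sham_only: frozenset[int]
    model_only: frozenset[int]

    @property
    def concordant(self) -> bool:
        return not self.sham_only and not self.model_only


def differential_report(records: Sequence[DistributionRecord]) -> list[DifferentialResult]:
    """Per-metabolite set differences between sham and model distributions."""
    return [
        DifferentialResult(
            r.metabolite_id,
            sham_only=r.sham - r.model,
            model_only=r.model - r.sham,
        )
        for r in records
    ]


def bbb_penetrance(
    records: Sequence[DistributionRecord],
) -> tuple[list[str], list[str]]:
    """Metabolites whose brain presence differs between groups.

    Returns ``(brain_in_model_only, brain_in_sham_only)`` metabolite-id
    lists, derived solely from matrix code 6 membership.
    """
    model_only = [r.metabolite_id for r in records if BRAIN in r.model and BRAIN not in r.sham]
    sham_only = [r.metabolite_id for r in records if BRAIN in r.sham and BRAIN not in r.model]
    return model_only, sham_only


def recognition_index(t_novel: float, t_familiar: float) -> float:
    """Novel-object recognition index: novel time over total exploration time."""
    if t_novel < 0 or t_familiar < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total == 0:
        raise ValueError("recognition index undefined: both exploration times are zero")
    return t_novel / total


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group: mean, standard deviation, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2 per group for a t-test")


def pooled_t_test(
    a: GroupSummary,
    b: GroupSummary,
    two_sided: bool = True,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    Default is the pooled-variance (Student) form with
    df = n_a + n_b - 2; ``welch=True`` switches to the Welch-Satterthwaite
    approximation.  Returns ``(t, df, p)``; the sign of ``t`` follows
    ``a.mean - b.mean``.  Zero variance with equal means gives
    ``(0, df, 1)``; zero variance with unequal means is an error.
    """
    va, vb = a.sd**2, b.sd**2
    diff = a.mean - b.mean
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    if welch:
        se2 = va / a.n + vb / b.n
        df = se2**2 / ((va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1))
    else:
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
        se2 = sp2 * (1.0 / a.n + 1.0 / b.n)
        df = float(a.n + b.n - 2)
    t = diff / se2**0.5
    tail = stats.t.sf(abs(t), df)
    p = 2.0 * tail if two_sided else stats.t.sf(t, df)
    return float(t), float(df), float(min(p, 1.0))


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni adjustment: each p multiplied by ``m``, capped at 1."""
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    return [min(1.0, p * m) for p in p_values]
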