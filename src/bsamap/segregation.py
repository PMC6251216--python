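"""Goodness-of-fit tests for Mendelian segregation ratios.

The core statistic is the Pearson chi-square without continuity correction,
``chi2 = sum_i (O_i - E_i)^2 / E_i`` with ``E_i = N * ratio_i / sum(ratio)``,
compared against the chi-square distribution with ``k - 1`` degrees of
freedom. For a two-class trait at alpha = 0.05 the critical value is 3.84.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

ALPHA = 0.05


@dataclass
class SegregationObservation:
    class_counts: list[int]
    expected_ratio: list[float]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.class_counts) != len(self.expected_ratio):
            raise ValueError("class_counts and expected_ratio must have equal length")
        if len(self.class_counts) < 2:
            raise ValueError("need at least two phenotype classes")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("counts must be non-negative")
        if sum(self.class_counts) == 0:
            raise ValueError("total observed count must be positive")
        if any(r <= 0 for r in self.expected_ratio):
            raise ValueError("expected ratio terms must be positive")


@dataclass
class GofResult:
    chi_square: float
    df: int
    p_value: float
    critical_value_alpha05: float
    fits: bool
    label: str = ""


@dataclass
class InheritanceVerdict:
    verdict: str  # "monogenic recessive" | "not consistent"
    reasons: list[str] = field(default_factory=list)
    bc1: GofResult | None = None
    f2: GofResult | None = None

    @property
    def consistent(self) -> bool:
        return self.verdict == "monogenic recessive"


def chi_square_gof(obs: SegregationObservation) -> GofResult:
    """Pearson goodness-of-fit of observed class counts to an expected ratio.

    No continuity correction is applied. ``fits`` is true when the statistic
    does not exceed the chi-square critical value at alpha = 0.05 (3.84 for
    two classes), i.e. when P > 0.05.
    """
    observed = np.asarray(obs.class_counts, dtype=float)
    ratio = np.asarray(obs.expected_ratio, dtype=float)
    expected = observed.sum() * ratio / ratio.sum()
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = observed.size - 1
    crit = float(stats.chi2.ppf(1.0 - ALPHA, df))
    return GofResult(
        chi_square=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        critical_value_alpha05=crit,
        fits=chi2 <= crit,
        label=obs.label,
    )


def classify_inheritance(
    f1_counts: list[tuple[int, int]],
    bc1: SegregationObservation,
    f2: SegregationObservation,
) -> InheritanceVerdict:
    """Classify a trait as monogenic recessive from F1, BC1 and F2 tallies.

    The verdict is "monogenic recessive" iff every F1 family is uniformly
    normal-phenotype (the cross of two homozygous parents is heterozygous,
    so a recessive trait cannot appear), the backcross to the mutant parent
    fits 1:1, and the F2 fits 3:1, both at P > 0.05. Otherwise every failing
    condition is named.
    """
    if not f1_counts or all(n + m == 0 for n, m in f1_counts):
        raise ValueError("F1 observations are empty")
    reasons: list[str] = []
    for i, (normal, mutant) in enumerate(f1_counts, start=1):
        if mutant > 0:
            reasons.append(
                f"F1 family {i} segregates ({normal} normal : {mutant} mutant); "
                "a recessive trait must be absent from F1"
            )
    bc1_res = chi_square_gof(bc1)
    if not bc1_res.fits:
        reasons.append(
            f"BC1 fails {_ratio_text(bc1)} (chi2={bc1_res.chi_square:.2f} > "
            f"{bc1_res.critical_value_alpha05:.2f})"
        )
    f2_res = chi_square_gof(f2)
    if not f2_res.fits:
        reasons.append(
            f"F2 fails {_ratio_text(f2)} (chi2={f2_res.chi_square:.2f} > "
            f"{f2_res.critical_value_alpha05:.2f})"
        )
    verdict = "monogenic recessive" if not reasons else "not consistent"
    return InheritanceVerdict(verdict=verdict, reasons=reasons, bc1=bc1_res, f2=f2_res)


def _ratio_text(obs: SegregationObservation) -> str:
    return ":".join(f"{r:g}" for r in obs.expected_ratio)
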