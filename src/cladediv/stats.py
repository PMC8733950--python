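"""Two-sample tests on branch-length samples.

The null hypothesis throughout is that the two clades do not diverge
differentially: their within-clade branch lengths are draws from the same
distribution. Three side-by-side tests cover the usual failure modes of
real trees:

* Student's t — equal-variance, normal-theory baseline;
* Welch's t — unequal variances (Welch–Satterthwaite degrees of freedom);
* Mann–Whitney U — no normality assumption at all.

All alternatives are two-sided: which duplicate diverged faster is unknown
a priori. The sign convention is first sample minus second, so a *less*
diverged first clade gives a negative t. The Mann–Whitney statistic
reported is U1 (the first sample's); for small tie-free samples
(n1 + n2 <= 16) the two-sided p-value is exact, computed from the full null
distribution of U; otherwise a normal approximation with midranks, tie
correction and a 0.5 continuity correction is used.

The three tests are reported side by side, deliberately without any
multiple-testing correction: they are alternative views of one comparison,
not independent hypotheses.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import stats as sps

from .errors import DegenerateSampleError, SampleSizeError
from .pruning import BranchLengthSample

__all__ = [
    "TestResult",
    "student_t_test",
    "welch_t_test",
    "mann_whitney_u",
    "run_all_tests",
    "BranchLengthSample",
]

EXACT_U_MAX_N = 16  # complete null distribution has <= C(16,8)=12870 states

TestName = Literal["student_t", "welch_t", "mann_whitney_u"]


class TestResult(BaseModel):
    """Outcome of one two-sample test.

    Either the statistic fields are populated, or ``error`` explains why the
    test was not computable on these samples (e.g. zero variance); the other
    tests in a panel still run.
    """

    name: TestName
    statistic: float | None = None
    df: float | None = None
    p_value: float | None = None
    p_display: str | None = None
    n1: int
    n2: int
    method: Literal["exact", "normal_approx"] | None = None
    error: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "TestResult":
        if self.error is None:
            if self.p_value is None or not (0.0 <= self.p_value <= 1.0):
                raise ValueError(f"p_value out of [0,1]: {self.p_value}")
            if self.name == "mann_whitney_u":
                if not (0.0 <= self.statistic <= self.n1 * self.n2):
                    raise ValueError("U outside [0, n1*n2]")
        return self


def _p_display(p: float) -> str:
    return "< 1e-15" if p < 1e-15 else f"{p:.6g}"


def _values(x: BranchLengthSample | Sequence[float]) -> np.ndarray:
    arr = np.asarray(x.values if isinstance(x, BranchLengthSample) else x, float)
    if arr.ndim != 1 or arr.size < 2:
        raise SampleSizeError(f"need a 1-d sample of size >= 2 (got {arr.size})")
    if not np.all(np.isfinite(arr)):
        raise SampleSizeError("sample contains non-finite values")
    return arr


def student_t_test(
    x: BranchLengthSample | Sequence[float], y: BranchLengthSample | Sequence[float]
) -> TestResult:
    """Equal-variance two-sample t-test, two-sided.

    t = (mean(x) - mean(y)) / sqrt(s_p^2 (1/n1 + 1/n2)) with the pooled
    variance s_p^2 and df = n1 + n2 - 2.
    """
    a, b = _values(x), _values(y)
    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 <= 0:
        raise DegenerateSampleError("pooled variance is zero")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = min(1.0, 2.0 * float(sps.t.sf(abs(t), df)))
    return TestResult(
        name="student_t", statistic=t, df=float(df), p_value=p,
        p_display=_p_display(p), n1=n1, n2=n2,
    )


def welch_t_test(
    x: BranchLengthSample | Sequence[float], y: BranchLengthSample | Sequence[float]
) -> TestResult:
    """Unequal-variance t-test with Welch–Satterthwaite df, two-sided."""
    a, b = _values(x), _values(y)
    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se1, se2 = v1 / n1, v2 / n2
    if se1 + se2 <= 0:
        raise DegenerateSampleError("both sample variances are zero")
    t = (a.mean() - b.mean()) / math.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = min(1.0, 2.0 * float(sps.t.sf(abs(t), df)))
    return TestResult(
        name="welch_t", statistic=t, df=df, p_value=p,
        p_display=_p_display(p), n1=n1, n2=n2,
    )


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Null distribution of U for tie-free samples: counts[u] = number of
    the C(n1+n2, n1) rank assignments giving U = u.

    Classic recurrence f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u): the
    largest rank belongs either to the first sample (contributing n wins)
    or to the second.
    """
    umax = n1 * n2
    # table[m][n] is a list of counts over u
    table: dict[tuple[int, int], list[int]] = {}
    for m in range(n1 + 1):
        for n in range(n2 + 1):
            if m == 0 or n == 0:
                table[(m, n)] = [1]
                continue
            prev_m = table[(m - 1, n)]
            prev_n = table[(m, n - 1)]
            counts = [0] * (m * n + 1)
            for u, c in enumerate(prev_m):
                counts[u + n] += c
            for u, c in enumerate(prev_n):
                counts[u] += c
            table[(m, n)] = counts
    out = table[(n1, n2)]
    assert len(out) == umax + 1
    return tuple(out)


def _exact_u_pvalue(u1: int, n1: int, n2: int) -> float:
    """Exact two-sided p: probability of a U at least as far from the null
    mean n1*n2/2 as the observed one (the null law of U is symmetric)."""
    counts = _u_null_counts(n1, n2)
    center2 = n1 * n2  # 2 * mean
    obs = abs(2 * u1 - center2)
    hits = sum(c for u, c in enumerate(counts) if abs(2 * u - center2) >= obs)
    return min(1.0, hits / math.comb(n1 + n2, n1))


def mann_whitney_u(
    x: BranchLengthSample | Sequence[float], y: BranchLengthSample | Sequence[float]
) -> TestResult:
    """Mann–Whitney U test, two-sided, reporting U1 (first sample).

    Exact p by complete enumeration of the null distribution when
    n1 + n2 <= 16 and there are no ties; otherwise normal approximation with
    midranks, tie correction, and 0.5 continuity correction.
    """
    a, b = _values(x), _values(y)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    r1 = ranks[:n1].sum()
    u1 = float(r1 - n1 * (n1 + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size

    if n1 + n2 <= EXACT_U_MAX_N and not has_ties:
        p = _exact_u_pvalue(round(u1), n1, n2)
        method: Literal["exact", "normal_approx"] = "exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:  # all values identical
            p = 1.0
        else:
            num = u1 - n1 * n2 / 2.0
            # continuity correction pulls |U - mu| toward zero by 0.5
            z = (abs(num) - 0.5) / math.sqrt(sigma2) if num != 0 else 0.0
            z = max(z, 0.0)
            p = min(1.0, 2.0 * float(sps.norm.sf(z)))
        method = "normal_approx"
    return TestResult(
        name="mann_whitney_u", statistic=u1, p_value=p,
        p_display=_p_display(p), n1=n1, n2=n2, method=method,
    )


def run_all_tests(
    x: BranchLengthSample | Sequence[float], y: BranchLengthSample | Sequence[float]
) -> list[TestResult]:
    """Run all three tests; a degenerate-sample failure in one slot is
    recorded there while the others still run."""
    a, b = _values(x), _values(y)
    results: list[TestResult] = []
    for name, fn in (
        ("student_t", student_t_test),
        ("welch_t", welch_t_test),
        ("mann_whitney_u", mann_whitney_u),
    ):
        try:
            results.append(fn(a, b))
        except DegenerateSampleError as exc:
            results.append(
                TestResult(name=name, n1=a.size, n2=b.size, error=str(exc))
            )
    if all(r.error is not None for r in results):
        raise DegenerateSampleError("all three tests degenerate on these samples")
    return results
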