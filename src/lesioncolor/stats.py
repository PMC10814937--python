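"""Cohort descriptive statistics and SPSS-convention Mann–Whitney U tests.

Two-group comparisons of the seven color parameters follow the reporting
conventions of SPSS NPAR TESTS, which clinical studies commonly tabulate:

* midranks for ties;
* U is the smaller of the two U statistics (half-integers possible under
  ties);
* W (the "Wilcoxon W") is the smaller of the two rank sums;
* Z is the tie-corrected normal approximation (U − n1·n2/2)/σ_ties,
  without continuity correction, hence Z ≤ 0;
* asymptotic two-tailed significance 2(1 − Φ(|Z|));
* exact significance is 2 × P(U ≤ observed) under the tie-free exact null
  distribution of U, capped at 1 (SPSS's "Exact Sig. (2*(1-tailed Sig.))"
  for small samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .features import PARAMETER_NAMES, PatientRecord

__all__ = [
    "GroupSummary",
    "MWUResult",
    "group_means",
    "mann_whitney",
    "exact_u_pmf",
    "comparison_table",
    "group_means_frame",
    "comparison_frame",
    "comparison_markdown",
]


@dataclass(frozen=True)
class GroupSummary:
    """Group size and the 7 parameter means of one diagnosis group."""

    diagnosis: str
    n: int
    means: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group must contain at least one record")
        if len(self.means) != len(PARAMETER_NAMES):
            raise ValueError("expected 7 parameter means")


@dataclass(frozen=True)
class MWUResult:
    """One Mann–Whitney U comparison as SPSS reports it.

    ``Z`` is ``nan`` (and flagged via ``degenerate``) when every pooled
    value is identical, where the normal approximation is undefined.
    """

    U: float
    W: float
    Z: float
    p_asymp: float
    p_exact: float
    n1: int
    n2: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not (0.0 <= self.U <= self.n1 * self.n2 / 2 + 1e-9):
                raise ValueError("U outside [0, n1*n2/2]")
            for p in (self.p_asymp, self.p_exact):
                if not (0.0 <= p <= 1.0):
                    raise ValueError("p-values must lie in [0, 1]")


@lru_cache(maxsize=128)
def exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null pmf of the Mann–Whitney U statistic of the first group.

    Dynamic-programming count over the C(n1+n2, n1) equally likely rank
    assignments (no tie adjustment), returned as probabilities over
    U = 0 … n1·n2.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be nonempty")
    max_u = n1 * n2
    counts = np.zeros((n1 + 1, max_u + 1))
    counts[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        for k in range(min(i, n1), 0, -1):
            # taking pooled rank i as the k-th member of group 1 adds
            # (i - k) pairs won over group-2 members ranked below it
            shift = i - k
            if shift <= max_u:
                counts[k, shift:] += counts[k - 1, : max_u + 1 - shift]
    pmf = counts[n1]
    return pmf / pmf.sum()


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MWUResult:
    """Mann–Whitney U test of two independent samples, SPSS conventions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    r2 = float(ranks[n1:].sum())
    u1 = n1 * n2 + n1 * (n1 + 1) / 2 - r1
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    w = min(r1, r2)
    _, tie_counts = np.unique(pooled, return_counts=True)
    if len(tie_counts) == 1:
        return MWUResult(
            U=u, W=w, Z=float("nan"), p_asymp=1.0, p_exact=1.0,
            n1=n1, n2=n2, degenerate=True,
        )
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma = math.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term))
    z = (u - n1 * n2 / 2) / sigma
    p_asymp = float(2 * norm.sf(abs(z)))
    pmf = exact_u_pmf(n1, n2)
    p_one = float(pmf[: int(math.floor(u)) + 1].sum())
    p_exact = min(1.0, 2 * p_one)
    return MWUResult(U=u, W=w, Z=z, p_asymp=p_asymp, p_exact=p_exact, n1=n1, n2=n2)


def _mean2(values: Sequence[float]) -> float:
    # exact double-precision accumulation; printed tables round half-even
    return math.fsum(values) / len(values)


def group_means(records: Sequence[PatientRecord]) -> list[GroupSummary]:
    """Per-diagnosis arithmetic means of the 7 lesion parameters."""
    if not records:
        raise ValueError("no records")
    order: list[str] = []
    groups: dict[str, list[np.ndarray]] = {}
    for rec in records:
        if rec.diagnosis not in groups:
            order.append(rec.diagnosis)
            groups[rec.diagnosis] = []
        groups[rec.diagnosis].append(rec.lesion.as_array())
    out = []
    for dx in order:
        arrs = groups[dx]
        means = tuple(_mean2([a[i] for a in arrs]) for i in range(len(PARAMETER_NAMES)))
        out.append(GroupSummary(diagnosis=dx, n=len(arrs), means=means))
    return out


def _group_values(
    records: Sequence[PatientRecord], diagnosis: str, parameter: str
) -> np.ndarray:
    vals = [rec.parameter(parameter) for rec in records if rec.diagnosis == diagnosis]
    if not vals:
        raise ValueError(f"no records with diagnosis {diagnosis!r}")
    return np.asarray(vals)


def comparison_table(
    records: Sequence[PatientRecord], group_a: str, group_b: str
) -> dict[str, MWUResult]:
    """Mann–Whitney comparisons of the 7 parameters between two groups."""
    return {
        p: mann_whitney(
            _group_values(records, group_a, p), _group_values(records, group_b, p)
        )
        for p in PARAMETER_NAMES
    }


def group_means_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Group-means table: one row per diagnosis, 7 parameter columns."""
    summaries = group_means(records)
    return pd.DataFrame(
        [dict(zip(PARAMETER_NAMES, s.means), diagnosis=s.diagnosis, n=s.n)
         for s in summaries],
        columns=["diagnosis", "n", *PARAMETER_NAMES],
    )


_ROW_LABELS = (
    ("U", "Mann-Whitney U"),
    ("W", "Wilcoxon W"),
    ("Z", "Z"),
    ("p_asymp", "Asymp. Sig. (2-tailed)"),
    ("p_exact", "Exact Sig. (2*(1-tailed Sig.))"),
)


def comparison_frame(results: Mapping[str, MWUResult]) -> pd.DataFrame:
    """Comparison table in the conventional layout: statistic rows,
    parameter columns."""
    data = {
        label: [getattr(results[p], attr) for p in PARAMETER_NAMES]
        for attr, label in _ROW_LABELS
    }
    frame = pd.DataFrame(data, index=list(PARAMETER_NAMES)).T
    frame.index.name = "statistic"
    return frame


def comparison_markdown(results: Mapping[str, MWUResult]) -> str:
    """Markdown rendering of :func:`comparison_frame` (3-decimal rounding
    for Z and significances, as statistical tables conventionally print)."""
    frame = comparison_frame(results)
    rows = ["| statistic | " + " | ".join(PARAMETER_NAMES) + " |",
            "|" + "---|" * (len(PARAMETER_NAMES) + 1)]
    for label, row in frame.iterrows():
        if label in ("Mann-Whitney U", "Wilcoxon W"):
            cells = [f"{v:g}" for v in row]
        else:
            cells = [f"{v:.3f}" for v in row]
        rows.append(f"| {label} | " + " | ".join(cells) + " |")
    return "\n".join(rows) + "\n"
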