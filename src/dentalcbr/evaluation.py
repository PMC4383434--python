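"""Evaluation statistics and report tables.

Contains the exact (small-sample) one-sided Mann-Whitney U test used to
compare prediction methods, the 5x2 cross-validation error table machinery
(five repetitions of a year-stratified half/half split, each half used for
training and testing in turn), leave-one-out mean absolute error, and the
yearly usage / average-duration / failure-rate report generators.

The exact Mann-Whitney null distribution is enumerated combinatorially:
U = #{(i, j) : x_i > y_j} and the one-sided p-value is the probability,
over all C(n_x + n_y, n_x) equally likely rank arrangements, of a U at or
below the observed one.  Small U therefore means "x ranks lower", which is
the alternative of interest when x is an error sample of the method under
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .case_model import AMALGAM, COMPOSITE, Case, CaseBase


class TieError(ValueError):
    """Pooled sample contains ties; the exact rank null does not apply."""

    def __init__(self):
        super().__init__(
            "ties present in the pooled sample; rerun with permutation=True to use "
            "mid-ranks with a Monte-Carlo permutation p-value"
        )


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of rank arrangements of n1 x's among n1+n2 with U == u."""
    max_u = n1 * n2
    # dp[i][u]: ways to have placed i x's with statistic u, scanning ranks upward;
    # assigning rank r to an x adds j = (#y so far) = (r-1) - i ... handled by
    # iterating positions and tracking both counts implicitly.
    dp = np.zeros((n1 + 1, max_u + 1))
    dp[0, 0] = 1.0
    for pos in range(1, n1 + n2 + 1):
        new = np.zeros_like(dp)
        for i in range(min(pos, n1) + 1):
            # position is a y: x count stays i, y count becomes pos - i
            if pos - i <= n2:
                new[i] += dp[i]
            # position is an x: it outranks the j = pos - i y's already placed
            if i >= 1:
                j = pos - i
                if j <= n2:
                    if j == 0:
                        new[i] += dp[i - 1]
                    else:
                        new[i, j:] += dp[i - 1, :-j]
        dp = new
    return dp[n1]


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "x_lower",
    permutation: bool = False,
    n_permutations: int = 20000,
    seed: int = 0,
) -> tuple[float, float]:
    """Exact one-sided Mann-Whitney test that x ranks lower than y.

    Returns ``(U, p)`` with U = #{x_i > y_j} and p = P(U_null <= U_obs)
    from the full enumeration of rank arrangements.  Ties raise
    :class:`TieError` unless ``permutation=True``, which switches to
    mid-rank U and a seeded Monte-Carlo permutation p-value.
    """
    if alternative != "x_lower":
        raise ValueError("only the 'x_lower' alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    # only ties *across* the samples make U ambiguous; ties within one
    # sample leave every x_i > y_j comparison intact
    has_ties = bool(np.isin(x, y).any())

    def u_stat(xs, ys):
        diff = xs[:, None] - ys[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    U = u_stat(x, y)
    if has_ties:
        if not permutation:
            raise TieError()
        rng = np.random.default_rng(seed)
        n1 = len(x)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if u_stat(perm[:n1], perm[n1:]) <= U + 1e-12:
                count += 1
        return U, (count + 1) / (n_permutations + 1)

    counts = _u_null_counts(len(x), len(y))
    total = comb(len(x) + len(y), len(x))
    p = float(counts[: int(U) + 1].sum() / total)
    return U, p


@dataclass
class ErrorTable:
    """Mean absolute longevity error (years) per method and repetition."""

    values: pd.DataFrame  # index = method names, columns = repetitions

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("errors must be nonnegative")

    @property
    def methods(self) -> list[str]:
        return list(self.values.index)


def compare_methods(table: ErrorTable, **mw_kwargs) -> pd.DataFrame:
    """One-sided exact Mann-Whitney p-values for every ordered method pair.

    Entry (row, col) tests the alternative that the row method's errors
    rank lower than the column method's.  The diagonal is NaN.
    """
    methods = table.methods
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    out = pd.DataFrame(np.nan, index=methods, columns=methods)
    for a in methods:
        for b in methods:
            if a == b:
                continue
            _, p = mann_whitney_exact(
                table.values.loc[a].to_numpy(), table.values.loc[b].to_numpy(), **mw_kwargs
            )
            out.loc[a, b] = p
    return out


# ---------------------------------------------------------------------------
# Cross-validation error tables
# ---------------------------------------------------------------------------

#: a method factory consumes a training CaseBase and returns a predictor
#: mapping a probe Case to a longevity estimate in years
MethodFactory = Callable[[CaseBase], Callable[[Case], float]]


def _year_strata(cb: CaseBase) -> dict[int, list[int]]:
    strata: dict[int, list[int]] = {}
    for i, c in enumerate(cb.cases):
        strata.setdefault(c.restoration_year, []).append(i)
    years = sorted(strata)
    merged: dict[int, list[int]] = {}
    pending: list[int] = []
    for y in years:
        idx = pending + strata[y]
        if len(idx) < 2:
            warnings.warn(f"year {y} has fewer than 2 cases; merged into the next year")
            pending = idx
            continue
        merged[y] = idx
        pending = []
    if pending:
        if merged:
            last = max(merged)
            warnings.warn(f"trailing sparse years merged into {last}")
            merged[last] = merged[last] + pending
        else:
            merged[years[0]] = pending
    return merged


def five_by_two_cv(
    cb: CaseBase, method_factories: Mapping[str, MethodFactory], seed: int = 0, repetitions: int = 5
) -> ErrorTable:
    """Year-stratified repeated half-split cross-validation.

    Each repetition draws a random half/half split inside every
    restoration-year stratum; every method is trained on each half and
    tested on the other, and the repetition's value is the mean absolute
    longevity error pooled over both directions.
    """
    rng = np.random.default_rng(seed)
    strata = _year_strata(cb)
    results = {name: [] for name in method_factories}
    for _ in range(repetitions):
        half_a: list[int] = []
        half_b: list[int] = []
        for _, idx in sorted(strata.items()):
            perm = rng.permutation(idx)
            half = len(perm) // 2
            half_a.extend(perm[:half].tolist())
            half_b.extend(perm[half:].tolist())
        for name, factory in method_factories.items():
            abs_errors: list[float] = []
            for train_idx, test_idx in ((half_a, half_b), (half_b, half_a)):
                predictor = factory(cb.subset(train_idx))
                for i in test_idx:
                    case = cb.cases[i]
                    abs_errors.append(abs(predictor(case) - case.restoration_longevity))
            results[name].append(float(np.mean(abs_errors)))
    df = pd.DataFrame(results).T
    df.columns = [f"rep_{r+1}" for r in range(repetitions)]
    return ErrorTable(df)


def leave_one_out_error(
    cb: CaseBase,
    kb_builder: Callable[[CaseBase], "object"],
    type_filter: str | None = None,
    full_retrain: bool = False,
) -> float:
    """Leave-one-out mean absolute error of the retrieval-average estimate.

    By default the knowledge base (clustering and classifier) is built once
    on the full case-base and only the retrieval pool excludes the probe;
    ``full_retrain=True`` rebuilds everything for every fold.
    """
    from .cbr_engine import predict_restoration

    probe_idx = [
        i
        for i, c in enumerate(cb.cases)
        if type_filter is None or c.restoration_type == type_filter
    ]
    if not probe_idx:
        raise ValueError(f"no cases match the type filter {type_filter!r}")

    kb = None if full_retrain else kb_builder(cb)
    abs_errors = []
    for i in probe_idx:
        case = cb.cases[i]
        if full_retrain:
            rest = cb.subset([j for j in range(len(cb)) if j != i])
            kb_i = kb_builder(rest)
            pred = predict_restoration(kb_i, case, with_mixture=False)
        else:
            pred = predict_restoration(kb, case, exclude={i}, with_mixture=False)
        abs_errors.append(abs(pred.average_by_type[case.restoration_type] - case.restoration_longevity))
    return float(np.mean(abs_errors))


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def report_yearly_usage(cb: CaseBase) -> pd.DataFrame:
    """Percentage of composite and amalgam restorations per placement year."""
    df = pd.DataFrame({"year": cb.years(), "type": cb.types()})
    counts = df.pivot_table(index="year", columns="type", aggfunc="size", fill_value=0)
    for t in (COMPOSITE, AMALGAM):
        if t not in counts:
            counts[t] = 0
    pct = counts[[COMPOSITE, AMALGAM]].div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns.name = None
    return pct


def report_average_duration(cb: CaseBase) -> pd.DataFrame:
    """Mean longevity (years) per placement year and restoration type.

    Censored durations (time to the reference date) are included as-is.
    """
    df = pd.DataFrame({"year": cb.years(), "type": cb.types(), "longevity": cb.longevities()})
    out = df.pivot_table(index="year", columns="type", values="longevity", aggfunc="mean")
    out.columns.name = None
    return out[[c for c in (COMPOSITE, AMALGAM) if c in out.columns]]


def report_failure_rates(cb: CaseBase) -> pd.DataFrame:
    """Per-year percentage of restorations counting as failures.

    A restoration is a failure when its longevity is strictly less than
    half the overall mean longevity of its restoration type.
    """
    df = pd.DataFrame({"year": cb.years(), "type": cb.types(), "longevity": cb.longevities()})
    type_mean = df.groupby("type")["longevity"].mean()
    df["failure"] = df["longevity"] < 0.5 * df["type"].map(type_mean)
    out = df.pivot_table(index="year", columns="type", values="failure", aggfunc="mean") * 100.0
    out.columns.name = None
    return out[[c for c in (COMPOSITE, AMALGAM) if c in out.columns]]
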