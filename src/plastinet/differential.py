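"""Differential gene selection with a random-matrix null threshold.

Each gene is tested naive vs plastic with a pooled-variance two-sample
t-test. The significance cutoff is not a multiple-testing correction but an
empirical null: the same test applied to matrices of standard Gaussian
deviates of the same shape and group split, repeated ``n_runs`` times; the
minimum p value of each run brackets how small a p value pure noise can
produce, and the smallest of those minima is taken as the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from plastinet.io import ExpressionMatrix


@dataclass
class DifferentialTable:
    """Per-gene t statistic, two-sided p value and 1-based rank.

    ``table`` is indexed by probe ID with columns ``t``, ``p``, ``rank`` and
    ``zero_variance`` (genes whose pooled variance was zero are flagged and
    given p = 1).
    """

    table: pd.DataFrame
    n_naive: int
    n_plastic: int

    def __post_init__(self) -> None:
        p = self.table["p"].to_numpy()
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p values must lie in (0, 1]")
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("ranks must be a permutation of 1..G")

    def rank_of(self, probe_id: str) -> int:
        return int(self.table.loc[probe_id, "rank"])

    def write(self, path) -> None:
        out = self.table.sort_values("rank")
        out.to_csv(path, sep="\t", index_label="probe_id")


@dataclass
class NullThresholdRecord:
    """Minimum p values from random-matrix null comparisons.

    ``threshold`` is the smallest per-run minimum: the most extreme p value
    that arose from pure noise at the data's shape and group split.
    """

    n_runs: int
    per_run_min_p: list[float]
    threshold: float
    seed: int
    mode: str = "random_split"

    def __post_init__(self) -> None:
        if len(self.per_run_min_p) != self.n_runs:
            raise ValueError("need one minimum per run")
        if self.threshold > min(self.per_run_min_p):
            raise ValueError("threshold must not exceed the smallest minimum")

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "per_run_min_p": list(map(float, self.per_run_min_p)),
            "threshold": float(self.threshold),
            "seed": self.seed,
            "mode": self.mode,
        }


def _pooled_ttest(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pooled-variance two-sample t-test.

    Returns (t, p, zero_variance_flag). Rows with zero pooled variance get
    t = 0, p = 1 and are flagged.
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    zero = sp2 <= 0.0
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (m1 - m2) / np.where(zero, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return t, p, zero


def _assign_ranks(table: pd.DataFrame) -> pd.DataFrame:
    """Rank ascending by p; ties by |t| descending, then probe ID."""
    # mergesort is stable, so pre-sorting the index makes equal (p, |t|)
    # resolve lexicographically by probe ID
    order = table.assign(abs_t=table["t"].abs()).sort_index().sort_values(
        ["p", "abs_t"], ascending=[True, False], kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table = table.copy()
    table["rank"] = ranks
    return table


def ttest_per_gene(expr: ExpressionMatrix) -> DifferentialTable:
    """Pooled-variance two-sided t-test of naive vs plastic for every gene."""
    naive = expr.samples_in("naive")
    plastic = expr.samples_in("plastic")
    if len(naive) < 2 or len(plastic) < 2:
        raise ValueError("need at least 2 samples per group")
    x1 = expr.values[naive].to_numpy(float)
    x2 = expr.values[plastic].to_numpy(float)
    t, p, zero = _pooled_ttest(x1, x2)
    table = pd.DataFrame({"t": t, "p": p, "zero_variance": zero},
                         index=expr.values.index)
    table = _assign_ranks(table)
    return DifferentialTable(table[["t", "p", "rank", "zero_variance"]],
                             len(naive), len(plastic))


def null_threshold(n_genes: int, n_naive: int, n_plastic: int,
                   n_runs: int = 10, seed: int = 0,
                   mode: str = "random_split",
                   data: np.ndarray | None = None) -> NullThresholdRecord:
    """Significance threshold from random-matrix null comparisons.

    ``random_split`` (default): each run draws a ``n_genes x (n_naive +
    n_plastic)`` matrix of standard Gaussian deviates, splits it into the
    study's group sizes and records the minimum t-test p value.

    ``data_vs_random``: each run tests every gene of ``data`` (all samples
    pooled as one group) against a freshly drawn Gaussian row of the same
    length — the literal experimental-versus-random comparison. Its minima
    are not null-distributed whenever the data carry signal, which is why it
    is not the default.
    """
    if n_genes < 1 or n_runs < 1:
        raise ValueError("n_genes and n_runs must be >= 1")
    if mode not in ("random_split", "data_vs_random"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "data_vs_random" and data is None:
        raise ValueError("data_vs_random mode requires a data matrix")
    minima: list[float] = []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        if mode == "random_split":
            mat = rng.standard_normal((n_genes, n_naive + n_plastic))
            _, p, _ = _pooled_ttest(mat[:, :n_naive], mat[:, n_naive:])
        else:
            rand = rng.standard_normal(data.shape)
            _, p, _ = _pooled_ttest(np.asarray(data, float), rand)
        minima.append(float(p.min()))
    return NullThresholdRecord(n_runs=n_runs, per_run_min_p=minima,
                               threshold=min(minima), seed=seed, mode=mode)


def select_top(table: DifferentialTable, k: int = 500,
               threshold: float = 1.0) -> list[str]:
    """The ``k`` lowest-p genes with p strictly below ``threshold``.

    Returned in rank order. If fewer than ``k`` genes pass the threshold,
    all passing genes are returned and a warning is issued.
    """
    if k > len(table.table):
        raise ValueError("k exceeds the number of genes")
    ordered = table.table.sort_values("rank")
    passing = ordered[ordered["p"] < threshold]
    if len(passing) < k:
        warnings.warn(
            f"only {len(passing)} genes pass p < {threshold:g} "
            f"(requested {k})", stacklevel=2)
        return list(passing.index)
    return list(passing.index[:k])
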