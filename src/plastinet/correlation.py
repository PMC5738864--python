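"""Pearson co-expression network at a fixed correlation cutoff.

The marginal-correlation counterpart of the graphical-lasso network: an
edge wherever the pairwise Pearson coefficient across all pooled samples
exceeds the cutoff. Marginal correlation conflates direct and indirect
dependencies, which is precisely the contrast the partial-correlation
(glasso) network is meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from plastinet.io import ExpressionMatrix, GeneAnnotation
from plastinet.network import GeneNetwork, network_from_edges


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson coefficients over selected genes.

    Rows/columns of zero-variance genes are NaN and flagged in ``degenerate``;
    they never produce edges.
    """

    r: np.ndarray
    gene_ids: list[str]
    n_samples: int
    degenerate: list[str]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, float)
        if r.shape[0] != r.shape[1] or r.shape[0] != len(self.gene_ids):
            raise ValueError("r must be square and match gene_ids")
        finite = np.isfinite(r)
        if not np.allclose(r[finite], np.clip(r[finite], -1.0, 1.0)):
            raise ValueError("correlations must lie in [-1, 1]")
        self.r = r


def pearson_matrix(expr: ExpressionMatrix,
                   genes: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson r across all pooled samples for the given genes."""
    if genes is None:
        genes = expr.gene_ids
    sub = expr.subset(list(genes))
    if sub.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    x = sub.values.to_numpy(float)
    sd = x.std(axis=1, ddof=1)
    degenerate = [g for g, s in zip(genes, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    r = np.clip(r, -1.0, 1.0)
    bad = sd == 0.0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    return CorrelationMatrix(r, list(genes), sub.n_samples, degenerate)


def correlation_edges(rmat: CorrelationMatrix, cutoff: float = 0.95,
                      annotation: GeneAnnotation | None = None,
                      absolute: bool = False,
                      p_cutoff: float | None = None) -> GeneNetwork:
    """Edges wherever r (or |r| with ``absolute``) strictly exceeds cutoff.

    With ``p_cutoff`` each candidate edge must additionally pass a two-sided
    test of zero correlation at that level (used for significance-annotated
    variants of the network). Degenerate (zero-variance) genes never form
    edges; symmetric duplicates collapse; method tag is ``"pearson"``.
    """
    r = rmat.r
    ids = rmat.gene_ids
    n = rmat.n_samples
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            val = r[i, j]
            if not np.isfinite(val):
                continue
            stat = abs(val) if absolute else val
            if stat > cutoff:
                if p_cutoff is not None and _corr_pvalue(val, n) >= p_cutoff:
                    continue
                edges.append((ids[i], ids[j], float(val)))
    provenance = {"cutoff": cutoff, "absolute": absolute,
                  "p_cutoff": p_cutoff}
    return network_from_edges(edges, method="pearson", annotation=annotation,
                              provenance=provenance)


def _corr_pvalue(r: float, n: int) -> float:
    """Two-sided p value for Pearson r under the null of no correlation."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))
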