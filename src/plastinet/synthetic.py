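"""Synthetic two-state expression data with a planted dependency structure.

The generator emulates the statistical design the downstream analysis
assumes: two sample groups (naive vs plastic), a subset of regulated genes
whose plastic-group mean is shifted, and — among the regulated genes — a
sparse Gaussian graphical dependency structure with a designated hub, so
that differential selection, network reconstruction and hub ranking can all
be validated against known truth.

Model
-----
Unregulated genes are independent ``N(0, noise_sd^2)``. The planted subgraph
genes are drawn from a zero-mean multivariate Gaussian whose precision
matrix is the identity plus ``+/- partial_corr_strength`` on planted edges
(sign alternating along the edge list); if any row's off-diagonal absolute
sum exceeds 0.9, all off-diagonals are rescaled so the largest row sum is
0.9, keeping the matrix strictly diagonally dominant, hence positive
definite. Because the diagonal stays at one, the realised off-diagonal
entries are (up to sign) the planted partial correlations; note that a
high-degree hub therefore caps how strong each of its edges can be.
Regulated genes receive ``effect_size * noise_sd`` added to the
plastic-group mean, and the whole matrix is multiplied by ``base_scale`` to
emulate raw-intensity units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from plastinet.io import ExpressionMatrix, write_expression

#: row off-diagonal absolute sum allowed before the diagonal is inflated
_DOMINANCE_BUDGET = 0.9


def star_adjacency(n_partners: int) -> np.ndarray:
    """Adjacency of a hub with ``n_partners`` leaves; node 0 is the hub."""
    m = n_partners + 1
    adj = np.zeros((m, m), dtype=int)
    adj[0, 1:] = adj[1:, 0] = 1
    return adj


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic two-state expression experiment.

    Defaults mirror the study design the analysis targets: 9 naive and 20
    plastic arrays, ~2.5% of genes regulated with a standardized mean shift
    of 2, and a 10-partner hub planted among the regulated genes.
    """

    n_genes: int = 2000
    n_naive: int = 9
    n_plastic: int = 20
    regulated_fraction: float = 0.025
    effect_size: float = 2.0
    planted_adjacency: np.ndarray = field(
        default_factory=lambda: star_adjacency(10))
    partial_corr_strength: float = 0.3
    noise_sd: float = 1.0
    base_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        adj = np.asarray(self.planted_adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("planted_adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("planted_adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("planted_adjacency must have zero diagonal")
        if self.n_naive + self.n_plastic < 4:
            raise ValueError("need at least 4 samples in total")
        if not 0.0 <= self.regulated_fraction <= 1.0:
            raise ValueError("regulated_fraction must be in [0, 1]")
        if self.n_regulated < adj.shape[0]:
            raise ValueError(
                "regulated_fraction must cover the planted subgraph "
                f"({adj.shape[0]} genes)")
        self.planted_adjacency = adj.astype(int)

    @property
    def n_regulated(self) -> int:
        return int(round(self.regulated_fraction * self.n_genes))

    @property
    def n_samples(self) -> int:
        return self.n_naive + self.n_plastic


@dataclass
class SyntheticDataset:
    """Generated expression plus the planted ground truth."""

    expression: ExpressionMatrix
    adjacency_edges: list[tuple[str, str]]
    hub_id: str | None
    regulated_ids: list[str]
    precision: np.ndarray  # planted precision over planted_gene_ids
    planted_gene_ids: list[str]

    def __post_init__(self) -> None:
        genes = set(self.expression.gene_ids)
        for gid in self.regulated_ids:
            if gid not in genes:
                raise ValueError(f"truth gene {gid!r} not in expression")

    def write(self, expr_path: str | Path, truth_path: str | Path) -> None:
        """Write expression as TSV and truth as JSON."""
        write_expression(self.expression, expr_path)
        truth = {
            "adjacency_edges": [list(e) for e in self.adjacency_edges],
            "hub_id": self.hub_id,
            "regulated_ids": list(self.regulated_ids),
            "planted_gene_ids": list(self.planted_gene_ids),
        }
        Path(truth_path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def planted_precision(spec: SyntheticSpec) -> np.ndarray:
    """Precision matrix over the planted subgraph genes.

    Starts from the identity, puts ``+/- partial_corr_strength`` on planted
    edges with the sign alternating by edge index, then — if any row's
    off-diagonal absolute sum exceeds 0.9 — rescales all off-diagonals by a
    common factor so the largest row sum equals 0.9. Every row is then
    strictly diagonally dominant, a simple always-valid guarantee of
    positive definiteness.
    """
    adj = spec.planted_adjacency
    m = adj.shape[0]
    prec = np.eye(m)
    if m == 0:
        return prec
    edges = [(i, j) for i in range(m) for j in range(i + 1, m) if adj[i, j]]
    s = spec.partial_corr_strength
    for k, (i, j) in enumerate(edges):
        val = s if k % 2 == 0 else -s
        prec[i, j] = prec[j, i] = val
    row_off = np.sum(np.abs(prec), axis=1) - np.abs(np.diag(prec))
    worst = row_off.max()
    if worst > _DOMINANCE_BUDGET:
        off = prec - np.eye(m)
        prec = np.eye(m) + off * (_DOMINANCE_BUDGET / worst)
    try:
        np.linalg.cholesky(prec)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - dominance holds
        raise ValueError("planted precision is not positive definite") from exc
    return prec


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"g{i:0{width}d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a dataset from the spec. Identical spec -> identical dataset."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_genes
    genes = _gene_ids(p)

    # placement of regulated genes and of the planted subgraph within them
    regulated_idx = np.sort(rng.choice(p, size=spec.n_regulated, replace=False))
    m = spec.planted_adjacency.shape[0]
    placement = rng.permutation(spec.n_regulated)[:m]
    planted_idx = regulated_idx[placement]  # planted node k -> gene index

    # latent draws: iid normals everywhere, multivariate on the planted block
    latent = rng.standard_normal((p, n))
    prec = planted_precision(spec)
    if m > 0:
        cov = np.linalg.inv(prec)
        chol = np.linalg.cholesky(cov)
        latent[planted_idx, :] = chol @ rng.standard_normal((m, n))

    values = spec.noise_sd * latent
    values[regulated_idx, spec.n_naive:] += spec.effect_size * spec.noise_sd
    values *= spec.base_scale

    sample_ids = ([f"naive{i + 1:02d}" for i in range(spec.n_naive)]
                  + [f"plastic{i + 1:02d}" for i in range(spec.n_plastic)])
    groups = pd.Series(["naive"] * spec.n_naive + ["plastic"] * spec.n_plastic,
                       index=sample_ids)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids), groups, "raw")

    adj = spec.planted_adjacency
    edges = [(genes[planted_idx[i]], genes[planted_idx[j]])
             for i in range(m) for j in range(i + 1, m) if adj[i, j]]
    hub_id = None
    if m > 0:
        hub_node = int(np.argmax(adj.sum(axis=1)))
        hub_id = genes[planted_idx[hub_node]]
    return SyntheticDataset(
        expression=expr,
        adjacency_edges=edges,
        hub_id=hub_id,
        regulated_ids=[genes[i] for i in regulated_idx],
        precision=prec,
        planted_gene_ids=[genes[i] for i in planted_idx],
    )
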