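"""Frobenius-norm comparison of gene-gene correlation structure.

Two expression datasets over a shared gene list are compared by the
Frobenius norm of the difference of their gene-gene Pearson correlation
matrices. The null permutes gene identities of one dataset, which preserves
the multiset of pairwise correlations while scrambling which pair carries
which value; P is the fraction of permuted distances strictly smaller than
the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .matrices import ExpressionMatrix


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    gene_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.gene_ids) != n:
            raise ValueError("correlation matrix must be square over the gene list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.values)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class DistanceResult:
    observed: float
    n_perm: int
    null: np.ndarray
    p: float
    p_floor: Optional[float] = None


def correlation_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson gene-gene correlations over samples; zero-variance genes dropped."""
    sd = expr.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        import logging

        logging.getLogger(__name__).warning(
            "correlation_matrix: excluded %d zero-variance genes", len(dropped)
        )
    vals = np.corrcoef(expr.values[keep])
    vals = np.clip(vals, -1.0, 1.0)
    return CorrelationMatrix(
        values=np.atleast_2d(vals),
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
    )


def frobenius_distance(a: CorrelationMatrix, b: CorrelationMatrix) -> float:
    """sqrt of the summed squared entries of A - B (gene lists must match)."""
    if a.gene_ids != b.gene_ids:
        diff = set(a.gene_ids) ^ set(b.gene_ids)
        raise ValueError(
            f"gene lists differ (symmetric difference of {len(diff)}): "
            f"{sorted(diff)[:5]}"
        )
    return float(np.linalg.norm(a.values - b.values, ord="fro"))


def permutation_distance_test(
    expr: ExpressionMatrix,
    reference: CorrelationMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    squared: bool = False,
) -> DistanceResult:
    """Permutation test of correlation-structure distance to a reference.

    Each permutation relabels the genes of ``expr`` (a symmetric row/column
    permutation of its correlation matrix — pairwise correlations are
    preserved) and recomputes the distance to ``reference``. P is the
    fraction of permuted distances strictly below the observed distance.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    obs_corr = correlation_matrix(expr)
    if obs_corr.gene_ids != reference.gene_ids:
        diff = set(obs_corr.gene_ids) ^ set(reference.gene_ids)
        raise ValueError(f"gene lists differ: {sorted(diff)[:5]}")
    observed = frobenius_distance(obs_corr, reference)
    rng = np.random.default_rng(seed)
    c = obs_corr.values
    r = reference.values
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(c.shape[0])
        d2 = np.sum((c[np.ix_(perm, perm)] - r) ** 2)
        null[t] = d2 if squared else np.sqrt(d2)
    obs_stat = observed**2 if squared else observed
    less = int(np.sum(null < obs_stat))
    return DistanceResult(
        observed=observed,
        n_perm=n_perm,
        null=null,
        p=less / n_perm,
        p_floor=(1.0 / n_perm if less == 0 else None),
    )
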