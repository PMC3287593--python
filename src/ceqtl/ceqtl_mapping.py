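"""Dosage-model fitting, pooled permutation nulls and cis/trans FDR.

For each gene-marker pair the expression log-ratio y is regressed on the
dosage log-ratio x (y = mu + alpha * x) and compared to the intercept-only
model with an F statistic (1 numerator df). Significance is calibrated
against an empirical null built by permuting clone labels of each expression
vector several times and pooling the resulting F statistics across all
evaluated pairs; the marker correlation structure is untouched by the
permutation. Benjamini-Hochberg FDR is applied separately within the cis
and trans record sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrices import DosageMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

CIS_RADIUS = 5_000_000
_VAR_TOL = 1e-14


@dataclass
class LinearFit:
    """OLS fit of y = mu + alpha * x with the F test vs y = mu."""

    mu: float
    alpha: float
    F: float
    n: int


@dataclass
class NullDistribution:
    """Pooled permutation F statistics (sorted ascending)."""

    values: np.ndarray
    n_perm: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float).ravel())
        if self.values.size and self.values[0] < 0:
            raise ValueError("null F statistics must be nonnegative")

    @property
    def count(self) -> int:
        return int(self.values.size)


def fit_dosage_model(y: Sequence[float], x: Sequence[float]) -> LinearFit:
    """Fit one gene-marker pair by ordinary least squares.

    Missing values (NaN) are dropped pairwise. A perfect fit yields
    ``F = inf``; a constant y with zero residual both ways yields ``F = 0``.
    A constant regressor raises ``ValueError``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    n = y.size
    if n < 3:
        raise ValueError(f"need >= 3 complete observations, got {n}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx < _VAR_TOL:
        raise ValueError("degenerate regressor: x is constant")
    yc = y - y.mean()
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    alpha = sxy / sxx
    rss_full = syy - alpha * sxy
    mu = float(y.mean() - alpha * x.mean())
    F = _f_statistic(syy, rss_full, n)
    return LinearFit(mu=mu, alpha=float(alpha), F=F, n=n)


def _f_statistic(rss_reduced: float, rss_full: float, n: int) -> float:
    if rss_full <= _VAR_TOL * max(1.0, rss_reduced):
        return 0.0 if rss_reduced <= _VAR_TOL else math.inf
    return (rss_reduced - rss_full) / (rss_full / (n - 2))


def _fit_many(y: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized alpha and F of one expression vector against marker rows.

    ``X`` is markers x clones. Rows with (numerically) constant x get
    ``alpha = F = nan``.
    """
    n = y.size
    yc = y - y.mean()
    syy = float(yc @ yc)
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    sxy = Xc @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = sxy / sxx
        rss_full = syy - alpha * sxy
        F = (syy - rss_full) * (n - 2) / rss_full
    bad = sxx < _VAR_TOL
    perfect = (rss_full <= _VAR_TOL * max(1.0, syy)) & ~bad
    F[perfect] = 0.0 if syy <= _VAR_TOL else np.inf
    alpha[bad] = np.nan
    F[bad] = np.nan
    np.maximum(F, 0.0, out=F, where=~np.isnan(F))
    return alpha, F


def count_pairs(n_genes: int, n_markers: int) -> int:
    """Size of the full gene x marker cross-product."""
    return int(n_genes) * int(n_markers)


def gene_marker_distance(
    gene_start: int, gene_end: int, marker_pos: int
) -> float:
    """Gap (bp) between a marker and a gene interval; 0 if inside."""
    if gene_start <= marker_pos < gene_end:
        return 0.0
    if marker_pos < gene_start:
        return float(gene_start - marker_pos)
    return float(marker_pos - (gene_end - 1))


def classify_pair(
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    marker_chrom: str,
    marker_pos: int,
    radius: int = CIS_RADIUS,
) -> Tuple[str, float]:
    """Return ``(class, distance)``; cis iff same chromosome and gap <= radius."""
    if gene_chrom != marker_chrom:
        return "trans", math.inf
    d = gene_marker_distance(gene_start, gene_end, marker_pos)
    return ("cis" if d <= radius else "trans"), d


def enumerate_pairs(
    expr: ExpressionMatrix,
    dosage: DosageMatrix,
    cis_radius: int = CIS_RADIUS,
    trans_stride: Optional[int] = None,
    full: bool = False,
) -> List[np.ndarray]:
    """Marker row indices evaluated per gene.

    ``full=True`` evaluates every marker for every gene. Otherwise each gene
    gets all same-chromosome markers within ``cis_radius`` plus, when
    ``trans_stride`` is set, every stride-th marker genome-wide.
    """
    n_markers = dosage.n_markers
    out: List[np.ndarray] = []
    chrom_rows = {c: rows for c, rows in dosage.chromosome_slices()}
    strided = np.arange(0, n_markers, trans_stride) if trans_stride else None
    for i in range(expr.n_genes):
        if full:
            out.append(np.arange(n_markers))
            continue
        rows = chrom_rows.get(str(expr.chrom[i]), np.empty(0, dtype=int))
        if rows.size:
            pos = dosage.position[rows]
            near = (pos >= expr.start[i] - cis_radius) & (pos < expr.end[i] + cis_radius)
            cis = rows[near]
        else:
            cis = np.empty(0, dtype=int)
        if strided is not None:
            out.append(np.union1d(cis, strided))
        else:
            out.append(cis)
    return out


def build_null(
    expr: ExpressionMatrix,
    dosage: DosageMatrix,
    pairs: Optional[List[np.ndarray]] = None,
    n_perm: int = 5,
    seed: int = 0,
    per_gene: bool = False,
) -> NullDistribution | Dict[str, NullDistribution]:
    """Permutation null: shuffle each expression vector's clone labels and
    refit every evaluated pair, ``n_perm`` times, pooling all F statistics.

    ``per_gene=True`` returns one pooled null per gene instead (for
    heteroscedasticity sensitivity checks).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if pairs is None:
        pairs = enumerate_pairs(expr, dosage, full=True)
    rng = np.random.default_rng(seed)
    n = expr.n_clones
    pooled: List[np.ndarray] = []
    gene_nulls: Dict[str, NullDistribution] = {}
    for i, rows in enumerate(pairs):
        if rows.size == 0:
            continue
        X = dosage.values[rows]
        gene_fs: List[np.ndarray] = []
        for _ in range(n_perm):
            yp = expr.values[i, rng.permutation(n)]
            _, F = _fit_many(yp, X)
            gene_fs.append(F[~np.isnan(F)])
        if per_gene:
            gene_nulls[expr.gene_ids[i]] = NullDistribution(
                np.concatenate(gene_fs), n_perm=n_perm, seed=seed
            )
        else:
            pooled.extend(gene_fs)
    if per_gene:
        return gene_nulls
    if not pooled:
        raise ValueError("no pairs evaluated; null is empty")
    return NullDistribution(np.concatenate(pooled), n_perm=n_perm, seed=seed)


def empirical_p(F_obs: float, null: NullDistribution) -> Tuple[float, Optional[float]]:
    """P = fraction of null values strictly greater than the observed F.

    Returns ``(p, floor)`` where ``floor = 1 / count`` is attached when the
    count of exceeding null values is zero (P reported as 0).
    """
    if null.count == 0:
        raise ValueError("empty null distribution")
    if math.isinf(F_obs):
        greater = 0
    else:
        greater = null.count - int(np.searchsorted(null.values, F_obs, side="right"))
    p = greater / null.count
    return p, (1.0 / null.count if greater == 0 else None)


def fdr_by_class(records: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg q-values computed independently per cis/trans class."""
    records = records.copy()
    records["q"] = np.nan
    for cls in records["class"].unique():
        idx = records.index[records["class"] == cls]
        records.loc[idx, "q"] = bh_qvalues(records.loc[idx, "p"].to_numpy())
    return records


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def summarize_records(records: pd.DataFrame) -> Dict[str, float]:
    """Headline counts of a record table: class sizes and sign fractions."""
    cis = records[records["class"] == "cis"]
    trans = records[records["class"] == "trans"]
    n_cis_neg = int((cis["alpha"] < 0).sum())
    out: Dict[str, float] = {
        "n_records": int(len(records)),
        "n_cis": int(len(cis)),
        "n_trans": int(len(trans)),
        "n_cis_negative": n_cis_neg,
        "negative_cis_fraction": n_cis_neg / len(cis) if len(cis) else float("nan"),
    }
    out["negative_cis_percent"] = (
        round(100.0 * out["negative_cis_fraction"]) if len(cis) else float("nan")
    )
    return out


def filter_variable_markers(
    dosage: DosageMatrix,
    gain_threshold: float = math.log10(3.0 / 2.0),
    loss_threshold: float = math.log10(1.0 / 2.0),
) -> DosageMatrix:
    """Keep markers showing a copy-number change in at least one sample.

    Thresholds default to a 3/2 gain and 1/2 loss expressed in log10 (the
    units of the matrices here); pass log2 values for log2 data.
    """
    keep = np.any(
        (dosage.values > gain_threshold) | (dosage.values < loss_threshold), axis=1
    )
    if not keep.any():
        logger.warning("filter_variable_markers: no marker passed; output is empty")
    return DosageMatrix(
        values=dosage.values[keep],
        marker_ids=[m for m, k in zip(dosage.marker_ids, keep) if k],
        chrom=dosage.chrom[keep],
        position=dosage.position[keep],
        chrom_class=dosage.chrom_class[keep],
        clone_ids=list(dosage.clone_ids),
        state=dosage.state,
    )


@dataclass
class Peak:
    chrom: str
    index: int  # index into the per-chromosome profile
    position: int
    height: float
    support_start: int  # bp of outermost markers within support_drop
    support_end: int


def find_peaks(
    position: np.ndarray,
    neglog10p: np.ndarray,
    chrom: Optional[np.ndarray] = None,
    support_drop: float = 2.0,
) -> List[Peak]:
    """Distinct peaks of a -log10 P profile along marker positions.

    Two local maxima are separate peaks only when the profile drops by at
    least ``support_drop`` below the lower summit between them. Each peak
    carries its support interval: the outermost contiguous markers within
    ``support_drop`` of the summit.
    """
    position = np.asarray(position)
    neglog10p = np.asarray(neglog10p, dtype=float)
    if chrom is None:
        chrom = np.array(["_"] * len(position))
    peaks: List[Peak] = []
    for c in dict.fromkeys(chrom.tolist()):
        rows = np.flatnonzero(chrom == c)
        order = np.argsort(position[rows], kind="stable")
        pos = position[rows][order]
        v = neglog10p[rows][order]
        peaks.extend(_peaks_one_chrom(str(c), pos, v, support_drop))
    return peaks


def _peaks_one_chrom(
    c: str, pos: np.ndarray, v: np.ndarray, drop: float
) -> List[Peak]:
    n = len(v)
    if n == 0:
        return []
    cand = [
        i
        for i in range(n)
        if (i == 0 or v[i] >= v[i - 1]) and (i == n - 1 or v[i] > v[i + 1])
        or (i == n - 1 and v[i] >= v[i - 1])
    ]
    if not cand:
        cand = [int(np.argmax(v))]
    cand.sort(key=lambda i: -v[i])
    accepted: List[int] = []
    for i in cand:
        ok = True
        for j in accepted:
            lo, hi = min(i, j), max(i, j)
            valley = v[lo : hi + 1].min()
            if valley > min(v[i], v[j]) - drop:
                ok = False
                break
        if ok:
            accepted.append(i)
    accepted.sort()
    out = []
    for i in accepted:
        lo = i
        while lo > 0 and v[lo - 1] >= v[i] - drop and v[lo - 1] <= v[lo]:
            lo -= 1
        hi = i
        while hi < n - 1 and v[hi + 1] >= v[i] - drop and v[hi + 1] <= v[hi]:
            hi += 1
        out.append(
            Peak(
                chrom=c,
                index=int(i),
                position=int(pos[i]),
                height=float(v[i]),
                support_start=int(pos[lo]),
                support_end=int(pos[hi]),
            )
        )
    return out


def map_ceqtls(
    expr: ExpressionMatrix,
    dosage: DosageMatrix,
    n_perm: int = 5,
    seed: int = 0,
    cis_radius: int = CIS_RADIUS,
    trans_stride: Optional[int] = None,
    full: bool = False,
) -> Tuple[pd.DataFrame, NullDistribution]:
    """Run the full mapping stage: fits, pooled null, empirical P, class FDR.

    Returns a record table (one row per evaluated gene-marker pair) and the
    pooled null. Pairs with a constant regressor are skipped and counted in
    the log.
    """
    pairs = enumerate_pairs(expr, dosage, cis_radius=cis_radius,
                            trans_stride=trans_stride, full=full)
    null = build_null(expr, dosage, pairs=pairs, n_perm=n_perm, seed=seed)
    rows_out: List[dict] = []
    n_skipped = 0
    for i, rows in enumerate(pairs):
        if rows.size == 0:
            continue
        alpha, F = _fit_many(expr.values[i], dosage.values[rows])
        valid = ~np.isnan(F)
        n_skipped += int((~valid).sum())
        for r, a, f in zip(rows[valid], alpha[valid], F[valid]):
            p, floor = empirical_p(float(f), null)
            cls, dist = classify_pair(
                str(expr.chrom[i]), int(expr.start[i]), int(expr.end[i]),
                str(dosage.chrom[r]), int(dosage.position[r]), radius=cis_radius,
            )
            rows_out.append(
                {
                    "gene": expr.gene_ids[i],
                    "marker": dosage.marker_ids[r],
                    "gene_chrom": expr.chrom[i],
                    "gene_start": int(expr.start[i]),
                    "gene_end": int(expr.end[i]),
                    "marker_chrom": dosage.chrom[r],
                    "marker_pos": int(dosage.position[r]),
                    "alpha": float(a),
                    "F": float(f),
                    "p": p,
                    "p_floor": floor if floor is not None else np.nan,
                    "class": cls,
                    "distance": dist,
                }
            )
    if n_skipped:
        logger.info("skipped %d pairs with constant regressor", n_skipped)
    records = pd.DataFrame(rows_out)
    if len(records):
        records = fdr_by_class(records)
    return records, null
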