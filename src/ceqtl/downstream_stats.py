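"""Hotspots, noncoding blocks, cross-dataset concordance and X attenuation."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .ceqtl_mapping import bh_qvalues
from .cgh_processing import AUTOSOME_TARGET, SEX_TARGET
from .genome import SEX, GeneRecord
from .matrices import DosageMatrix

logger = logging.getLogger(__name__)


@dataclass
class HotspotResult:
    unit: str
    count: int
    lam: float
    p: float
    q: float = float("nan")


@dataclass
class NoncodingBlock:
    chrom: str
    start: int
    end: int
    members: List[Tuple[str, int]] = field(default_factory=list)  # (peak id, pos)
    best_neglog10p: float = float("nan")
    partner: Optional[str] = None

    @property
    def block_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ConcordanceTable:
    table: np.ndarray  # [[++, +-], [-+, --]]
    chi2: float
    df: int
    p: float
    n_zero_excluded: int

    @property
    def n(self) -> int:
        return int(self.table.sum())


def poisson_tail(count: int, lam: float) -> float:
    """Pr(X > count) for X ~ Poisson(lam)."""
    return float(stats.poisson.sf(count, lam))


def hotspot_fdr(
    trans_records: pd.DataFrame,
    direction: str = "per-marker",
    include_zero_units: bool = False,
    all_units: Optional[Sequence[str]] = None,
) -> List[HotspotResult]:
    """Poisson tail test for units regulating (or regulated by) many genes.

    ``direction='per-marker'`` counts distinct genes per marker;
    ``'per-gene'`` counts distinct markers per gene. The Poisson mean is the
    average count over units; by default only units with at least one trans
    record enter the mean (pass ``all_units`` plus ``include_zero_units=True``
    to average over a fixed universe including zero-count units).
    """
    if trans_records is None or len(trans_records) == 0:
        raise ValueError("empty trans record set")
    if direction == "per-marker":
        counts = trans_records.groupby("marker")["gene"].nunique()
    elif direction == "per-gene":
        counts = trans_records.groupby("gene")["marker"].nunique()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    counts = counts.to_dict()
    if include_zero_units:
        if all_units is None:
            raise ValueError("include_zero_units requires all_units")
        counts = {u: counts.get(u, 0) for u in all_units}
    lam = float(np.mean(list(counts.values())))
    results = [
        HotspotResult(unit=u, count=int(c), lam=lam, p=poisson_tail(int(c), lam))
        for u, c in counts.items()
    ]
    q = bh_qvalues(np.array([r.p for r in results]))
    for r, qv in zip(results, q):
        r.q = float(qv)
    return results


def _interval_distance(pos: int, start: int, end: int) -> int:
    """Gap (bp) from a point to a half-open interval; 0 if inside."""
    if start <= pos < end:
        return 0
    return start - pos if pos < start else pos - (end - 1)


def define_noncoding(
    peaks: Sequence[Tuple[str, str, int]],
    annotation: Sequence[Tuple[str, int, int]],
    exclusion: int = 300_000,
) -> List[Tuple[str, str, int]]:
    """Keep peaks farther than ``exclusion`` bp from every annotated interval.

    ``peaks`` are ``(peak_id, chrom, position)``; ``annotation`` holds
    ``(chrom, start, end)`` gene/microRNA intervals. A peak on a chromosome
    with no annotation is retained (infinite distance).
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for c, s, e in annotation:
        by_chrom.setdefault(str(c), []).append((int(s), int(e)))
    out = []
    for pid, c, pos in peaks:
        iv = by_chrom.get(str(c), [])
        d = min((_interval_distance(int(pos), s, e) for s, e in iv), default=math.inf)
        if d > exclusion:
            out.append((pid, c, int(pos)))
    return out


def merge_blocks(
    peaks: Sequence[Tuple[str, str, int]],
    merge_distance: int = 300_000,
    scores: Optional[Dict[str, float]] = None,
) -> List[NoncodingBlock]:
    """Single-linkage chaining of peaks within ``merge_distance`` per chromosome."""
    blocks: List[NoncodingBlock] = []
    by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for pid, c, pos in peaks:
        by_chrom.setdefault(str(c), []).append((int(pos), pid))
    for c in sorted(by_chrom):
        items = sorted(by_chrom[c])
        run: List[Tuple[int, str]] = []
        for pos, pid in items:
            if run and pos - run[-1][0] > merge_distance:
                blocks.append(_finish_block(c, run, scores))
                run = []
            run.append((pos, pid))
        if run:
            blocks.append(_finish_block(c, run, scores))
    return blocks


def _finish_block(
    c: str, run: List[Tuple[int, str]], scores: Optional[Dict[str, float]]
) -> NoncodingBlock:
    best = float("nan")
    if scores:
        vals = [scores[pid] for _, pid in run if pid in scores]
        if vals:
            best = max(vals)
    return NoncodingBlock(
        chrom=c,
        start=run[0][0],
        end=run[-1][0] + 1,
        members=[(pid, pos) for pos, pid in run],
        best_neglog10p=best,
    )


def _overlap(a: NoncodingBlock, b: NoncodingBlock) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _gap(a: NoncodingBlock, b: NoncodingBlock) -> int:
    if _overlap(a, b) > 0:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def match_blocks_one_to_one(
    blocks_a: Sequence[NoncodingBlock],
    blocks_b: Sequence[NoncodingBlock],
    universe: int,
) -> Dict[str, object]:
    """Greedy one-to-one matching of two block sets in shared coordinates.

    Candidate pairs on the same chromosome are ranked by overlap length
    (descending), ties broken by boundary gap (ascending); each block is used
    at most once. Joint presence over a ``universe`` of candidate blocks is
    tested with an uncorrected 2x2 chi-square.
    """
    cand = []
    for i, a in enumerate(blocks_a):
        for j, b in enumerate(blocks_b):
            if a.chrom != b.chrom:
                continue
            cand.append((-_overlap(a, b), _gap(a, b), i, j))
    cand.sort()
    used_a: set = set()
    used_b: set = set()
    matches: List[Tuple[NoncodingBlock, NoncodingBlock]] = []
    for neg_ov, gap, i, j in cand:
        if neg_ov == 0 and gap > 0:
            continue  # require actual overlap
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        blocks_a[i].partner = blocks_b[j].block_id
        blocks_b[j].partner = blocks_a[i].block_id
        matches.append((blocks_a[i], blocks_b[j]))
    shared = len(matches)
    n_a, n_b = len(blocks_a), len(blocks_b)
    neither = universe - (n_a + n_b - shared)
    if neither < 0:
        raise ValueError(
            f"universe {universe} smaller than observed block categories "
            f"({n_a} + {n_b} - {shared})"
        )
    table = np.array(
        [[shared, n_a - shared], [n_b - shared, neither]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "matches": matches,
        "n_shared": shared,
        "table": table,
        "chi2": float(chi2),
        "p": float(p),
    }


def sign_concordance(
    alpha_a: Sequence[float], alpha_b: Sequence[float]
) -> ConcordanceTable:
    """2x2 chi-square of effect-size signs over a shared gene list.

    Genes with a zero effect in either dataset are excluded and counted.
    """
    a = np.asarray(alpha_a, dtype=float)
    b = np.asarray(alpha_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("effect vectors must share the gene list")
    nz = (a != 0) & (b != 0)
    n_zero = int((~nz).sum())
    a, b = a[nz], b[nz]
    table = np.array(
        [
            [int(np.sum((a > 0) & (b > 0))), int(np.sum((a > 0) & (b < 0)))],
            [int(np.sum((a < 0) & (b > 0))), int(np.sum((a < 0) & (b < 0)))],
        ],
        dtype=float,
    )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ConcordanceTable(
        table=table, chi2=float(chi2), df=int(df), p=float(p), n_zero_excluded=n_zero
    )


def concordance_from_counts(
    both_pos: int, both_neg: int, pos_a: int, neg_a: int
) -> ConcordanceTable:
    """Build the 2x2 sign table from printed margins of dataset A.

    Cells: ``pos_a - both_pos`` genes positive in A / negative in B and
    ``neg_a - both_neg`` negative in A / positive in B.
    """
    table = np.array(
        [[both_pos, pos_a - both_pos], [neg_a - both_neg, both_neg]], dtype=float
    )
    if (table < 0).any():
        raise ValueError("inconsistent counts: negative cell")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ConcordanceTable(table=table, chi2=float(chi2), df=int(df), p=float(p),
                            n_zero_excluded=0)


def x_attenuation_test(
    cis_records: pd.DataFrame,
    dosage: DosageMatrix,
    gain_fraction: float = 0.5,
) -> Dict[str, object]:
    """Paired per-clone comparison of cis effect sizes: autosomes vs X.

    For each clone and each sign, the mean effect size is taken over
    cis-regulated genes whose record marker shows a copy gain in that clone
    (normalized dosage above ``gain_fraction`` of the class mode-2 target);
    a paired t-test across clones compares autosomal vs sex-chromosome
    means. Clones lacking gained genes in either group are dropped and
    logged. Also reports the unpaired mean |alpha| comparison.
    """
    marker_row = {m: i for i, m in enumerate(dosage.marker_ids)}
    rows = cis_records["marker"].map(marker_row).to_numpy()
    if np.isnan(rows.astype(float)).any():
        missing = cis_records.loc[pd.isna(cis_records["marker"].map(marker_row)), "marker"]
        raise ValueError(f"records reference unknown markers: {sorted(set(missing))[:5]}")
    rows = rows.astype(int)
    is_sex = dosage.chrom_class[rows] == SEX
    target = np.where(is_sex, SEX_TARGET, AUTOSOME_TARGET)
    gained = dosage.values[rows] > (gain_fraction * target)[:, None]  # records x clones
    alpha = cis_records["alpha"].to_numpy()

    out: Dict[str, object] = {
        "mean_abs_alpha_autosome": float(np.mean(np.abs(alpha[~is_sex])))
        if (~is_sex).any() else float("nan"),
        "mean_abs_alpha_x": float(np.mean(np.abs(alpha[is_sex])))
        if is_sex.any() else float("nan"),
    }
    for sign, name in ((1, "positive"), (-1, "negative")):
        sel = np.sign(alpha) == sign
        auto_means, x_means = [], []
        dropped = 0
        for j in range(dosage.n_clones):
            ga = sel & ~is_sex & gained[:, j]
            gx = sel & is_sex & gained[:, j]
            if not ga.any() or not gx.any():
                dropped += 1
                continue
            auto_means.append(alpha[ga].mean())
            x_means.append(alpha[gx].mean())
        if dropped:
            logger.info("x_attenuation_test(%s): dropped %d clones with no gained "
                        "genes in one group", name, dropped)
        if len(auto_means) >= 2:
            res = stats.ttest_rel(auto_means, x_means)
            out[name] = {
                "t": float(res.statistic),
                "df": len(auto_means) - 1,
                "p": float(res.pvalue),
                "n_clones": len(auto_means),
                "mean_autosome": float(np.mean(auto_means)),
                "mean_x": float(np.mean(x_means)),
            }
        else:
            out[name] = None
    return out


def binned_hotspot_overlap(
    trans_a: pd.DataFrame,
    trans_b: pd.DataFrame,
    bin_size: int = 1_000_000,
) -> Dict[str, object]:
    """Chi-square association of per-bin trans-regulated gene counts.

    The genome is cut into fixed bins over marker positions; per bin each
    dataset contributes the number of distinct regulated genes. Bins are
    cross-classified as above/below each dataset's median count.
    """
    def bin_counts(df: pd.DataFrame) -> pd.Series:
        key = df["marker_chrom"].astype(str) + ":" + (
            df["marker_pos"] // bin_size
        ).astype(str)
        return df.groupby(key)["gene"].nunique()

    ca, cb = bin_counts(trans_a), bin_counts(trans_b)
    bins = sorted(set(ca.index) | set(cb.index))
    va = np.array([ca.get(b, 0) for b in bins], dtype=float)
    vb = np.array([cb.get(b, 0) for b in bins], dtype=float)
    ha = va > np.median(va)
    hb = vb > np.median(vb)
    table = np.array(
        [
            [int(np.sum(ha & hb)), int(np.sum(ha & ~hb))],
            [int(np.sum(~ha & hb)), int(np.sum(~ha & ~hb))],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"table": table, "chi2": float(chi2), "p": float(p), "n_bins": len(bins),
            "counts_a": va, "counts_b": vb}


def closest_gene_assignment(
    peaks: Sequence[Tuple[str, str, int]],
    genes: Sequence[GeneRecord],
) -> Dict[str, Tuple[Optional[str], float, bool]]:
    """Assign each peak the same-chromosome gene with minimal boundary gap.

    Returns ``peak_id -> (gene_id, distance, tied)``; ties go to the gene
    with the lower start coordinate and are flagged.
    """
    by_chrom: Dict[str, List[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for v in by_chrom.values():
        v.sort(key=lambda g: g.start)
    out: Dict[str, Tuple[Optional[str], float, bool]] = {}
    for pid, c, pos in peaks:
        best: Optional[GeneRecord] = None
        best_d = math.inf
        tied = False
        for g in by_chrom.get(str(c), []):
            d = _interval_distance(int(pos), g.start, g.end)
            if d < best_d:
                best, best_d, tied = g, d, False
            elif d == best_d and best is not None and g.gene_id != best.gene_id:
                tied = True  # earlier start already kept (list is start-sorted)
        out[pid] = (best.gene_id if best else None, float(best_d), tied)
    return out
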