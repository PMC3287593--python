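"""Smoothing, bimodal normalization and retention calling for aCGH ratios.

The raw log10 ratio distribution pooled over clones is bimodal: a lower mode
for markers with no extra copy and an upper mode for a single copy gain. The
normalization is the affine map sending the lower mode to 0 and the upper
mode to log10(3/2) for autosomal markers or log10(2/1) for sex-chromosome
markers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .genome import SEX, GenomeDefinition
from .matrices import BINNED, NORMALIZED, SMOOTHED, DosageMatrix

logger = logging.getLogger(__name__)

AUTOSOME_TARGET = math.log10(3.0 / 2.0)
SEX_TARGET = math.log10(2.0 / 1.0)


class NoGainDetectedError(ValueError):
    """Raised when the pooled ratio distribution has no credible second mode."""


@dataclass
class ModeEstimate:
    """Two mode centers of the pooled log10 ratio distribution.

    ``mode1_p95`` is the 95th percentile of the lower component, where
    component membership is split at the density minimum between the modes.
    """

    mode1_center: float
    mode2_center: float
    mode1_p95: float
    split: float
    weight2: float
    bandwidth: float

    def __post_init__(self) -> None:
        if not self.mode2_center > self.mode1_center:
            raise ValueError("mode2_center must exceed mode1_center")


@dataclass
class RetentionTable:
    """Binary retained/lost calls, rows = loci, columns = clones."""

    calls: np.ndarray
    locus_ids: List[str]
    chrom: np.ndarray
    position: np.ndarray
    clone_ids: List[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if not np.all(np.isin(self.calls, (0, 1))):
            raise ValueError("retention calls must be binary")

    @property
    def marker_frequency(self) -> np.ndarray:
        """Per-locus retention frequency (row mean)."""
        return self.calls.mean(axis=1)

    @property
    def clone_fraction(self) -> np.ndarray:
        """Per-clone retained fraction (column mean)."""
        return self.calls.mean(axis=0)


def sliding_window_smooth(raw: DosageMatrix, window: int = 10) -> DosageMatrix:
    """Average each marker over a centered window of adjacent markers.

    The window covers ``window // 2`` markers to the left and the remainder
    to the right, truncated at chromosome ends (windows never span
    chromosomes). A chromosome with fewer markers than the window falls back
    to its whole-chromosome mean with a logged warning.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    out = np.empty_like(raw.values)
    left = window // 2
    right = window - 1 - left
    for chrom, rows in raw.chromosome_slices():
        block = raw.values[rows]
        n = len(rows)
        if window > n:
            logger.warning(
                "window %d exceeds %d markers on %s; using whole-chromosome mean",
                window, n, chrom,
            )
            out[rows] = block.mean(axis=0, keepdims=True)
            continue
        csum = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        lo = np.maximum(np.arange(n) - left, 0)
        hi = np.minimum(np.arange(n) + right + 1, n)
        out[rows] = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return raw.with_values(out, SMOOTHED)


def _refine_mode(kde: stats.gaussian_kde, x0: float, half_width: float) -> float:
    res = optimize.minimize_scalar(
        lambda x: -float(kde(np.atleast_1d(x))[0]),
        bounds=(x0 - half_width, x0 + half_width),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def fit_bimodal_modes(
    values: Sequence[float],
    min_separation: float = 0.02,
    weight_floor: float = 0.02,
    grid_size: int = 1024,
) -> ModeEstimate:
    """Locate the two modes of a pooled log10 ratio sample.

    Uses a Gaussian KDE with Silverman bandwidth; modes are the two highest
    local maxima at least ``min_separation`` apart, refined by bounded
    optimization so the estimate is affine-equivariant to numerical
    tolerance. Raises :class:`NoGainDetectedError` when the upper component
    holds less than ``weight_floor`` of the sample.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise NoGainDetectedError("need at least 2 values to fit modes")
    uniq = np.unique(v)
    if uniq.size == 1:
        raise NoGainDetectedError("no gain detected: all values identical")
    if uniq.size == 2:
        # degenerate two-point mixture: the modes are the points themselves
        lo, hi = float(uniq[0]), float(uniq[1])
        w2 = float(np.mean(v == hi))
        if w2 < weight_floor:
            raise NoGainDetectedError(
                f"no gain detected: upper component weight {w2:.4f} < {weight_floor}"
            )
        split = 0.5 * (lo + hi)
        return ModeEstimate(lo, hi, float(np.percentile(v[v <= split], 95)),
                            split, w2, 0.0)

    kde = stats.gaussian_kde(v, bw_method="silverman")
    bw = float(kde.factor * v.std(ddof=1))
    # coarse scan: binned kernel density (affine-covariant, O(n + grid log grid));
    # exact KDE is only evaluated near candidate peaks during refinement
    lo, hi = v.min() - 3 * bw, v.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    half_bin = 0.5 * (grid[1] - grid[0])
    hist, _ = np.histogram(v, bins=grid_size, range=(lo - half_bin, hi + half_bin))
    m = int(np.ceil(4 * bw / (2 * half_bin)))
    kernel = np.exp(-0.5 * ((np.arange(-m, m + 1) * 2 * half_bin) / bw) ** 2)
    dens = np.convolve(hist.astype(float), kernel, mode="same")
    interior = np.flatnonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    if interior.size == 0:
        raise NoGainDetectedError("no gain detected: density has no interior maxima")
    order = interior[np.argsort(dens[interior])[::-1]]
    width = max(float(bw), 2 * (grid[1] - grid[0]))
    primary = _refine_mode(kde, grid[order[0]], width)
    secondary = None
    for idx in order[1:]:
        cand = _refine_mode(kde, grid[idx], width)
        if abs(cand - primary) >= min_separation:
            secondary = cand
            break
    if secondary is None:
        raise NoGainDetectedError(
            "no gain detected: only one mode above the separation floor"
        )
    m1, m2 = sorted((primary, secondary))
    between = (grid > m1) & (grid < m2)
    split = float(grid[between][np.argmin(dens[between])]) if between.any() else 0.5 * (m1 + m2)
    w2 = float(np.mean(v > split))
    if min(w2, 1.0 - w2) < weight_floor:
        raise NoGainDetectedError(
            f"no gain detected: minority component weight {min(w2, 1 - w2):.4f}"
            f" below floor {weight_floor}"
        )
    lower = v[v <= split]
    return ModeEstimate(m1, m2, float(np.percentile(lower, 95)), split, w2, bw)


def normalize_dosage(
    smoothed: DosageMatrix,
    modes: ModeEstimate,
    epsilon: float = 1e-9,
) -> DosageMatrix:
    """Affine-map values so mode 1 sits at 0 and mode 2 at the class target.

    Autosomal markers are scaled to log10(3/2), sex-chromosome markers to
    log10(2/1) (one extra copy on a diploid vs haploid background).
    """
    sep = modes.mode2_center - modes.mode1_center
    if sep < epsilon:
        raise ValueError(f"degenerate mode separation {sep:.3g} < {epsilon:.3g}")
    target = np.where(smoothed.chrom_class == SEX, SEX_TARGET, AUTOSOME_TARGET)
    scale = (target / sep)[:, None]
    values = (smoothed.values - modes.mode1_center) * scale
    return smoothed.with_values(values, NORMALIZED)


def normalized_threshold(modes: ModeEstimate) -> float:
    """Mode-1 95th percentile mapped through the autosomal normalization."""
    sep = modes.mode2_center - modes.mode1_center
    return (modes.mode1_p95 - modes.mode1_center) * AUTOSOME_TARGET / sep


def call_retention(
    normalized: DosageMatrix,
    loci: Sequence[Tuple[str, int]],
    modes: Optional[ModeEstimate] = None,
    k: int = 10,
    threshold: Optional[float] = None,
) -> RetentionTable:
    """Call each locus retained/lost per clone from the k nearest markers.

    The mean normalized ratio over the ``k`` nearest same-chromosome markers
    is compared to the 95th percentile of the first mode. ``modes`` should be
    fitted on the *normalized* values; when omitted it is refitted here.
    """
    if threshold is None:
        if modes is None:
            modes = fit_bimodal_modes(normalized.values.ravel())
        threshold = modes.mode1_p95
    calls = np.zeros((len(loci), normalized.n_clones), dtype=np.int8)
    chroms = []
    positions = []
    chrom_rows = {c: rows for c, rows in normalized.chromosome_slices()}
    for i, (chrom, pos) in enumerate(loci):
        rows = chrom_rows.get(chrom)
        if rows is None or rows.size == 0:
            raise ValueError(f"locus {chrom}:{pos} lies on a chromosome with no markers")
        d = np.abs(normalized.position[rows] - pos)
        nearest = rows[np.argsort(d, kind="stable")[: min(k, rows.size)]]
        calls[i] = normalized.values[nearest].mean(axis=0) > threshold
        chroms.append(chrom)
        positions.append(pos)
    return RetentionTable(
        calls=calls,
        locus_ids=[f"{c}:{p}" for c, p in loci],
        chrom=np.array(chroms),
        position=np.array(positions, dtype=np.int64),
        clone_ids=list(normalized.clone_ids),
    )


def retention_stats(table: RetentionTable) -> Dict[str, object]:
    """Panel-level retention summary.

    ``representation`` is the genome-wide mean retention multiplied by the
    clone count: the expected number of clones covering a locus.
    """
    if table.calls.size == 0:
        raise ValueError("empty retention table")
    freq = table.marker_frequency
    frac = table.clone_fraction
    mean = float(table.calls.mean())
    return {
        "marker_frequency": freq,
        "clone_fraction": frac,
        "genome_wide_mean": mean,
        "representation": mean * table.calls.shape[1],
        "n_clones": table.calls.shape[1],
        "n_loci": table.calls.shape[0],
    }


def concordance_with_legacy(
    table: RetentionTable,
    legacy_calls: np.ndarray,
    legacy_locus_ids: Sequence[str],
    legacy_clone_ids: Sequence[str],
) -> Dict[str, object]:
    """Chi-square agreement of aCGH retention calls with legacy genotypes.

    Returns the 2x2 contingency table, the uncorrected Pearson chi-square
    (df=1) and P, plus the marker loss fraction (legacy present, call
    absent) and gain fraction (legacy absent, call present).
    """
    missing_loci = set(legacy_locus_ids) ^ set(table.locus_ids)
    missing_clones = set(legacy_clone_ids) ^ set(table.clone_ids)
    if missing_loci or missing_clones:
        raise ValueError(
            f"mismatched locus/clone sets; loci differ by {sorted(missing_loci)!r}, "
            f"clones differ by {sorted(missing_clones)!r}"
        )
    legacy = np.asarray(legacy_calls, dtype=np.int8)
    li = [list(legacy_locus_ids).index(x) for x in table.locus_ids]
    ci = [list(legacy_clone_ids).index(x) for x in table.clone_ids]
    legacy = legacy[np.ix_(li, ci)]
    call = table.calls
    both = int(np.sum((call == 1) & (legacy == 1)))
    call_only = int(np.sum((call == 1) & (legacy == 0)))
    legacy_only = int(np.sum((call == 0) & (legacy == 1)))
    neither = int(np.sum((call == 0) & (legacy == 0)))
    cont = np.array([[both, legacy_only], [call_only, neither]], dtype=float)
    chi2, p, dof, _ = stats.chi2_contingency(cont, correction=False)
    n_legacy = both + legacy_only
    n_nolegacy = call_only + neither
    return {
        "table": cont,
        "chi2": float(chi2),
        "df": int(dof),
        "p": float(p),
        "loss_fraction": legacy_only / n_legacy if n_legacy else 0.0,
        "gain_fraction": call_only / n_nolegacy if n_nolegacy else 0.0,
    }


def centromere_retention_test(
    table: RetentionTable, genome: GenomeDefinition
) -> Dict[str, float]:
    """Welch's t-test of per-locus retention inside vs outside centromeres."""
    if not genome.centromeres:
        raise ValueError("genome has no centromere annotation")
    freq = table.marker_frequency
    inside = np.zeros(len(freq), dtype=bool)
    for i, (c, p) in enumerate(zip(table.chrom, table.position)):
        cen = genome.centromeres.get(str(c))
        if cen is not None and cen[0] <= p < cen[1]:
            inside[i] = True
    a, b = freq[inside], freq[~inside]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 loci both inside and outside centromeres")
    res = stats.ttest_ind(a, b, equal_var=False)
    # Welch–Satterthwaite df
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return {
        "t": float(res.statistic),
        "df": float(df),
        "p": float(res.pvalue),
        "p_one_sided_greater": float(
            stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
        ),
        "mean_inside": float(a.mean()),
        "mean_outside": float(b.mean()),
    }


def _best_split(csum: np.ndarray, csum2: np.ndarray, i: int, j: int) -> Tuple[int, float]:
    """Best single changepoint of segment [i, j) by pooled RSS; O(j-i)."""
    ks = np.arange(i + 1, j)
    nl = ks - i
    nr = j - ks
    sl = csum[ks] - csum[i]
    sr = csum[j] - csum[ks]
    s2l = csum2[ks] - csum2[i]
    s2r = csum2[j] - csum2[ks]
    rss = (s2l - sl**2 / nl) + (s2r - sr**2 / nr)
    b = int(np.argmin(rss))
    return int(ks[b]), float(rss[b])


def _segment(x: np.ndarray, penalty: float, eps: float = 1e-12) -> List[Tuple[int, int]]:
    """Recursive binary segmentation with a BIC-style acceptance rule."""
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def rss(i: int, j: int) -> float:
        s = csum[j] - csum[i]
        return float(csum2[j] - csum2[i] - s * s / (j - i))

    segments: List[Tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            segments.append((i, j))
            continue
        k, rss_split = _best_split(csum, csum2, i, j)
        m = j - i
        cost0 = m * math.log(max(rss(i, j), eps) / m)
        nl, nr = k - i, j - k
        cost1 = nl * math.log(max(rss(i, k), eps) / nl) + nr * math.log(
            max(rss(k, j), eps) / nr
        )
        if cost0 - cost1 > penalty:
            stack.append((i, k))
            stack.append((k, j))
        else:
            segments.append((i, j))
    return sorted(segments)


def bin_copy_number(normalized: DosageMatrix, penalty: Optional[float] = None) -> DosageMatrix:
    """Segment each clone's per-chromosome profile and round segments to 0/1.

    Segmentation is recursive binary splitting on Gaussian segment
    likelihood with a BIC penalty; each segment is assigned 0 or 1 extra
    copy by whichever of {0, class target} its mean is closer to.
    """
    out = np.zeros_like(normalized.values)
    for chrom, rows in normalized.chromosome_slices():
        target = SEX_TARGET if normalized.chrom_class[rows[0]] == SEX else AUTOSOME_TARGET
        n = rows.size
        pen = penalty if penalty is not None else 3.0 * math.log(max(n, 2))
        for j in range(normalized.n_clones):
            x = normalized.values[rows, j]
            for i0, i1 in _segment(x, pen):
                seg_mean = x[i0:i1].mean()
                out[rows[i0:i1], j] = float(abs(seg_mean - target) < abs(seg_mean))
    return normalized.with_values(out, BINNED)
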