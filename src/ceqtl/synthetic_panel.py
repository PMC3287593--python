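"""Simulate radiation-hybrid-like panels with planted ground truth.

A clone carries a random assortment of donor fragments (Poisson starts,
exponential lengths) plus one fragment forced over the selectable locus.
Copy number is 0/1 extra copies per marker; aCGH ratios are a two-mode
mixture; expression is baseline + alpha * dosage (+ trans links) + noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genome import SEX, GenomeDefinition
from .matrices import RAW, DosageMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

# fixed stage tags so each sub-generator derives a documented child stream
_STAGE_FRAGMENTS = 1
_STAGE_EFFECTS = 2
_STAGE_ACGH = 3
_STAGE_EXPRESSION = 4


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass
class SimulationConfig:
    """Panel simulation parameters; defaults follow the reference panel."""

    n_clones: int = 79
    target_retention: float = 0.114
    mean_fragment_length: float = 4_000_000.0
    centromere_retention_multiplier: float = 1.0
    acgh_noise_sd: float = 0.03
    expr_noise_sd: float = 0.05
    alpha_positive_mean: float = 0.73
    alpha_negative_mean: float = -0.12
    alpha_sd: float = 0.15
    fraction_negative: float = 0.36
    x_attenuation_factor: float = 0.5
    baseline_sd: float = 0.10
    n_trans_links: int = 0
    trans_alpha_mean: float = 1.0
    raw_mode_separation: float = 0.20
    raw_mode_offset: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError(f"n_clones must be >= 1, got {self.n_clones}")
        if not 0.0 < self.target_retention < 1.0:
            raise ValueError(
                f"target_retention must lie strictly in (0, 1), got {self.target_retention}"
            )
        if self.mean_fragment_length <= 0:
            raise ValueError(
                f"mean_fragment_length must be positive, got {self.mean_fragment_length}"
            )
        if self.centromere_retention_multiplier < 1.0:
            raise ValueError(
                "centromere_retention_multiplier must be >= 1, "
                f"got {self.centromere_retention_multiplier}"
            )
        for name in ("acgh_noise_sd", "expr_noise_sd", "alpha_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.fraction_negative <= 1.0:
            raise ValueError(f"fraction_negative must be in [0, 1], got {self.fraction_negative}")
        if not 0.0 < self.x_attenuation_factor <= 1.0:
            raise ValueError(
                f"x_attenuation_factor must be in (0, 1], got {self.x_attenuation_factor}"
            )
        if self.n_trans_links < 0:
            raise ValueError(f"n_trans_links must be >= 0, got {self.n_trans_links}")


@dataclass
class TransLink:
    source_chrom: str
    source_pos: int
    target_gene: str
    alpha: float


@dataclass
class PanelTruth:
    """Planted ground truth: fragments, binary copy state and effect sizes."""

    fragments: List[List[Tuple[str, int, int]]]  # per clone
    copy_state: np.ndarray  # markers x clones, {0,1}
    gene_alpha: Optional[Dict[str, float]] = None
    gene_mu: Optional[Dict[str, float]] = None
    trans_links: List[TransLink] = field(default_factory=list)


def _solve_start_rate(config: SimulationConfig) -> float:
    """Fragment-start rate per bp giving the target marker retention.

    For Poisson(start rate rho) fragments with Exp(mean L) lengths the
    stationary coverage probability of a point is 1 - exp(-rho * L).
    """
    return -np.log1p(-config.target_retention) / config.mean_fragment_length


def simulate_fragments(
    genome: GenomeDefinition,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> PanelTruth:
    """Draw donor fragments per clone and derive the binary copy state.

    Every clone receives one extra fragment covering the selectable locus
    unless a random fragment already covers it.
    """
    if genome.n_markers == 0:
        raise ValueError("genome has zero markers")
    rng = _stage_rng(config.seed if seed is None else seed, _STAGE_FRAGMENTS)
    rho = _solve_start_rate(config)
    L = config.mean_fragment_length
    mult = config.centromere_retention_multiplier
    sel_chrom, sel_pos = genome.selectable_locus
    # the forced fragment must also reach the nearest marker so that the
    # selectable locus is *called* retained in every clone
    sel_markers = genome.marker_positions.get(sel_chrom)
    if sel_markers is not None and sel_markers.size:
        nearest = int(sel_markers[np.argmin(np.abs(sel_markers - sel_pos))])
        sel_lo, sel_hi = min(sel_pos, nearest), max(sel_pos, nearest) + 1
    else:
        sel_lo, sel_hi = sel_pos, sel_pos + 1

    # per-chromosome piecewise start density: weight `mult` inside centromere
    chrom_specs = []
    for name, length, _ in genome.chromosomes:
        cen = genome.centromeres.get(name)
        if cen is not None and mult > 1.0:
            eff = length + (mult - 1.0) * (cen[1] - cen[0])
        else:
            cen, eff = None, float(length)
        chrom_specs.append((name, length, cen, eff))

    ids, chroms, positions, _ = genome.marker_table()
    n_markers = len(ids)
    copy_state = np.zeros((n_markers, config.n_clones), dtype=np.int8)
    fragments: List[List[Tuple[str, int, int]]] = []

    for clone in range(config.n_clones):
        clone_frags: List[Tuple[str, int, int]] = []
        covers_sel = False
        for name, length, cen, eff in chrom_specs:
            n_frag = rng.poisson(rho * eff)
            if n_frag == 0:
                continue
            u = rng.uniform(0.0, eff, size=n_frag)
            if cen is not None:
                starts = _unmap_weighted(u, length, cen, mult)
            else:
                starts = u
            lens = rng.exponential(L, size=n_frag)
            for s, fl in zip(starts, lens):
                s = int(s)
                e = int(min(length, s + max(1.0, fl)))
                clone_frags.append((name, s, e))
                if name == sel_chrom and s <= sel_lo and sel_hi <= e:
                    covers_sel = True
        if not covers_sel:
            span = sel_hi - sel_lo
            fl = int(max(span, rng.exponential(L)))
            slack = fl - span
            s = max(0, sel_lo - int(rng.uniform(0.0, slack + 1)))
            e = min(genome.chrom_lengths[sel_chrom], s + fl)
            if e < sel_hi:  # truncated at chromosome end: anchor on the span
                s, e = max(0, sel_hi - fl), sel_hi
            clone_frags.append((sel_chrom, int(s), int(e)))
        fragments.append(clone_frags)
        for name, s, e in clone_frags:
            on = np.flatnonzero(chroms == name)
            if on.size:
                hit = (positions[on] >= s) & (positions[on] < e)
                copy_state[on[hit], clone] = 1

    return PanelTruth(fragments=fragments, copy_state=copy_state)


def _unmap_weighted(
    u: np.ndarray, length: int, cen: Tuple[int, int], mult: float
) -> np.ndarray:
    """Map uniform draws on the weighted axis back to bp coordinates."""
    cs, ce = cen
    a = float(cs)  # weighted length before centromere
    b = a + mult * (ce - cs)  # ... through centromere
    out = np.empty_like(u)
    pre = u < a
    mid = (u >= a) & (u < b)
    post = u >= b
    out[pre] = u[pre]
    out[mid] = cs + (u[mid] - a) / mult
    out[post] = ce + (u[post] - b)
    return out


def plant_effects(
    truth: PanelTruth,
    genome: GenomeDefinition,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> PanelTruth:
    """Populate per-gene baseline, cis effect sizes and optional trans links.

    Effect sizes are a two-component Gaussian mixture (positive and negative
    components); X-linked effect magnitudes are multiplied by the attenuation
    factor at generation time.
    """
    rng = _stage_rng(config.seed if seed is None else seed, _STAGE_EFFECTS)
    classes = genome.chrom_classes
    gene_alpha: Dict[str, float] = {}
    gene_mu: Dict[str, float] = {}
    for g in genome.genes:
        if rng.uniform() < config.fraction_negative:
            a = rng.normal(config.alpha_negative_mean, config.alpha_sd)
            a = -abs(a)
        else:
            a = rng.normal(config.alpha_positive_mean, config.alpha_sd)
            a = abs(a)
        if classes[g.chrom] == SEX:
            a *= config.x_attenuation_factor
        gene_alpha[g.gene_id] = float(a)
        gene_mu[g.gene_id] = float(rng.normal(0.0, config.baseline_sd))

    links: List[TransLink] = []
    if config.n_trans_links > 0:
        ids, chroms, positions, _ = genome.marker_table()
        gene_ids = [g.gene_id for g in genome.genes]
        for _ in range(config.n_trans_links):
            m = int(rng.integers(len(ids)))
            g = gene_ids[int(rng.integers(len(gene_ids)))]
            links.append(
                TransLink(
                    source_chrom=str(chroms[m]),
                    source_pos=int(positions[m]),
                    target_gene=g,
                    alpha=float(rng.normal(config.trans_alpha_mean, config.alpha_sd)),
                )
            )
    truth.gene_alpha = gene_alpha
    truth.gene_mu = gene_mu
    truth.trans_links = links
    return truth


def simulate_acgh(
    truth: PanelTruth,
    genome: GenomeDefinition,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> DosageMatrix:
    """Raw aCGH log10 ratios: offset + copy_state * separation + noise."""
    rng = _stage_rng(config.seed if seed is None else seed, _STAGE_ACGH)
    ids, chroms, positions, classes = genome.marker_table()
    if truth.copy_state.shape[0] != len(ids):
        raise ValueError("copy_state rows do not match genome markers")
    values = (
        config.raw_mode_offset
        + truth.copy_state.astype(float) * config.raw_mode_separation
    )
    if config.acgh_noise_sd > 0:
        values = values + rng.normal(0.0, config.acgh_noise_sd, size=values.shape)
    clone_ids = [f"clone{j:03d}" for j in range(truth.copy_state.shape[1])]
    return DosageMatrix(
        values=values,
        marker_ids=ids,
        chrom=chroms,
        position=positions,
        chrom_class=classes,
        clone_ids=clone_ids,
        state=RAW,
    )


def simulate_expression(
    truth: PanelTruth,
    normalized_dosage: DosageMatrix,
    genome: GenomeDefinition,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> ExpressionMatrix:
    """Expression log-ratios: mu + alpha * dosage at the nearest marker
    (+ planted trans contributions) + Gaussian noise.
    """
    if truth.gene_alpha is None or truth.gene_mu is None:
        raise ValueError("plant_effects must run before simulate_expression")
    rng = _stage_rng(config.seed if seed is None else seed, _STAGE_EXPRESSION)
    n_clones = normalized_dosage.n_clones
    genes = genome.genes
    values = np.zeros((len(genes), n_clones), dtype=float)

    chrom_rows = {c: rows for c, rows in normalized_dosage.chromosome_slices()}
    for i, g in enumerate(genes):
        rows = chrom_rows.get(g.chrom)
        if rows is None or rows.size == 0:
            raise ValueError(f"gene {g.gene_id}: no marker on chromosome {g.chrom}")
        mid = (g.start + g.end) // 2
        r = rows[np.argmin(np.abs(normalized_dosage.position[rows] - mid))]
        values[i] = truth.gene_mu[g.gene_id] + truth.gene_alpha[g.gene_id] * (
            normalized_dosage.values[r]
        )
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    for link in truth.trans_links:
        rows = chrom_rows.get(link.source_chrom)
        if rows is None or rows.size == 0:
            continue
        r = rows[np.argmin(np.abs(normalized_dosage.position[rows] - link.source_pos))]
        values[gene_index[link.target_gene]] += link.alpha * normalized_dosage.values[r]
    if config.expr_noise_sd > 0:
        values = values + rng.normal(0.0, config.expr_noise_sd, size=values.shape)
    return ExpressionMatrix(
        values=values,
        gene_ids=[g.gene_id for g in genes],
        chrom=np.array([g.chrom for g in genes]),
        start=np.array([g.start for g in genes], dtype=np.int64),
        end=np.array([g.end for g in genes], dtype=np.int64),
        clone_ids=list(normalized_dosage.clone_ids),
    )


def fragment_lengths(truth: PanelTruth) -> np.ndarray:
    """All simulated fragment lengths (bp), pooled across clones."""
    return np.array(
        [e - s for clone in truth.fragments for (_, s, e) in clone], dtype=float
    )
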