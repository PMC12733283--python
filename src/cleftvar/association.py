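"""Common-variant association scan over gene locus windows.

For each gene locus (gene body plus a flank, default 100 kb on each side),
common SNVs (sample-wide MAF at or above 0.05 by default) are tested for a
linear trend in case proportion across genotype copy classes with the
Cochran-Armitage trend test (1-df chi-square score test). Effect sizes are
allelic odds ratios oriented to the pooled minor allele. Two Bonferroni
thresholds are reported: alpha divided by the number of genes, and alpha
divided by the total number of SNVs tested.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import GenotypeCounts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    flank_bp: int = 100_000
    maf_min: float = 0.05
    alpha: float = 0.05
    trend_weights: Tuple[float, float, float] = (0.0, 1.0, 2.0)
    haldane_correction: bool = True

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        w = self.trend_weights
        if not (w[0] < w[1] < w[2]):
            raise ValueError("trend weights must be strictly increasing")


@dataclass(frozen=True)
class AssociationResult:
    snv_id: str
    gene: str
    chrom: str
    pos: int
    maf: float
    chi2: float
    p_trend: float
    or_allelic: float
    significant_gene_level: bool = False
    significant_snv_level: bool = False


@dataclass
class ScanResult:
    results: List[AssociationResult]
    best_per_gene: Dict[str, AssociationResult]
    gene_threshold: float
    snv_threshold: float
    n_genes: int
    n_snvs: int


def trend_test(
    counts: GenotypeCounts,
    weights: Sequence[float] = (0.0, 1.0, 2.0),
) -> Tuple[float, float]:
    """Cochran-Armitage trend test on a 2x3 genotype table.

    With case counts n_i, control counts m_i, column totals c_i = n_i + m_i,
    R cases, S controls, N = R + S and weights w_i, the score statistic is

        T = sum_i w_i (n_i S - m_i R)
        Var(T) = (R S / N) [N sum_i w_i^2 c_i - (sum_i w_i c_i)^2]
        chi2 = T^2 / Var(T),  p = P(Chi2_1 >= chi2).

    With two genotype classes this reduces exactly to the Pearson
    chi-square of the collapsed 2x2 table.

    A monomorphic table (zero variance) returns chi2 0, p 1.
    """
    n = np.asarray(counts.case_counts, dtype=float)
    m = np.asarray(counts.control_counts, dtype=float)
    w = np.asarray(weights, dtype=float)
    R, S = n.sum(), m.sum()
    N = R + S
    c = n + m
    T = float(np.sum(w * (n * S - m * R)))
    var = (R * S / N) * (N * np.sum(w * w * c) - np.sum(w * c) ** 2)
    if var <= 0:
        return 0.0, 1.0
    chi2 = T * T / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), max(p, np.finfo(float).tiny)


def allelic_or(counts: GenotypeCounts, haldane: bool = True) -> float:
    """Allelic odds ratio from the collapsed 2x2 allele table.

    With any zero cell and ``haldane`` enabled, 0.5 is added to all four
    cells (Haldane-Anscombe correction), keeping the estimate finite.
    """
    a, b, c, d = (float(x) for x in counts.allele_counts())
    if haldane and 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0.0:
        return float("inf")
    return (a * d) / (b * c)


def window_select(
    gene: Tuple[str, int, int],
    snvs: Sequence[Tuple[str, str, int]],
    flank_bp: int = 100_000,
) -> List[str]:
    """SNV ids within the closed window [start - flank, end + flank].

    ``gene`` is (chrom, start, end) in 1-based fully closed coordinates;
    ``snvs`` are (snv_id, chrom, pos) tuples. Results are in position order
    (ties by id).
    """
    chrom, start, end = gene
    if start > end:
        raise ValueError(f"malformed interval: start {start} > end {end}")
    lo, hi = start - flank_bp, end + flank_bp
    hits = [(pos, sid) for sid, c, pos in snvs
            if c == chrom and lo <= pos <= hi]
    return [sid for _pos, sid in sorted(hits)]


def bonferroni_thresholds(alpha: float, n_genes: int,
                          n_snvs: int) -> Tuple[float, float]:
    """(gene-level, SNV-level) Bonferroni significance thresholds."""
    if n_genes <= 0 or n_snvs <= 0:
        raise ValueError("need at least one gene and one SNV")
    return alpha / n_genes, alpha / n_snvs


def oriented_to_minor(counts: GenotypeCounts) -> GenotypeCounts:
    """Re-index the table by the pooled minor allele if necessary."""
    if counts.pooled_alt_fraction() > 0.5:
        return counts.flipped()
    return counts


def scan(
    genes: Mapping[str, Tuple[str, int, int]],
    snvs: Sequence[Tuple[str, str, int]],
    genotype_counts: Mapping[str, GenotypeCounts],
    config: ScanConfig = ScanConfig(),
) -> ScanResult:
    """Run the locus scan over all gene windows.

    Parameters
    ----------
    genes : mapping
        gene symbol -> (chrom, start, end), 1-based closed coordinates.
    snvs : sequence of (snv_id, chrom, pos)
        Positions of the genotyped SNVs (one assembly throughout).
    genotype_counts : mapping
        snv_id -> 2x3 case/control genotype counts.

    SNVs below the sample-wide MAF floor are dropped before testing. Each
    SNV contributes once to the SNV-level Bonferroni denominator even when
    it falls in several overlapping windows. Per-gene best SNVs are the
    minimal trend p, ties broken by position then id.
    """
    if not genes:
        raise ValueError("need at least one gene")
    per_snv: Dict[str, Tuple[float, float, float, float]] = {}
    results: List[AssociationResult] = []
    pos_of = {sid: (chrom, pos) for sid, chrom, pos in snvs}
    tested_snvs: set = set()

    for gene_symbol, interval in genes.items():
        for sid in window_select(interval, snvs, config.flank_bp):
            counts = genotype_counts.get(sid)
            if counts is None:
                continue
            oriented = oriented_to_minor(counts)
            maf = oriented.pooled_alt_fraction()
            if maf < config.maf_min:
                continue
            if sid not in per_snv:
                chi2, p = trend_test(oriented, config.trend_weights)
                orr = allelic_or(oriented, config.haldane_correction)
                per_snv[sid] = (maf, chi2, p, orr)
            maf, chi2, p, orr = per_snv[sid]
            tested_snvs.add(sid)
            chrom, pos = pos_of[sid]
            results.append(AssociationResult(
                snv_id=sid, gene=gene_symbol, chrom=chrom, pos=pos,
                maf=maf, chi2=chi2, p_trend=p, or_allelic=orr))

    if not results:
        logger.warning("no SNVs passed the MAF filter in any gene window")
        g_thr, s_thr = config.alpha / len(genes), float("nan")
        return ScanResult([], {}, g_thr, s_thr, len(genes), 0)

    g_thr, s_thr = bonferroni_thresholds(
        config.alpha, len(genes), len(tested_snvs))
    flagged = [
        AssociationResult(
            snv_id=r.snv_id, gene=r.gene, chrom=r.chrom, pos=r.pos,
            maf=r.maf, chi2=r.chi2, p_trend=r.p_trend,
            or_allelic=r.or_allelic,
            significant_gene_level=r.p_trend < g_thr,
            significant_snv_level=r.p_trend < s_thr)
        for r in results]

    best: Dict[str, AssociationResult] = {}
    for r in flagged:
        cur = best.get(r.gene)
        key = (r.p_trend, r.pos, r.snv_id)
        if cur is None or key < (cur.p_trend, cur.pos, cur.snv_id):
            best[r.gene] = r
    return ScanResult(flagged, best, g_thr, s_thr, len(genes),
                      len(tested_snvs))
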