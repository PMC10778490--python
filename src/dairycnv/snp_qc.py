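"""Genotype quality control and population-structure diagnostics.

Filters a B-allele-dosage genotype panel with the study's criteria — SNP call
rate > 90%, sample call rate > 95%, MAF >= 0.05, Hardy-Weinberg exact-test
p >= 1e-6 — and computes identity-by-state (IBS) similarity with
average-linkage hierarchical clustering to screen for population
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import gammaln

MISSING = -1


@dataclass
class GenotypePanel:
    """SNP map plus a samples x SNPs dosage matrix (0/1/2 copies of the B
    allele, -1 = missing).  Positions must be strictly increasing within a
    chromosome."""

    snp_map: pd.DataFrame  # columns: name, chrom, pos
    genotypes: np.ndarray  # (n_samples, n_snps) int8
    sample_ids: list

    def __post_init__(self):
        g = self.genotypes
        if g.shape != (len(self.sample_ids), len(self.snp_map)):
            raise ValueError("genotype matrix shape does not match map/samples")
        if not np.isin(g, [MISSING, 0, 1, 2]).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        for _, grp in self.snp_map.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions not strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypePanel":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else sample_mask
        km = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypePanel(
            snp_map=self.snp_map[km].reset_index(drop=True),
            genotypes=self.genotypes[np.ix_(sm, km)],
            sample_ids=[s for s, keep in zip(self.sample_ids, sm) if keep],
        )


@dataclass(frozen=True)
class QcThresholds:
    """Defaults follow the study's criteria; the HWE threshold is the PLINK
    convention p < 1e-6."""

    min_snp_call_rate: float = 0.90  # strictly greater retained
    min_sample_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6


@dataclass
class QcReport:
    thresholds: QcThresholds
    removed_snps: dict[str, list] = field(default_factory=dict)
    removed_samples: list = field(default_factory=list)
    n_snps_in: int = 0
    n_snps_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts (with the parity the allele counts allow) whose
    conditional probability does not exceed that of the observed table.
    Degenerate inputs (n = 0 or a fixed allele) give p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    het_obs = n_ab
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | n, rare) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == het_obs][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _call_rates(g: np.ndarray, axis: int) -> np.ndarray:
    return (g != MISSING).mean(axis=axis)


def filter_genotypes(
    panel: GenotypePanel, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypePanel, QcReport]:
    """Apply the QC criteria in order: (1) SNP call rate, (2) sample call
    rate, (3) MAF, (4) HWE — MAF and HWE computed after sample removal."""
    rep = QcReport(
        thresholds=thresholds,
        n_snps_in=panel.n_snps,
        n_samples_in=panel.n_samples,
    )
    names = panel.snp_map["name"]

    snp_cr = _call_rates(panel.genotypes, axis=0)
    keep_snp = snp_cr > thresholds.min_snp_call_rate
    rep.removed_snps["call_rate"] = list(names[~keep_snp])
    panel = panel.subset(snp_mask=keep_snp)

    samp_cr = _call_rates(panel.genotypes, axis=1)
    keep_samp = samp_cr > thresholds.min_sample_call_rate
    rep.removed_samples = [s for s, k in zip(panel.sample_ids, keep_samp) if not k]
    panel = panel.subset(sample_mask=keep_samp)

    g = np.ma.masked_equal(panel.genotypes, MISSING)
    called = (~g.mask).sum(axis=0) if g.mask is not np.ma.nomask else np.full(panel.n_snps, panel.n_samples)
    bsum = g.sum(axis=0).filled(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(called > 0, bsum / (2.0 * called), 0.0)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    keep_maf = maf >= thresholds.min_maf
    rep.removed_snps["maf"] = list(panel.snp_map["name"][~keep_maf])
    panel = panel.subset(snp_mask=keep_maf)

    gm = panel.genotypes
    n0 = (gm == 0).sum(axis=0)
    n1 = (gm == 1).sum(axis=0)
    n2 = (gm == 2).sum(axis=0)
    hwe_p = np.array([hwe_exact(a, b, c) for a, b, c in zip(n0, n1, n2)])
    keep_hwe = hwe_p >= thresholds.hwe_alpha
    rep.removed_snps["hwe"] = list(panel.snp_map["name"][~keep_hwe])
    panel = panel.subset(snp_mask=keep_hwe)

    rep.n_snps_out = panel.n_snps
    rep.n_samples_out = panel.n_samples
    if panel.n_snps == 0:
        raise ValueError("all SNPs removed by quality control")
    return panel, rep


def ibs_matrix(panel: GenotypePanel) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Pairwise identity-by-state matrix.

    IBS(i, j) is the mean over jointly called SNPs of (2 - |g_i - g_j|)/2,
    in [0, 1] with unit diagonal.  Pairs sharing no called SNP are NaN and
    returned in the flagged list.
    """
    if panel.n_samples < 2:
        raise ValueError("IBS requires at least 2 samples")
    g = panel.genotypes.astype(float)
    called = g != MISSING
    n = panel.n_samples
    M = np.eye(n)
    flagged: list[tuple[int, int]] = []
    for i in range(n):
        both = called[i] & called[i + 1:]
        diff = np.abs(g[i] - g[i + 1:])
        counts = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.where(
                counts > 0,
                ((2.0 - diff) / 2.0 * both).sum(axis=1) / counts,
                np.nan,
            )
        M[i, i + 1:] = M[i + 1:, i] = vals
        for off in np.nonzero(counts == 0)[0]:
            flagged.append((i, i + 1 + off))
    return M, flagged


def cluster(ibs: np.ndarray, n_groups: int | None = None):
    """Average-linkage hierarchical clustering on 1 - IBS.

    Returns the scipy linkage matrix, and group labels if ``n_groups`` is
    given.
    """
    D = 1.0 - ibs
    np.fill_diagonal(D, 0.0)
    if np.isnan(D).any():
        raise ValueError("IBS matrix has undefined entries; cannot cluster")
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    if n_groups is None:
        return Z, None
    labels = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    return Z, labels
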