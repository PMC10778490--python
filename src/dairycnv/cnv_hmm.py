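"""Per-sample copy-number calling from SNP-array LRR/BAF signals.

The caller is a five-state hidden Markov model over copy numbers 0-4 decoded
by the Viterbi algorithm, in the tradition of intensity-based SNP-array CNV
callers:

* **LRR** (log2 ratio of observed to expected probe intensity) is emitted as
  a state-specific Gaussian.
* **BAF** (B-allele frequency) is emitted, for copy number s >= 1, as a
  mixture over the B-copy count k = 0..s with binomial weights
  Binom(s, PFB) — PFB being the per-SNP population B-allele frequency — and
  Gaussian components centred at k/s.  Values pinned at exactly 0 or 1 carry
  the tail mass of the components beyond the boundary.  Copy number 0 has no
  genotype, so its BAF is uniform on [0, 1].
* Transitions decay with inter-SNP distance d: the probability of moving to
  state t != u is (1 - exp(-d/D)) * pi_t, where pi is the diploid-dominant
  state prior and D a length scale (default 100 kb); the self-transition is
  the remainder.  Longer gaps therefore strictly increase the probability of
  a state change.

Also here: PFB compilation, GC-wave correction of LRR (regression of LRR on
the mean GC of the 1 Mb window centred on each SNP), per-sample signal
quality metrics (LRR SD, BAF drift, GC waviness factor), and the segment
confidence score (emission log-likelihood ratio against the diploid state).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

COPY_NUMBERS = (0, 1, 2, 3, 4)
DIPLOID = 2  # index of the diploid state


@dataclass(frozen=True)
class HmmParams:
    """Emission/transition parameters; one row per copy-number state 0-4."""

    lrr_mean: tuple = (-3.5, -0.66, 0.0, 0.40, 0.68)
    lrr_sd: tuple = (1.3, 0.28, 0.16, 0.21, 0.24)
    baf_sd: float = 0.04
    pi: tuple = (1e-4, 1e-3, 0.9965, 2e-3, 4e-4)
    d_scale: float = 100_000.0  # bp

    def __post_init__(self):
        if min(self.lrr_sd) <= 0 or self.baf_sd <= 0:
            raise ValueError("emission SDs must be positive")
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("state prior must sum to 1")
        if self.pi[DIPLOID] != max(self.pi):
            raise ValueError("diploid state prior must dominate")


@dataclass
class IntensityPanel:
    """Per-sample, per-SNP LRR/BAF/genotype aligned to a sorted SNP map."""

    snp_map: pd.DataFrame  # columns: name, chrom, pos (sorted)
    sample_ids: list
    lrr: np.ndarray  # (n_samples, n_snps)
    baf: np.ndarray  # (n_samples, n_snps), in [0, 1] or NaN
    gtype: np.ndarray | None = None  # (n_samples, n_snps) of 'AA'/'AB'/'BB'/'NC'

    def __post_init__(self):
        shape = (len(self.sample_ids), len(self.snp_map))
        if self.lrr.shape != shape or self.baf.shape != shape:
            raise ValueError("signal matrix shape does not match map/samples")
        b = self.baf[np.isfinite(self.baf)]
        if len(b) and (b.min() < 0 or b.max() > 1):
            raise ValueError("BAF values outside [0, 1]")


@dataclass
class CnvCall:
    """One per-sample copy-number segment (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    start_idx: int  # global SNP index within the chromosome's map rows
    end_idx: int
    state: int  # copy number, != 2
    n_snps: int
    conf: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_gain(self) -> bool:
        return self.state > DIPLOID


@dataclass
class SampleSignalMetrics:
    """Per-sample signal quality: corrected-LRR SD, BAF drift (fraction of
    BAF in the inter-band windows (0.2, 0.25) and (0.75, 0.8)), and the
    signed GC waviness factor."""

    lrr_sd: float
    baf_drift: float
    gcwf: float
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# PFB and GC correction
# ---------------------------------------------------------------------------


def compile_pfb(panel: IntensityPanel) -> pd.DataFrame:
    """Population B-allele frequency per SNP: the across-sample median BAF,
    clipped to [0.01, 0.99].  SNPs with no called BAF get PFB 0.5 and a flag.
    """
    if len(panel.sample_ids) < 2:
        raise ValueError("PFB compilation requires at least 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(panel.baf, axis=0)
    flagged = ~np.isfinite(med)
    pfb = np.clip(np.where(flagged, 0.5, med), 0.01, 0.99)
    out = panel.snp_map[["name", "chrom", "pos"]].copy()
    out["pfb"] = pfb
    out["all_missing"] = flagged
    return out


def snp_window_gc(
    snp_map: pd.DataFrame, gc_track: pd.DataFrame, half_window: int = 500_000
) -> np.ndarray:
    """Mean GC fraction of the window centred on each SNP (``half_window`` bp
    each side, truncated at chromosome ends), length-weighted over the
    overlapping track intervals.  ``gc_track`` has columns chrom, start, end,
    gc_fraction with half-open [start, end) intervals."""
    out = np.full(len(snp_map), np.nan)
    for chrom, grp in snp_map.groupby("chrom"):
        track = gc_track[gc_track["chrom"] == chrom]
        if track.empty:
            continue
        ts = track["start"].to_numpy(float)
        te = track["end"].to_numpy(float)
        gv = track["gc_fraction"].to_numpy(float)
        pos = grp["pos"].to_numpy(float)
        lo = np.maximum(pos - half_window, ts.min())
        hi = np.minimum(pos + half_window, te.max())
        i0 = np.searchsorted(te, lo, side="right")
        i1 = np.searchsorted(ts, hi, side="left")
        vals = np.empty(len(pos))
        for k in range(len(pos)):
            sl = slice(i0[k], max(i1[k], i0[k] + 1))
            w = np.clip(np.minimum(te[sl], hi[k]) - np.maximum(ts[sl], lo[k]), 0, None)
            tot = w.sum()
            vals[k] = (w @ gv[sl]) / tot if tot > 0 else gv[sl].mean()
        out[grp.index] = vals
    return out


def gc_correct(lrr: np.ndarray, snp_gc: np.ndarray) -> tuple[np.ndarray, dict]:
    """Regress one sample's LRR on window GC content and return the residual
    plus the original sample mean, with the fit summary.  Constant GC makes
    the correction a no-op (with a warning)."""
    lrr = np.asarray(lrr, float)
    ok = np.isfinite(lrr) & np.isfinite(snp_gc)
    if ok.sum() < 3 or np.std(snp_gc[ok]) == 0:
        warnings.warn("GC content constant or insufficient data; LRR left unadjusted")
        return lrr.copy(), {"slope": 0.0, "intercept": float(np.nanmean(lrr)), "r2": 0.0}
    slope, intercept = np.polyfit(snp_gc[ok], lrr[ok], 1)
    fitted = slope * snp_gc + intercept
    resid = lrr - fitted
    adj = resid + np.nanmean(lrr[ok])
    ss_res = float(np.nansum(resid[ok] ** 2))
    ss_tot = float(np.nansum((lrr[ok] - np.nanmean(lrr[ok])) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return adj, {"slope": float(slope), "intercept": float(intercept), "r2": r2}


# ---------------------------------------------------------------------------
# Emissions and transitions
# ---------------------------------------------------------------------------


def baf_logpdf(baf: np.ndarray, pfb: np.ndarray, params: HmmParams) -> np.ndarray:
    """(n_snps, 5) BAF log-emission.  Copy number 0 is uniform on [0, 1];
    s >= 1 is a binomial mixture of Gaussian bands at k/s with boundary
    point masses at 0 and 1.  Missing BAF contributes log 1 = 0."""
    n = len(baf)
    out = np.zeros((n, len(COPY_NUMBERS)))
    sd = params.baf_sd
    missing = ~np.isfinite(baf)
    b = np.where(missing, 0.5, baf)
    at0 = b <= 0.0
    at1 = b >= 1.0
    interior = ~(at0 | at1)
    for si, s in enumerate(COPY_NUMBERS):
        if s == 0:
            continue  # uniform: log density 0 everywhere
        dens = np.zeros(n)
        for k in range(s + 1):
            w = sps.binom.pmf(k, s, pfb)
            mu = k / s
            dens += np.where(
                interior,
                w * sps.norm.pdf(b, mu, sd),
                np.where(at0, w * sps.norm.cdf((0.0 - mu) / sd), w * sps.norm.cdf((mu - 1.0) / sd)),
            )
        out[:, si] = np.log(np.maximum(dens, 1e-300))
    out[missing, :] = 0.0
    return out


def emission_logprob(
    lrr: np.ndarray, baf: np.ndarray, pfb: np.ndarray, params: HmmParams
) -> np.ndarray:
    """(n_snps, 5) total log-emission; missing LRR or BAF terms contribute
    log 1 = 0."""
    n = len(lrr)
    mu = np.asarray(params.lrr_mean)
    sd = np.asarray(params.lrr_sd)
    lrr_term = np.zeros((n, len(COPY_NUMBERS)))
    ok = np.isfinite(lrr)
    lrr_term[ok] = sps.norm.logpdf(lrr[ok, None], mu[None, :], sd[None, :])
    return lrr_term + baf_logpdf(baf, pfb, params)


def transition_logmatrices(gaps: np.ndarray, params: HmmParams) -> np.ndarray:
    """(n_gaps, 5, 5) log transition matrices for inter-SNP gaps in bp."""
    pi = np.asarray(params.pi)
    S = len(pi)
    mix = 1.0 - np.exp(-np.maximum(np.asarray(gaps, float), 1.0) / params.d_scale)
    T = mix[:, None, None] * pi[None, None, :] * np.ones((1, S, 1))
    di = np.arange(S)
    T[:, di, di] = 0.0
    T[:, di, di] = 1.0 - T.sum(axis=2)
    return np.log(np.maximum(T, 1e-300))


def transition_logmatrix(d: float, params: HmmParams) -> np.ndarray:
    """5x5 log transition matrix for an inter-SNP gap of d bp."""
    return transition_logmatrices(np.array([d]), params)[0]


def viterbi_path(loge: np.ndarray, logT: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    """Most probable state path.  ``loge`` is (n, S); ``logT`` is
    (n-1, S, S) per-step log transition matrices; ties break toward the
    lowest state index."""
    n, S = loge.shape
    delta = logpi + loge[0]
    back = np.zeros((n, S), dtype=np.int8)
    for i in range(1, n):
        cand = delta[:, None] + logT[i - 1]
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], np.arange(S)] + loge[i]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def viterbi_call(
    sample_id: str,
    lrr: np.ndarray,
    baf: np.ndarray,
    snp_map: pd.DataFrame,
    pfb: np.ndarray,
    params: HmmParams = HmmParams(),
) -> list[CnvCall]:
    """Decode one sample's (GC-corrected) signals chromosome by chromosome and
    emit maximal non-diploid runs as CNV calls.

    The confidence score of a call is the emission-only log-likelihood ratio
    of the called state against the diploid state, summed over the run's
    SNPs; SNPs with missing signals contribute 0.
    """
    calls: list[CnvCall] = []
    logpi = np.log(np.asarray(params.pi))
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            log.info("chromosome %s has <2 SNPs; skipped", chrom)
            continue
        pos = grp["pos"].to_numpy()
        loge = emission_logprob(lrr[idx], baf[idx], pfb[idx], params)
        logT = transition_logmatrices(np.diff(pos), params)
        path = viterbi_path(loge, logT, logpi)
        # maximal runs of non-diploid states
        i = 0
        while i < len(path):
            if path[i] == DIPLOID:
                i += 1
                continue
            j = i
            while j + 1 < len(path) and path[j + 1] == path[i]:
                j += 1
            conf = float(np.sum(loge[i: j + 1, path[i]] - loge[i: j + 1, DIPLOID]))
            calls.append(
                CnvCall(
                    sample_id=sample_id,
                    chrom=str(chrom),
                    start=int(pos[i]),
                    end=int(pos[j]),
                    start_idx=int(i),
                    end_idx=int(j),
                    state=int(COPY_NUMBERS[path[i]]),
                    n_snps=j - i + 1,
                    conf=conf,
                )
            )
            i = j + 1
    return calls


def signal_metrics(
    lrr: np.ndarray,
    baf: np.ndarray,
    snp_map: pd.DataFrame,
    snp_gc: np.ndarray,
    window: int = 1_000_000,
    min_snps: int = 100,
) -> SampleSignalMetrics:
    """Per-sample signal quality metrics on (corrected) autosomal signals.

    GCWF is the SD of the per-1 Mb-window median LRR, signed by the
    correlation between window median LRR and window GC content.
    """
    ok = np.isfinite(lrr)
    lrr_sd = float(np.std(lrr[ok], ddof=1)) if ok.sum() > 1 else np.nan
    bok = np.isfinite(baf)
    if bok.sum():
        b = baf[bok]
        drift = float(np.mean(((b > 0.2) & (b < 0.25)) | ((b > 0.75) & (b < 0.8))))
    else:
        drift = np.nan

    win = (
        snp_map.assign(lrr=lrr, gc=snp_gc, w=snp_map["pos"] // window)
        .groupby(["chrom", "w"])
        .agg(med_lrr=("lrr", "median"), gc=("gc", "mean"))
        .dropna()
    )
    if len(win) >= 3 and win["med_lrr"].std() > 0 and win["gc"].std() > 0:
        sign = np.sign(np.corrcoef(win["med_lrr"], win["gc"])[0, 1])
        gcwf = float(sign * win["med_lrr"].std(ddof=1))
    else:
        gcwf = 0.0
    return SampleSignalMetrics(
        lrr_sd=lrr_sd,
        baf_drift=drift,
        gcwf=gcwf,
        low_confidence=int(ok.sum()) < min_snps,
    )
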