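"""Synthetic herd generator: multi-parity test-day phenotypes with pedigree
structure, and SNP-array intensity signals carrying planted copy-number
variants.

The phenotype arm simulates the additive animal model the downstream REML
assumes: breeding values are drawn matrix-normally with the pedigree
relationship matrix A as row covariance and the genetic (co)variance of the
15 trait x parity combinations as column covariance; a test-day record is a
Wood lactation-curve mean plus the animal's breeding value, a
lactation-level environmental effect, and test-day noise.  Rule-violating
rows are injected at a configurable contamination rate so the edit rules are
testable; with zero contamination every record passes them (clean values are
truncated at +-2.5 total SD for this reason).

The intensity arm simulates a 100K-chip-like panel: exponentially spaced SNP
maps, a GC track with long-range autocorrelation, an LRR "genomic wave"
proportional to standardised window GC, and planted CNVs whose LRR/BAF are
drawn from the caller's own state emission model (shared parameter table),
so the caller is well-specified on its generator by construction —
misspecification studies vary the table.

Every output is a deterministic function of the configuration (including its
seed).  The generating truth (breeding values, variance components, planted
CNVs) is returned alongside for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cnv_hmm
from .cnv_hmm import HmmParams, IntensityPanel
from .dhi_pheno import TRAITS
from .genetic_params import a_matrix


def _corr(offdiag: float, k: int) -> np.ndarray:
    return np.full((k, k), offdiag) + (1.0 - offdiag) * np.eye(k)


def _default_ra(n_parities: int) -> np.ndarray:
    # cross-parity genetic correlation high (same trait re-expressed),
    # cross-trait moderate; Kronecker of two correlation matrices stays PSD
    return np.kron(_corr(0.50, len(TRAITS)), _corr(0.86, n_parities))


def _default_rp(n_parities: int) -> np.ndarray:
    return np.kron(_corr(0.35, len(TRAITS)), _corr(0.47, n_parities))


def _default_cnv_plan() -> list[tuple[float, int, int]]:
    """(carrier fraction, copy number, length in SNPs) per planted locus.
    State mix follows the dominant-duplication pattern of array surveys
    (mostly copy number 3); lengths 15-40 SNPs (~0.4-1 Mb at 25 kb
    spacing)."""
    return [
        (0.05, 3, 30), (0.08, 3, 18), (0.04, 3, 40), (0.06, 3, 22),
        (0.03, 3, 35), (0.07, 3, 15), (0.05, 3, 26), (0.04, 3, 33),
        (0.06, 3, 20), (0.03, 3, 38), (0.05, 3, 16), (0.04, 3, 28),
        (0.05, 4, 24), (0.03, 4, 31), (0.06, 1, 19), (0.04, 1, 36),
        (0.03, 0, 15), (0.05, 3, 21), (0.04, 3, 29), (0.06, 3, 17),
    ]


@dataclass
class SimConfig:
    """Configuration of the synthetic herd; defaults are the package's
    standard study conditions."""

    # phenotype arm
    n_cows: int = 500
    n_parities: int = 3
    h2: tuple = (0.30, 0.30, 0.25, 0.35, 0.25)  # per trait
    ra_matrix: np.ndarray | None = None  # (5*n_parities)^2, trait-major
    rp_targets: np.ndarray | None = None
    sd_cow: tuple = (5.2, 0.62, 0.26, 0.23, 0.16)  # between-cow SD per trait
    sd_testday: tuple = (3.0, 0.45, 0.15, 0.13, 0.10)
    parity_means: tuple = (
        (30.39, 36.28, 36.94),  # milk kg/d
        (3.84, 3.91, 3.97),  # fat %
        (1.17, 1.41, 1.46),  # fat kg/d
        (3.27, 3.29, 3.30),  # protein %
        (1.00, 1.18, 1.21),  # protein kg/d
    )
    curve_shapes: tuple = (  # Wood (b, c) per trait: y = a * t^b * exp(-c t)
        (0.20, 0.0035),
        (-0.06, -0.0006),
        (0.18, 0.0030),
        (-0.04, -0.0004),
        (0.18, 0.0030),
    )
    participation: tuple = (1.0, 0.55, 0.50)  # nested fraction per parity
    contamination_rate: float = 0.0
    n_sires: int | None = None
    n_dams: int | None = None

    # intensity arm
    n_samples: int = 200
    n_snps: int = 5000
    n_chromosomes: int = 5
    snp_spacing_bp: float = 25_000.0
    cnv_plan: list = field(default_factory=_default_cnv_plan)
    lrr_noise_sd: tuple = (1.3, 0.28, 0.16, 0.21, 0.24)  # per state
    lrr_means: tuple = (-3.5, -0.66, 0.0, 0.40, 0.68)
    baf_sd: float = 0.04
    gc_wave_amplitude: float = 0.10
    missing_rate: float = 0.005

    seed: int = 0

    def __post_init__(self):
        k = len(TRAITS) * self.n_parities
        if self.ra_matrix is None:
            self.ra_matrix = _default_ra(self.n_parities)
        if self.rp_targets is None:
            self.rp_targets = _default_rp(self.n_parities)
        self.ra_matrix = np.asarray(self.ra_matrix, float)
        self.rp_targets = np.asarray(self.rp_targets, float)
        for name, M in (("ra_matrix", self.ra_matrix), ("rp_targets", self.rp_targets)):
            if M.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k} (trait-major combos)")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(M), 1.0):
                raise ValueError(f"{name} must have unit diagonal")
            w = np.linalg.eigvalsh(M)
            if w.min() < -1e-9:
                raise ValueError(
                    f"{name} is not positive semi-definite: "
                    f"minimum eigenvalue {w.min():.6g}"
                )
        for h in self.h2:
            if not 0.0 <= h < 1.0:
                raise ValueError("heritabilities must lie in [0, 1)")
        for frac, cn, length in self.cnv_plan:
            if length < 1:
                raise ValueError("cnv_plan lengths must be >= 1")
            if cn not in (0, 1, 3, 4):
                raise ValueError("cnv_plan copy numbers must be in {0, 1, 3, 4}")
            if not 0 < frac <= 1:
                raise ValueError("cnv_plan carrier fractions must be in (0, 1]")

    def hmm_params(self) -> HmmParams:
        """The emission/transition table shared with the caller."""
        return HmmParams(
            lrr_mean=tuple(self.lrr_means),
            lrr_sd=tuple(self.lrr_noise_sd),
            baf_sd=self.baf_sd,
        )

    def combo_index(self, trait: str, parity: int) -> int:
        return TRAITS.index(trait) * self.n_parities + (parity - 1)

    @property
    def combo_names(self) -> list[str]:
        return [f"{t}_p{p}" for t in TRAITS for p in range(1, self.n_parities + 1)]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("cnv_plan",):
            if key in raw:
                raw[key] = [tuple(item) for item in raw[key]]
        return cls(**raw)


@dataclass
class TruthSet:
    """Generating truth for recovery testing."""

    breeding_values: pd.DataFrame | None = None  # cow x combo
    variance_components: dict | None = None
    planted_cnvs: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# phenotype arm
# ---------------------------------------------------------------------------


def _genetic_cov(config: SimConfig) -> np.ndarray:
    sa = np.array(
        [np.sqrt(config.h2[t]) * config.sd_cow[t] for t in range(len(TRAITS))]
    ).repeat(config.n_parities)
    return np.outer(sa, sa) * config.ra_matrix


def _env_cov(config: SimConfig) -> np.ndarray:
    """Lactation-environment covariance implied by the phenotypic targets:
    Cov_E = Cov_P - Cov_A, bent to the nearest PSD correlation if needed."""
    sp = np.array(config.sd_cow).repeat(config.n_parities)
    se = np.sqrt(
        np.array([1.0 - h for h in config.h2]).repeat(config.n_parities)
    ) * sp
    cov_e = np.outer(sp, sp) * config.rp_targets - _genetic_cov(config)
    # normalise to a correlation, bend, restore the target scale
    d = np.sqrt(np.diag(cov_e))
    if (d <= 0).any():
        raise ValueError("phenotypic targets imply non-positive residual variance")
    corr = cov_e / np.outer(d, d)
    w, V = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() < 0:
        w = np.maximum(w, 1e-6)
        corr = (V * w) @ V.T
        dd = np.sqrt(np.diag(corr))
        corr = corr / np.outer(dd, dd)
    return np.outer(se, se) * corr


def simulate_pedigree(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Two-generation pedigree: unrelated founder sires/dams, recorded cows
    as offspring of random matings (so paternal and maternal sib families
    carry the additive signal).

    Defaults give paternal half-sib families of ~10 and maternal families of
    ~3 — typical of AI-bred herds, and enough family replication to keep the
    additive (co)variances identifiable at a few hundred cows.
    """
    n_sires = config.n_sires or max(4, config.n_cows // 10)
    n_dams = config.n_dams or max(8, config.n_cows // 3)
    sires = [f"S{i+1}" for i in range(n_sires)]
    dams = [f"D{i+1}" for i in range(n_dams)]
    cows = [f"C{i+1}" for i in range(config.n_cows)]
    rows = [{"id": s, "sire": 0, "dam": 0} for s in sires + dams]
    for c in cows:
        rows.append(
            {
                "id": c,
                "sire": sires[rng.integers(n_sires)],
                "dam": dams[rng.integers(n_dams)],
            }
        )
    return pd.DataFrame(rows)


def simulate_breeding_values(
    config: SimConfig, pedigree: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Matrix-normal breeding values: row covariance A, column covariance the
    genetic (co)variance across trait x parity combinations."""
    ids, A = a_matrix(pedigree)
    La = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
    G0 = _genetic_cov(config)
    # h2 = 0 traits have zero variance: use eigen square root
    w, V = np.linalg.eigh(G0)
    Lg = V * np.sqrt(np.maximum(w, 0.0))
    U = La @ rng.standard_normal((len(ids), G0.shape[0])) @ Lg.T
    return pd.DataFrame(U, index=ids, columns=config.combo_names)


def simulate_pedigree_phenotypes(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Simulate the pedigree, breeding values and DHI test-day records.

    Returns (pedigree, records, truth).  Records carry the columns the DHI
    filter expects; with ``contamination_rate > 0`` a matching fraction of
    rows (and cows, for the calving-age rule) deliberately violate the edit
    rules.
    """
    rng = np.random.default_rng([config.seed, 1])
    nt, npar = len(TRAITS), config.n_parities
    pedigree = simulate_pedigree(config, rng)
    bv = simulate_breeding_values(config, pedigree, rng)
    cows = [i for i in pedigree["id"] if str(i).startswith("C")]
    U = bv.loc[cows].to_numpy()

    E = rng.standard_normal((len(cows), nt * npar)) @ np.linalg.cholesky(
        _env_cov(config) + 1e-12 * np.eye(nt * npar)
    ).T

    # Wood curve scale per trait x parity, calibrated on the canonical grid
    grid = np.arange(5.0, 306.0)
    scale = np.zeros((nt, npar))
    shape_mean = np.zeros(nt)
    for t in range(nt):
        b, c = config.curve_shapes[t]
        shape = grid**b * np.exp(-c * grid)
        shape_mean[t] = shape.mean()
        for p in range(npar):
            scale[t, p] = config.parity_means[t][p] / shape_mean[t]

    # total-SD clip bounds so clean data survive the +-3 SD rule
    clip_lo = np.zeros((nt, npar))
    clip_hi = np.zeros((nt, npar))
    for t in range(nt):
        b, c = config.curve_shapes[t]
        for p in range(npar):
            curve = scale[t, p] * grid**b * np.exp(-c * grid)
            tot_sd = np.sqrt(
                curve.var() + config.sd_cow[t] ** 2 + config.sd_testday[t] ** 2
            )
            m = config.parity_means[t][p]
            clip_lo[t, p] = m - 2.5 * tot_sd
            clip_hi[t, p] = m + 2.5 * tot_sd
    clip_lo[0] = np.maximum(clip_lo[0], 5.2)  # daily milk floor above the edit bound
    clip_hi[0] = np.minimum(clip_hi[0], 79.8)
    clip_lo[[2, 4]] = np.maximum(clip_lo[[2, 4]], 0.05)
    clip_lo[[1, 3]] = np.maximum(clip_lo[[1, 3]], 0.3)

    afc = np.clip(rng.normal(27.0, 2.5, len(cows)), 22.5, 35.5)
    bad_afc = rng.random(len(cows)) < config.contamination_rate
    afc[bad_afc] = rng.choice([20.5, 37.5], bad_afc.sum())

    # lactation schedules
    cow_idx_col, parity_col, dim_col = [], [], []
    in_parity = np.ones(len(cows), bool)
    for p in range(npar):
        if p > 0:
            in_parity &= rng.random(len(cows)) < (
                config.participation[p] / config.participation[p - 1]
            )
        for ci in np.nonzero(in_parity)[0]:
            d = int(rng.integers(5, 35))
            while d <= 305:
                cow_idx_col.append(ci)
                parity_col.append(p + 1)
                dim_col.append(d)
                d += int(30 + rng.integers(-3, 4))
    cow_idx = np.array(cow_idx_col)
    parity = np.array(parity_col)
    dim = np.array(dim_col, float)
    n_rec = len(dim)

    data = {
        "cow_id": np.array(cows)[cow_idx],
        "parity": parity,
        "afc_months": afc[cow_idx],
        "dim": dim.astype(int),
    }
    for t, trait in enumerate(TRAITS):
        b, c = config.curve_shapes[t]
        curve = scale[t, parity - 1] * dim**b * np.exp(-c * dim)
        combo = t * npar + (parity - 1)
        y = curve + U[cow_idx, combo] + E[cow_idx, combo]
        y += rng.normal(0.0, config.sd_testday[t], n_rec)
        y = np.clip(y, clip_lo[t, parity - 1], clip_hi[t, parity - 1])
        data[trait] = y
    data["scs"] = np.clip(rng.normal(3.0, 1.3, n_rec), 0.1, 8.9)
    records = pd.DataFrame(data)

    # row-level contamination: one deliberate rule violation per hit row
    hit = np.nonzero(rng.random(n_rec) < config.contamination_rate)[0]
    kinds = rng.integers(0, 6, len(hit))
    for row, kind in zip(hit, kinds):
        if kind == 0:
            records.loc[row, "dim"] = int(rng.integers(1, 5))
        elif kind == 1:
            records.loc[row, "dim"] = int(rng.integers(306, 350))
        elif kind == 2:
            records.loc[row, "my"] = float(rng.uniform(81.0, 95.0))
        elif kind == 3:
            records.loc[row, "scs"] = float(rng.uniform(9.1, 11.0))
        elif kind == 4:
            records.loc[row, "parity"] = int(rng.integers(4, 6))
        else:  # +-3 SD outlier in one composition trait
            t = int(rng.integers(1, 5))
            p = int(records.loc[row, "parity"]) - 1
            m = config.parity_means[t][p]
            span = clip_hi[t, p] - m
            records.loc[row, TRAITS[t]] = m + float(rng.uniform(1.3, 1.6)) * span

    g_cov = _genetic_cov(config)
    e_cov = _env_cov(config)
    truth = TruthSet(
        breeding_values=bv,
        variance_components={
            "combo_names": config.combo_names,
            "sigma_a2": dict(zip(config.combo_names, np.diag(g_cov))),
            "sigma_e2": dict(zip(config.combo_names, np.diag(e_cov))),
            "h2": dict(zip(TRAITS, config.h2)),
            "ra_matrix": config.ra_matrix,
            "genetic_cov": g_cov,
            "env_cov": e_cov,
        },
    )
    return pedigree, records, truth


# ---------------------------------------------------------------------------
# intensity arm
# ---------------------------------------------------------------------------


def _simulate_map_and_gc(config: SimConfig, rng: np.random.Generator):
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    rows = []
    gc_rows = []
    lengths: dict[str, int] = {}
    win = 500_000
    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        gaps = rng.exponential(config.snp_spacing_bp, per_chrom[ci]) + 100.0
        pos = np.cumsum(gaps).astype(np.int64) + 1
        for k, p in enumerate(pos):
            rows.append({"name": f"snp_{chrom}_{k+1}", "chrom": chrom, "pos": int(p)})
        length = int(pos[-1] + config.snp_spacing_bp)
        lengths[chrom] = length
        n_win = int(np.ceil(length / win))
        g = np.empty(n_win)
        g[0] = rng.standard_normal()
        for w in range(1, n_win):
            g[w] = 0.7 * g[w - 1] + np.sqrt(1 - 0.49) * rng.standard_normal()
        gc = np.clip(0.45 + 0.05 * g, 0.30, 0.60)
        for w in range(n_win):
            gc_rows.append(
                {
                    "chrom": chrom,
                    "start": w * win,
                    "end": min((w + 1) * win, length),
                    "gc_fraction": gc[w],
                }
            )
    snp_map = pd.DataFrame(rows)
    gc_track = pd.DataFrame(gc_rows)
    return snp_map, gc_track, lengths


def simulate_intensities(
    config: SimConfig,
) -> tuple[pd.DataFrame, IntensityPanel, pd.DataFrame, TruthSet]:
    """Simulate the SNP map, GC track and per-sample LRR/BAF signals with
    planted CNVs.

    Background (diploid) LRR is Gaussian noise plus the GC wave
    (``gc_wave_amplitude`` x standardised window GC); BAF clusters at
    {0, 1/2, 1} by the simulated genotype.  Inside planted CNVs both signals
    come from the caller's state emission model.  Planted regions never
    overlap within a sample and must fit their chromosome.
    """
    rng = np.random.default_rng([config.seed, 2])
    snp_map, gc_track, lengths = _simulate_map_and_gc(config, rng)
    n, m = config.n_samples, len(snp_map)
    params = config.hmm_params()

    snp_gc = cnv_hmm.snp_window_gc(snp_map, gc_track)
    gcz = (snp_gc - snp_gc.mean()) / snp_gc.std()
    wave = config.gc_wave_amplitude * gcz

    pfb_true = rng.uniform(0.05, 0.95, m)

    chrom_of = snp_map["chrom"].to_numpy()
    chrom_start = {c: int(np.nonzero(chrom_of == c)[0][0]) for c in lengths}
    chrom_n = {c: int((chrom_of == c).sum()) for c in lengths}

    # place planted loci without overlap (3-SNP margin)
    sample_ids = [f"C{i+1}" for i in range(n)]
    state = np.full((n, m), 2, dtype=np.int8)
    used: list[tuple[int, int]] = []
    planted = []
    for frac, cn, length in config.cnv_plan:
        candidates = [c for c in lengths if chrom_n[c] >= length + 2]
        if not candidates:
            raise ValueError(
                f"cnv_plan region of {length} SNPs exceeds every chromosome span"
            )
        placed = False
        for _ in range(200):
            chrom = candidates[rng.integers(len(candidates))]
            lo = chrom_start[chrom]
            i0 = int(rng.integers(lo + 1, lo + chrom_n[chrom] - length))
            i1 = i0 + length - 1
            if all(i1 + 3 < s or e + 3 < i0 for s, e in used):
                placed = True
                break
        if not placed:
            raise ValueError("could not place cnv_plan regions without overlap")
        used.append((i0, i1))
        carriers = rng.choice(n, size=max(1, int(round(frac * n))), replace=False)
        state[np.ix_(carriers, np.arange(i0, i1 + 1))] = cn
        for s in carriers:
            planted.append(
                {
                    "sample_id": sample_ids[s],
                    "chrom": chrom,
                    "start": int(snp_map["pos"].iloc[i0]),
                    "end": int(snp_map["pos"].iloc[i1]),
                    "cn": cn,
                    "n_snps": length,
                    "start_idx": i0 - chrom_start[chrom],
                    "end_idx": i1 - chrom_start[chrom],
                }
            )

    # signals
    geno = rng.binomial(2, np.broadcast_to(pfb_true, (n, m)))
    lrr = rng.normal(
        np.asarray(params.lrr_mean)[state], np.asarray(params.lrr_sd)[state]
    ) + wave[None, :]
    k = np.where(state == 2, geno, rng.binomial(np.maximum(state, 1), pfb_true[None, :]))
    with np.errstate(invalid="ignore", divide="ignore"):
        centers = np.where(state > 0, k / np.maximum(state, 1), 0.0)
    baf = np.clip(centers + rng.normal(0.0, params.baf_sd, (n, m)), 0.0, 1.0)
    cn0 = state == 0
    baf[cn0] = rng.uniform(0.0, 1.0, int(cn0.sum()))

    gtype = np.array(["AA", "AB", "BB"], dtype=object)[geno]
    miss = rng.random((n, m)) < config.missing_rate
    gtype[miss] = "NC"

    panel = IntensityPanel(
        snp_map=snp_map, sample_ids=sample_ids, lrr=lrr, baf=baf, gtype=gtype
    )
    truth = TruthSet(
        planted_cnvs=pd.DataFrame(
            planted,
            columns=[
                "sample_id", "chrom", "start", "end", "cn", "n_snps",
                "start_idx", "end_idx",
            ],
        )
    )
    return snp_map, panel, gc_track, truth


def chrom_lengths_from_track(gc_track: pd.DataFrame) -> dict[str, int]:
    return gc_track.groupby("chrom")["end"].max().astype(int).to_dict()


def genotype_panel_from_intensities(panel: IntensityPanel):
    """B-allele dosage panel (for snp_qc) from the simulated genotype calls."""
    from .snp_qc import GenotypePanel

    code = {"AA": 0, "AB": 1, "BB": 2, "NC": -1}
    g = np.vectorize(code.__getitem__, otypes=[np.int8])(panel.gtype)
    return GenotypePanel(
        snp_map=panel.snp_map.copy(), genotypes=g, sample_ids=list(panel.sample_ids)
    )


def recovery_stats(
    planted: pd.DataFrame, calls, min_reciprocal_overlap: float = 0.5
) -> dict:
    """Sensitivity/precision of a call set against the planted truth at a
    reciprocal-overlap threshold, requiring the gain/loss direction to
    match."""
    def _dir(cn):
        return 1 if cn > 2 else -1

    calls_by_sample: dict = {}
    for c in calls:
        calls_by_sample.setdefault((c.sample_id, c.chrom), []).append(c)

    matched_calls = set()
    n_found = 0
    for _, t in planted.iterrows():
        found = False
        for c in calls_by_sample.get((t["sample_id"], str(t["chrom"])), []):
            ov = min(c.end, t["end"]) - max(c.start, t["start"]) + 1
            if ov <= 0 or _dir(c.state) != _dir(t["cn"]):
                continue
            if (
                ov / (t["end"] - t["start"] + 1) >= min_reciprocal_overlap
                and ov / (c.end - c.start + 1) >= min_reciprocal_overlap
            ):
                found = True
                matched_calls.add(id(c))
        n_found += found
    n_calls = sum(len(v) for v in calls_by_sample.values())
    return {
        "n_planted": len(planted),
        "n_calls": n_calls,
        "sensitivity": n_found / len(planted) if len(planted) else np.nan,
        "precision": len(matched_calls) / n_calls if n_calls else np.nan,
    }
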