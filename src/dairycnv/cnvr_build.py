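"""CNV call quality control, same-sample merging, and CNVR construction.

The study's six CNV quality criteria are applied first: three sample-level
signal criteria (LRR SD < 0.3, BAF drift < 0.01, |GCWF| < 0.05) remove every
call of a failing sample, two call-level criteria (confidence > 10, >= 10
SNPs) remove individual calls, and calls seen in only one individual (no SNP
shared with any other sample's retained call) are removed last.

Same-sample adjacent calls of the same direction (both gains or both losses)
whose overlap is at least 20% of their union span are merged, to a fixed
point.  Across samples, calls sharing at least one SNP are transitively
grouped into CNV regions (CNVRs) spanning the outermost member coordinates;
regions carried by a single sample are dropped, and the survivors are
numbered CNVR_1, CNVR_2, ... in genome order and classified Gain / Loss /
Mixed from their member states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cnv_hmm import DIPLOID, CnvCall, SampleSignalMetrics


@dataclass(frozen=True)
class CnvQcCriteria:
    max_lrr_sd: float = 0.3  # strict <
    max_baf_drift: float = 0.01  # strict <
    max_abs_gcwf: float = 0.05  # strict <
    min_conf: float = 10.0  # strict >
    min_snps: int = 10  # inclusive >=
    min_carriers: int = 2


@dataclass
class Cnvr:
    """Cross-sample merged copy-number region (1-based inclusive)."""

    id: str
    chrom: str
    start: int
    end: int
    type: str  # Gain / Loss / Mixed
    calls: list[CnvCall] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def carriers(self) -> dict:
        """Carrier sample -> copy-number state (of its longest member call)."""
        best: dict = {}
        for c in self.calls:
            if c.sample_id not in best or c.length > best[c.sample_id].length:
                best[c.sample_id] = c
        return {s: c.state for s, c in best.items()}

    @property
    def n_samples(self) -> int:
        return len({c.sample_id for c in self.calls})


def _direction(state: int) -> int:
    return 1 if state > DIPLOID else -1


def qc_cnvs(
    calls: list[CnvCall],
    metrics: dict[str, SampleSignalMetrics],
    criteria: CnvQcCriteria = CnvQcCriteria(),
) -> tuple[list[CnvCall], dict[str, int]]:
    """Apply the six QC criteria; returns retained calls and a per-criterion
    removal audit (first-triggering attribution, in the listed order)."""
    audit = {k: 0 for k in ("sample_signal", "confidence", "n_snps", "singleton")}
    kept: list[CnvCall] = []
    for c in calls:
        m = metrics.get(c.sample_id)
        if m is None or not (
            m.lrr_sd < criteria.max_lrr_sd
            and m.baf_drift < criteria.max_baf_drift
            and abs(m.gcwf) < criteria.max_abs_gcwf
        ):
            audit["sample_signal"] += 1
        elif not c.conf > criteria.min_conf:
            audit["confidence"] += 1
        elif c.n_snps < criteria.min_snps:
            audit["n_snps"] += 1
        else:
            kept.append(c)

    # criterion (6): must share >= 1 SNP with another sample's retained call
    final: list[CnvCall] = []
    for c in kept:
        shared = any(
            o.chrom == c.chrom
            and o.sample_id != c.sample_id
            and o.start_idx <= c.end_idx
            and c.start_idx <= o.end_idx
            for o in kept
        )
        if shared or criteria.min_carriers <= 1:
            final.append(c)
        else:
            audit["singleton"] += 1
    return final, audit


def _try_merge(a: CnvCall, b: CnvCall, min_overlap: float) -> CnvCall | None:
    if a.chrom != b.chrom or _direction(a.state) != _direction(b.state):
        return None
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    union = max(a.end, b.end) - min(a.start, b.start) + 1
    if ov <= 0 or ov / union < min_overlap:
        return None
    major = a if a.length >= b.length else b
    return replace(
        major,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        start_idx=min(a.start_idx, b.start_idx),
        end_idx=max(a.end_idx, b.end_idx),
        n_snps=max(a.end_idx, b.end_idx) - min(a.start_idx, b.start_idx) + 1,
        conf=a.conf + b.conf,
    )


def merge_same_sample(calls: list[CnvCall], min_overlap: float = 0.20) -> list[CnvCall]:
    """Merge a sample's adjacent same-direction calls whose overlap is at
    least ``min_overlap`` of the union span; repeated to a fixed point.
    Input order does not matter; output is genome-sorted per sample."""
    out: list[CnvCall] = []
    groups: dict = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.chrom), []).append(c)
    for _, grp in sorted(groups.items(), key=lambda kv: kv[0]):
        grp = sorted(grp, key=lambda c: (c.start, c.end))
        changed = True
        while changed:
            changed = False
            merged: list[CnvCall] = []
            i = 0
            while i < len(grp):
                if i + 1 < len(grp):
                    m = _try_merge(grp[i], grp[i + 1], min_overlap)
                    if m is not None:
                        merged.append(m)
                        merged.extend(grp[i + 2:])
                        changed = True
                        break
                merged.append(grp[i])
                i += 1
            grp = sorted(merged, key=lambda c: (c.start, c.end))
        out.extend(grp)
    return out


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


def build_cnvrs(calls: list[CnvCall], min_carriers: int = 2) -> list[Cnvr]:
    """Group calls sharing >= 1 SNP (transitively, per chromosome) into
    CNVRs; drop regions carried by fewer than ``min_carriers`` distinct
    samples; number survivors in genome order."""
    by_chrom: dict = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)

    regions: list[Cnvr] = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        grp = sorted(by_chrom[chrom], key=lambda c: (c.start_idx, c.end_idx))
        comp: list[CnvCall] = []
        max_end = -1
        for c in grp + [None]:
            if c is not None and (not comp or c.start_idx <= max_end):
                comp.append(c)
                max_end = max(max_end, c.end_idx)
                continue
            if comp:
                states = {m.state for m in comp}
                if all(s > DIPLOID for s in states):
                    kind = "Gain"
                elif all(s < DIPLOID for s in states):
                    kind = "Loss"
                else:
                    kind = "Mixed"
                regions.append(
                    Cnvr(
                        id="",
                        chrom=str(chrom),
                        start=min(m.start for m in comp),
                        end=max(m.end for m in comp),
                        type=kind,
                        calls=list(comp),
                    )
                )
            if c is not None:
                comp = [c]
                max_end = c.end_idx
    regions = [r for r in regions if r.n_samples >= min_carriers]
    for k, r in enumerate(regions, start=1):
        r.id = f"CNVR_{k}"
    return regions


def summarize(
    calls: list[CnvCall],
    cnvrs: list[Cnvr],
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-state CNV count/length table (with percentages) and per-chromosome
    CNVR coverage fractions.  Coverage is the union of CNVR spans divided by
    the chromosome length (undefined when the length is missing)."""
    rows = []
    total = len(calls)
    for state in (0, 1, 3, 4):
        lens = [c.length for c in calls if c.state == state]
        rows.append(
            {
                "state": state,
                "count": len(lens),
                "pct": 100.0 * len(lens) / total if total else np.nan,
                "mean_length": float(np.mean(lens)) if lens else np.nan,
                "min_length": min(lens) if lens else np.nan,
                "max_length": max(lens) if lens else np.nan,
            }
        )
    state_table = pd.DataFrame(rows)

    cov_rows = []
    by_chrom: dict = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        spans = sorted((r.start, r.end) for r in by_chrom[chrom])
        covered = 0
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        covered += cur_e - cur_s + 1
        length = (chrom_lengths or {}).get(chrom)
        cov_rows.append(
            {
                "chrom": chrom,
                "n_cnvrs": len(by_chrom[chrom]),
                "covered_bp": covered,
                "coverage": covered / length if length else np.nan,
            }
        )
    return state_table, pd.DataFrame(cov_rows)
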