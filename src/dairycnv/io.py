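"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated.  Intensity data use the Illumina
Final-Report-style long format (Sample ID / SNP Name / Chr / Position /
GType / Log R Ratio / B Allele Freq); CNV calls use a PennCNV-like one-line
format::

    chr1:1000-2000  numsnp=15  length=1001  state3,cn=3  SAMPLE  startsnp=4  endsnp=18  conf=23.1
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .cnv_hmm import CnvCall, IntensityPanel
from .cnvr_build import Cnvr

FINAL_REPORT_COLUMNS = [
    "Sample ID", "SNP Name", "Chr", "Position", "GType", "Log R Ratio", "B Allele Freq",
]


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    return df.fillna("0")


def write_dhi(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dhi(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cow_id": str})


def write_gc_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gc_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_final_report(panel: IntensityPanel, path) -> None:
    n, m = panel.lrr.shape
    long = pd.DataFrame(
        {
            "Sample ID": np.repeat(panel.sample_ids, m),
            "SNP Name": np.tile(panel.snp_map["name"].to_numpy(), n),
            "Chr": np.tile(panel.snp_map["chrom"].to_numpy(), n),
            "Position": np.tile(panel.snp_map["pos"].to_numpy(), n),
            "GType": (panel.gtype if panel.gtype is not None else np.full((n, m), "NC")).ravel(),
            "Log R Ratio": np.round(panel.lrr.ravel(), 4),
            "B Allele Freq": np.round(panel.baf.ravel(), 4),
        }
    )
    long.to_csv(path, sep="\t", index=False)


def read_final_report(path) -> IntensityPanel:
    df = pd.read_csv(path, sep="\t", dtype={"Sample ID": str, "Chr": str})
    snp_map = (
        df[["SNP Name", "Chr", "Position"]]
        .drop_duplicates("SNP Name")
        .rename(columns={"SNP Name": "name", "Chr": "chrom", "Position": "pos"})
        .sort_values(["chrom", "pos"], key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s)
        .reset_index(drop=True)
    )
    order = {nm: i for i, nm in enumerate(snp_map["name"])}
    samples = list(dict.fromkeys(df["Sample ID"]))
    srow = {s: i for i, s in enumerate(samples)}
    n, m = len(samples), len(snp_map)
    lrr = np.full((n, m), np.nan)
    baf = np.full((n, m), np.nan)
    gtype = np.full((n, m), "NC", dtype=object)
    ri = df["Sample ID"].map(srow).to_numpy()
    ci = df["SNP Name"].map(order).to_numpy()
    lrr[ri, ci] = df["Log R Ratio"].to_numpy(float)
    baf[ri, ci] = df["B Allele Freq"].to_numpy(float)
    gtype[ri, ci] = df["GType"].to_numpy()
    return IntensityPanel(snp_map=snp_map, sample_ids=samples, lrr=lrr, baf=baf, gtype=gtype)


def _chrom_key(c):
    return (0, int(c)) if str(c).isdigit() else (1, 0)


_CALL_RE = re.compile(
    r"chr(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+numsnp=(?P<numsnp>\d+)\s+"
    r"length=(?P<length>\d+)\s+state\d*,cn=(?P<cn>\d+)\s+(?P<sample>\S+)\s+"
    r"startsnp=(?P<startsnp>\d+)\s+endsnp=(?P<endsnp>\d+)\s+conf=(?P<conf>\S+)"
)


def write_calls(calls: list[CnvCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"chr{c.chrom}:{c.start}-{c.end}\tnumsnp={c.n_snps}\t"
                f"length={c.length}\tstate{c.state},cn={c.state}\t{c.sample_id}\t"
                f"startsnp={c.start_idx}\tendsnp={c.end_idx}\tconf={c.conf:.3f}\n"
            )


def read_calls(path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            m = _CALL_RE.match(line)
            if m is None:
                raise ValueError(f"unparseable CNV call line: {line!r}")
            d = m.groupdict()
            calls.append(
                CnvCall(
                    sample_id=d["sample"],
                    chrom=d["chrom"],
                    start=int(d["start"]),
                    end=int(d["end"]),
                    start_idx=int(d["startsnp"]),
                    end_idx=int(d["endsnp"]),
                    state=int(d["cn"]),
                    n_snps=int(d["numsnp"]),
                    conf=float(d["conf"]),
                )
            )
    return calls


def write_cnvrs(cnvrs: list[Cnvr], path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "id": r.id,
            "type": r.type,
            "size": r.size,
            "n_samples": r.n_samples,
        }
        for r in cnvrs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_l305(l305: pd.DataFrame, path) -> None:
    l305.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_l305(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cow_id": str})
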