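"""CNVR-trait association by one-way GLM with FDR control.

Each sample is assigned a three-level CNVR genotype class — loss (copy number
< 2), normal (no retained call), gain (> 2) — and each 305-day milk trait is
tested against the class factor with the one-way ANOVA F-test implied by the
model ``y = mu + G_i + e_i``.  Raw p-values are adjusted per trait across
CNVRs by the Benjamini-Hochberg step-up procedure, and regions with adjusted
p (q) below 0.05 are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cnv_hmm import DIPLOID, CnvCall
from .cnvr_build import Cnvr

CLASSES = ("loss", "normal", "gain")


def code_genotypes(
    cnvrs: list[Cnvr], calls: list[CnvCall], sample_ids: list
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-sample CNVR genotype classes.

    A sample carrying a call inside a CNVR is 'loss' or 'gain' by the call's
    direction; samples without a retained call are 'normal'.  A sample with
    both gain and loss calls in one CNVR takes the class of the longer
    aggregate span; exact ties are excluded (None) and flagged.
    """
    df = pd.DataFrame("normal", index=list(sample_ids), columns=[r.id for r in cnvrs])
    flagged: list[tuple[str, str]] = []
    for r in cnvrs:
        spans: dict[str, dict[int, int]] = {}
        for c in r.calls:
            d = spans.setdefault(c.sample_id, {1: 0, -1: 0})
            d[1 if c.state > DIPLOID else -1] += c.length
        for s, d in spans.items():
            if s not in df.index:
                continue
            if d[1] > d[-1]:
                df.loc[s, r.id] = "gain"
            elif d[-1] > d[1]:
                df.loc[s, r.id] = "loss"
            else:
                df.loc[s, r.id] = None
                flagged.append((s, r.id))
    return df, flagged


def glm_anova(
    y: np.ndarray, classes: np.ndarray, min_class_n: int = 3
) -> dict:
    """One-way ANOVA of a trait on the CNVR genotype factor.

    Classes with fewer than ``min_class_n`` observations are dropped.  With
    fewer than two usable classes the test is skipped and p is NaN (not 1).
    Returns F, p, per-class means and counts, and the degrees of freedom.
    """
    y = np.asarray(y, float)
    classes = np.asarray(classes, object)
    ok = np.isfinite(y) & pd.notna(classes)
    y, classes = y[ok], classes[ok]
    groups = []
    means, ns = {}, {}
    for cls in CLASSES:
        vals = y[classes == cls]
        if len(vals):
            means[cls] = float(vals.mean())
            ns[cls] = int(len(vals))
        if len(vals) >= min_class_n:
            groups.append(vals)
    if len(groups) < 2:
        return {"F": np.nan, "p": np.nan, "means": means, "n": ns, "df": (np.nan, np.nan)}
    if all(np.all(g == groups[0][0]) for g in groups):
        # identical values in every class: no between- or within-group variance
        k = len(groups)
        n = sum(len(g) for g in groups)
        return {"F": 0.0, "p": 1.0, "means": means, "n": ns, "df": (k - 1, n - k)}
    F, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return {"F": float(F), "p": float(p), "means": means, "n": ns, "df": (k - 1, n - k)}


def fdr_adjust(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (or Benjamini-Yekutieli) adjusted p-values with
    step-up monotonicity; NaN inputs give NaN outputs."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    meth = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method=meth)[1]
    return q


def associate(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    traits: list[str],
    min_class_n: int = 3,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Test every CNVR against every trait; adjust p per trait across CNVRs.

    ``genotypes`` is samples x CNVR-ids (from :func:`code_genotypes`);
    ``phenotypes`` is indexed by sample with one column per trait.
    """
    common = genotypes.index.intersection(phenotypes.index)
    rows = []
    for trait in traits:
        y = phenotypes.loc[common, trait].to_numpy(float)
        for cnvr_id in genotypes.columns:
            res = glm_anova(y, genotypes.loc[common, cnvr_id].to_numpy(), min_class_n)
            rows.append(
                {
                    "trait": trait,
                    "cnvr_id": cnvr_id,
                    "F": res["F"],
                    "p": res["p"],
                    "n_loss": res["n"].get("loss", 0),
                    "n_normal": res["n"].get("normal", 0),
                    "n_gain": res["n"].get("gain", 0),
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for trait in traits:
        sel = out["trait"] == trait
        out.loc[sel, "q"] = fdr_adjust(out.loc[sel, "p"].to_numpy(), fdr_method)
    out["significant"] = out["q"] < 0.05
    return out


def report(
    results: pd.DataFrame, cnvrs: list[Cnvr] | None = None, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Significant associations grouped by trait, plus explicit per-trait
    counts (zero rows included)."""
    info = {r.id: r for r in (cnvrs or [])}
    sig = results[results["q"] < alpha].copy()
    if info:
        sig["chrom"] = [info[i].chrom if i in info else None for i in sig["cnvr_id"]]
        sig["start"] = [info[i].start if i in info else None for i in sig["cnvr_id"]]
        sig["end"] = [info[i].end if i in info else None for i in sig["cnvr_id"]]
        sig["size"] = [info[i].size if i in info else None for i in sig["cnvr_id"]]
        sig["type"] = [info[i].type if i in info else None for i in sig["cnvr_id"]]
    sig = sig.sort_values(["trait", "q"]).reset_index(drop=True)
    counts = (
        results.groupby("trait")["significant"]
        .sum()
        .astype(int)
        .rename("n_significant")
        .reset_index()
    )
    return sig, counts
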