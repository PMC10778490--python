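"""Quality control and summarisation of dairy test-day (DHI) records.

A DHI record is one cow's measured performance on one recording day: milk
yield (kg/d), fat and protein percentage, fat and protein yield (kg/d) and
somatic cell score, together with parity, age at first calving and days in
milk (DIM).  This module

* filters raw records with the study's edit rules (parity 1-3, age at first
  calving 22-36 months, DIM 5-305, daily milk 5-80 kg, SCS 0-9, values within
  3 SD of the trait x parity mean, at least 7 tests per lactation);
* standardises each surviving lactation to a 305-day yield with the
  test-interval method;
* produces descriptive statistics (SPSS-convention skewness/kurtosis) and
  paired Pearson correlations between parities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: the five milk production traits, in report order
TRAITS = ("my", "mfp", "mfy", "mpp", "mpy")

TRAIT_LABELS = {
    "my": "milk yield (kg)",
    "mfp": "milk fat percentage (%)",
    "mfy": "milk fat yield (kg)",
    "mpp": "milk protein percentage (%)",
    "mpy": "milk protein yield (kg)",
}

REQUIRED_COLUMNS = ("cow_id", "parity", "afc_months", "dim") + TRAITS + ("scs",)


@dataclass(frozen=True)
class FilterRules:
    """Edit bounds for :func:`filter_dhi` (defaults = the study's rules)."""

    parity_min: int = 1
    parity_max: int = 3
    afc_min: float = 22.0
    afc_max: float = 36.0
    dim_min: int = 5
    dim_max: int = 305
    my_min: float = 5.0
    my_max: float = 80.0
    scs_min: float = 0.0
    scs_max: float = 9.0
    sd_multiplier: float = 3.0
    min_tests: int = 7


#: filter rule names in application order
RULE_ORDER = ("parity", "calving_age", "dim", "daily_bounds", "sd_outlier", "min_tests")


@dataclass
class FilterAudit:
    """Per-rule removal counts with first-triggering-rule attribution."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})
    #: per (trait, parity) reference mean/SD used by the +-3 SD rule
    reference_stats: pd.DataFrame | None = None

    def check(self) -> None:
        assert self.n_input == self.n_retained + sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.removed[r]} for r in RULE_ORDER]
        rows.append({"rule": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)


def filter_dhi(
    records: pd.DataFrame,
    rules: FilterRules = FilterRules(),
    reference_stats: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the edit rules in order; each record is attributed to the first
    rule it violates.

    The +-3 SD rule uses mean/SD computed per trait x parity on the records
    surviving the bound rules, in a single pass; pass ``reference_stats``
    (from a previous audit) to reuse frozen statistics instead.  Cows with
    fewer than ``rules.min_tests`` surviving records in a lactation are
    dropped last.
    """
    audit = FilterAudit(n_input=len(records))
    if len(records) == 0:
        audit.reference_stats = pd.DataFrame(columns=["trait", "parity", "mean", "sd"])
        audit.check()
        return records.copy(), audit

    df = records.copy()

    masks = {
        "parity": ~df["parity"].between(rules.parity_min, rules.parity_max),
        "calving_age": ~df["afc_months"].between(rules.afc_min, rules.afc_max),
        "dim": ~df["dim"].between(rules.dim_min, rules.dim_max),
        "daily_bounds": ~df["my"].between(rules.my_min, rules.my_max)
        | ~df["scs"].between(rules.scs_min, rules.scs_max),
    }
    dropped = pd.Series(False, index=df.index)
    for rule in ("parity", "calving_age", "dim", "daily_bounds"):
        hit = masks[rule] & ~dropped
        audit.removed[rule] = int(hit.sum())
        dropped |= hit
    df = df[~dropped]

    # rule (5): per trait x parity mean +- k*SD, single pass on survivors
    if reference_stats is None:
        ref_rows = []
        for parity, grp in df.groupby("parity"):
            for t in TRAITS:
                ref_rows.append(
                    {
                        "trait": t,
                        "parity": parity,
                        "mean": grp[t].mean(),
                        "sd": grp[t].std(ddof=1),
                    }
                )
        reference_stats = pd.DataFrame(ref_rows)
    audit.reference_stats = reference_stats

    out_mask = pd.Series(False, index=df.index)
    for _, row in reference_stats.iterrows():
        if not np.isfinite(row["sd"]):
            continue
        sel = df["parity"] == row["parity"]
        lo = row["mean"] - rules.sd_multiplier * row["sd"]
        hi = row["mean"] + rules.sd_multiplier * row["sd"]
        out_mask |= sel & ~df[row["trait"]].between(lo, hi)
    audit.removed["sd_outlier"] = int(out_mask.sum())
    df = df[~out_mask]

    # minimum number of tests per cow x parity, applied last
    counts = df.groupby(["cow_id", "parity"])["dim"].transform("size")
    few = counts < rules.min_tests
    audit.removed["min_tests"] = int(few.sum())
    df = df[~few]

    audit.n_retained = len(df)
    audit.check()
    return df, audit


def _test_interval_total(dim: np.ndarray, y: np.ndarray, last_day: int = 305) -> float:
    """Accumulate a daily-yield trait to a lactation total by the
    test-interval method: first interval y1*d1, interior intervals
    mean-of-neighbours times the gap, tail yn*(305-dn)."""
    total = y[0] * dim[0]
    if len(dim) > 1:
        gaps = np.diff(dim)
        total += float(np.sum((y[:-1] + y[1:]) / 2.0 * gaps))
    total += y[-1] * (last_day - dim[-1])
    return float(total)


def adjust_305(
    records: pd.DataFrame, min_tests: int = 7, last_day: int = 305
) -> tuple[pd.DataFrame, list[tuple]]:
    """Standardise each cow x parity lactation to 305-day performance.

    Yields (milk, fat, protein kg) are accumulated with the test-interval
    method; 305-day fat % is 100*fat305/milk305 (protein % analogous).
    Lactations with duplicated DIM values are rejected and reported in the
    second return value as ``(cow_id, parity, reason)`` tuples.  The result is
    invariant under re-ordering of the input records.
    """
    rows = []
    rejected: list[tuple] = []
    for (cow, parity), grp in records.groupby(["cow_id", "parity"]):
        grp = grp.sort_values("dim")
        dim = grp["dim"].to_numpy(float)
        if len(np.unique(dim)) != len(dim):
            rejected.append((cow, parity, "duplicate DIM values"))
            continue
        if len(dim) < min_tests:
            rejected.append((cow, parity, f"fewer than {min_tests} tests"))
            continue
        my305 = _test_interval_total(dim, grp["my"].to_numpy(float), last_day)
        mfy305 = _test_interval_total(dim, grp["mfy"].to_numpy(float), last_day)
        mpy305 = _test_interval_total(dim, grp["mpy"].to_numpy(float), last_day)
        rows.append(
            {
                "cow_id": cow,
                "parity": parity,
                "my305": my305,
                "mfp305": 100.0 * mfy305 / my305,
                "mfy305": mfy305,
                "mpp305": 100.0 * mpy305 / my305,
                "mpy305": mpy305,
                "n_tests": len(dim),
            }
        )
    cols = ["cow_id", "parity", "my305", "mfp305", "mfy305", "mpp305", "mpy305", "n_tests"]
    return pd.DataFrame(rows, columns=cols), rejected


@dataclass(frozen=True)
class Summary:
    """Descriptive statistics of one trait vector (SPSS conventions)."""

    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    skewness: float
    kurtosis: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def describe(values: np.ndarray | pd.Series) -> Summary:
    """Descriptive statistics with sample SD (n-1), adjusted Fisher-Pearson
    skewness and bias-corrected excess kurtosis (the SPSS convention).

    Statistics whose minimum sample size is not met, or that are undefined for
    a constant vector, are reported as NaN rather than zero.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n == 0:
        return Summary(0, *([np.nan] * 7))
    sd = float(np.std(x, ddof=1)) if n >= 2 else np.nan
    skew = np.nan
    kurt = np.nan
    if n >= 3 and sd > 0:
        skew = float(sps.skew(x, bias=False))
    if n >= 4 and sd > 0:
        kurt = float(sps.kurtosis(x, fisher=True, bias=False))
    return Summary(
        n=n,
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        skewness=skew,
        kurtosis=kurt,
    )


def describe_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per trait x parity descriptive table (parity 0 = pooled 1-3 row),
    including the number of recorded individuals (NI) and records (NR)."""
    rows = []
    parities = sorted(records["parity"].unique())
    for t in TRAITS:
        for parity in list(parities) + [0]:
            grp = records if parity == 0 else records[records["parity"] == parity]
            s = describe(grp[t])
            rows.append(
                {
                    "trait": t,
                    "parity": parity,
                    "n_individuals": grp["cow_id"].nunique(),
                    "n_records": s.n,
                    **{k: v for k, v in s.as_dict().items() if k != "n"},
                }
            )
    return pd.DataFrame(rows)


def pearson_matrix(
    l305: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Paired Pearson correlations of each 305-day trait between parities.

    Uses cows with complete observations in both parities of a pair; the
    two-sided p-value comes from the t distribution with n-2 df.  Pairs with
    fewer than 3 complete observations are reported as NaN.
    """
    parities = sorted(l305["parity"].unique())
    rows = []
    for t in TRAITS:
        col = f"{t}305"
        wide = l305.pivot_table(index="cow_id", columns="parity", values=col)
        for i, p1 in enumerate(parities):
            for p2 in parities[i + 1 :]:
                if p1 not in wide.columns or p2 not in wide.columns:
                    continue
                sub = wide[[p1, p2]].dropna()
                if len(sub) < 3 or sub[p1].std() == 0 or sub[p2].std() == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = sps.pearsonr(sub[p1], sub[p2])
                rows.append(
                    {
                        "trait": t,
                        "parity_a": p1,
                        "parity_b": p2,
                        "n": len(sub),
                        "r": r,
                        "p": p,
                        "significant": bool(p < alpha) if np.isfinite(p) else False,
                    }
                )
    return pd.DataFrame(rows)
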