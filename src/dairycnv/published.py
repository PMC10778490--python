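"""Published summary tables from a Holstein milk-trait CNV survey, used as
validation inputs.

These constants are the printed summary numbers of the study this pipeline
models (the underlying herd data are not public).  They serve two purposes:

* cross-checking arithmetic conventions (e.g. the 1-based inclusive size of a
  CNV region, ``end - start + 1``) against independently printed sizes;
* recomputing derived percentages (per-state CNV shares, parity-1 record
  shares) from the printed counts.
"""

from __future__ import annotations

# Per-state CNV counts over 29 autosomes (copy numbers 0, 1, 3, 4).
CNV_STATE_COUNTS: dict[int, int] = {0: 14, 1: 68, 3: 1550, 4: 99}

# Printed per-state shares (%), as reported alongside the counts.
CNV_STATE_PCT_PRINTED: dict[int, float] = {0: 0.80, 1: 3.93, 3: 89.54, 4: 5.73}

# CNV regions with independently printed coordinates AND size (bp).
# One printed row (CNVR_161) is internally inconsistent (printed size does not
# match its coordinates under any convention) and is excluded.
CNVR_COORDINATES: dict[str, tuple[str, int, int, int]] = {
    # id: (chromosome, start, end, printed size)
    "CNVR_155": ("17", 71_644_239, 71_885_069, 240_831),
    "CNVR_124": ("14", 146_715, 891_340, 744_626),
    "CNVR_107": ("11", 104_418_358, 106_541_521, 2_123_164),
}

# Descriptive-table count columns: (trait, parity) -> (n individuals, n records).
# Parity 0 denotes the pooled 1-3 row.  Milk yield has its own counts; the four
# composition traits share a common record set.
TABLE1_COUNTS: dict[tuple[str, int], tuple[int, int]] = {
    ("my", 1): (6437, 46_749),
    ("my", 2): (3402, 24_864),
    ("my", 3): (3124, 23_162),
    ("my", 0): (9834, 95_375),
    ("composition", 1): (6263, 45_814),
    ("composition", 2): (3196, 23_785),
    ("composition", 3): (3088, 23_104),
    ("composition", 0): (9497, 92_763),
}

# Printed parity-1 shares (%): records share for milk yield, individuals share
# for milk yield, records share for the composition traits.
PARITY1_SHARES_PRINTED: dict[str, float] = {
    "my_records": 49.02,
    "my_individuals": 65.46,
    "composition_records": 49.39,
}


def cnv_state_percentages() -> dict[int, float]:
    """Per-state CNV percentages recomputed from the published counts."""
    total = sum(CNV_STATE_COUNTS.values())
    return {s: 100.0 * c / total for s, c in CNV_STATE_COUNTS.items()}


def cnvr_sizes_from_coordinates() -> dict[str, int]:
    """CNVR sizes recomputed from published coordinates (1-based inclusive)."""
    return {k: end - start + 1 for k, (_, start, end, _) in CNVR_COORDINATES.items()}


def parity1_shares() -> dict[str, float]:
    """Parity-1 shares (%) recomputed from the published count columns."""
    return {
        "my_records": 100.0 * TABLE1_COUNTS[("my", 1)][1] / TABLE1_COUNTS[("my", 0)][1],
        "my_individuals": 100.0 * TABLE1_COUNTS[("my", 1)][0] / TABLE1_COUNTS[("my", 0)][0],
        "composition_records": 100.0
        * TABLE1_COUNTS[("composition", 1)][1]
        / TABLE1_COUNTS[("composition", 0)][1],
    }
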