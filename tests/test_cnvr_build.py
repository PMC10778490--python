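"""CNV QC criteria, same-sample merging and CNVR construction."""

import numpy as np
import pytest

from dairycnv.cnv_hmm import CnvCall, SampleSignalMetrics
from dairycnv.cnvr_build import build_cnvrs, merge_same_sample, qc_cnvs, summarize


def call(sample="s1", chrom="1", start=100, end=200, si=10, ei=20, state=3,
         conf=50.0, n_snps=None):
    return CnvCall(
        sample_id=sample, chrom=chrom, start=start, end=end, start_idx=si,
        end_idx=ei, state=state, n_snps=n_snps or (ei - si + 1), conf=conf,
    )


GOOD = SampleSignalMetrics(lrr_sd=0.15, baf_drift=0.0, gcwf=0.01)


class TestQcCnvs:
    def test_failing_sample_loses_all_calls(self):
        metrics = {
            "s1": SampleSignalMetrics(lrr_sd=0.31, baf_drift=0.0, gcwf=0.0),
            "s2": GOOD,
        }
        calls = [call("s1"), call("s1", start=500, end=600, si=50, ei=60), call("s2")]
        kept, audit = qc_cnvs(calls, metrics)
        assert audit["sample_signal"] == 2
        # s2's call is now private and dropped by the two-individual rule
        assert audit["singleton"] == 1 and kept == []

    @pytest.mark.parametrize(
        "metric, value",
        [("lrr_sd", 0.35), ("baf_drift", 0.02), ("gcwf", -0.06)],
    )
    def test_each_sample_criterion_triggers(self, metric, value):
        m = SampleSignalMetrics(lrr_sd=0.1, baf_drift=0.0, gcwf=0.0)
        setattr(m, metric, value)
        kept, audit = qc_cnvs([call("s1")], {"s1": m})
        assert audit["sample_signal"] == 1

    def test_boundary_semantics_conf_and_snps(self):
        metrics = {"s1": GOOD, "s2": GOOD}
        ok = call("s1", si=10, ei=19, conf=10.1)  # 10 SNPs, conf > 10
        mate = call("s2", si=15, ei=30, conf=50)
        kept, audit = qc_cnvs([ok, mate], metrics)
        assert ok in kept
        border = call("s1", si=10, ei=19, conf=10.0)  # conf not > 10
        kept, audit = qc_cnvs([border, mate], metrics)
        assert audit["confidence"] == 1
        short = call("s1", si=10, ei=18, conf=50.0)  # 9 SNPs
        kept, audit = qc_cnvs([short, mate], metrics)
        assert audit["n_snps"] == 1

    def test_private_call_removed_by_two_individual_rule(self):
        metrics = {"s1": GOOD, "s2": GOOD}
        a = call("s1", si=10, ei=25)
        b = call("s2", si=20, ei=35)
        private = call("s2", start=9000, end=9900, si=90, ei=105)
        kept, audit = qc_cnvs([a, b, private], metrics)
        assert audit["singleton"] == 1
        assert private not in kept and a in kept and b in kept


class TestMergeSameSample:
    def test_sufficient_overlap_merges(self):
        # [100,200] + [150,250]: overlap 51, union 151 -> 33.8% >= 20%
        a = call(start=100, end=200, si=10, ei=20)
        b = call(start=150, end=250, si=15, ei=25)
        merged = merge_same_sample([a, b])
        assert len(merged) == 1
        m = merged[0]
        assert (m.start, m.end) == (100, 250)
        assert m.n_snps == 16 and m.conf == a.conf + b.conf

    def test_insufficient_overlap_kept_apart(self):
        # [100,200] + [180,300]: overlap 21, union 201 -> 10.4% < 20%
        a = call(start=100, end=200, si=10, ei=20)
        b = call(start=180, end=300, si=18, ei=30)
        assert len(merge_same_sample([a, b])) == 2

    def test_opposite_directions_never_merge(self):
        a = call(start=100, end=200, state=1)
        b = call(start=100, end=200, state=3)
        assert len(merge_same_sample([a, b])) == 2

    def test_same_direction_different_state_merges_to_major(self):
        a = call(start=100, end=300, si=10, ei=30, state=3)
        b = call(start=250, end=350, si=25, ei=35, state=4)
        merged = merge_same_sample([a, b])
        assert len(merged) == 1 and merged[0].state == 3  # longer member wins

    def test_idempotent_and_order_invariant(self, rng):
        calls = [
            call(start=100, end=200, si=10, ei=20),
            call(start=150, end=250, si=15, ei=25),
            call(start=1000, end=1200, si=100, ei=120),
            call(start=1100, end=1250, si=110, ei=125),
            call(sample="s2", start=120, end=260, si=12, ei=26),
        ]
        once = merge_same_sample(calls)
        twice = merge_same_sample(once)
        key = lambda c: (c.sample_id, c.chrom, c.start, c.end, c.state)
        assert sorted(map(key, once)) == sorted(map(key, twice))
        shuffled = [calls[i] for i in rng.permutation(len(calls))]
        assert sorted(map(key, merge_same_sample(shuffled))) == sorted(map(key, once))

    def test_chain_merging_reaches_fixed_point(self):
        # pairwise overlaps: 61/141 = 43% then 61/201 = 30%, both >= 20%
        calls = [
            call(start=100, end=200, si=10, ei=20),
            call(start=140, end=240, si=14, ei=24),
            call(start=180, end=300, si=18, ei=30),
        ]
        merged = merge_same_sample(calls)
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (100, 300)


class TestBuildCnvrs:
    def test_shared_snp_joins_across_samples(self):
        a = call("sA", si=10, ei=20, start=1000, end=2000)
        b = call("sB", si=20, ei=30, start=2000, end=3000)
        regions = build_cnvrs([a, b])
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (1000, 3000) and r.n_samples == 2

    def test_adjacent_but_disjoint_snps_stay_apart_and_drop(self):
        a = call("sA", si=10, ei=20, start=1000, end=2000)
        b = call("sB", si=21, ei=30, start=2100, end=3000)
        assert build_cnvrs([a, b]) == []

    def test_type_classification(self):
        gain = build_cnvrs([call("sA", state=3), call("sB", state=4, si=15, ei=25)])
        loss = build_cnvrs([call("sA", state=0), call("sB", state=1, si=15, ei=25)])
        mixed = build_cnvrs([call("sA", state=3), call("sB", state=1, si=15, ei=25)])
        assert gain[0].type == "Gain" and loss[0].type == "Loss"
        assert mixed[0].type == "Mixed"

    def test_ids_genome_ordered_and_sizes_inclusive(self):
        calls = [
            call("sA", chrom="2", start=500, end=900, si=5, ei=9),
            call("sB", chrom="2", start=600, end=1000, si=6, ei=10),
            call("sA", chrom="1", start=7000, end=9000, si=70, ei=90),
            call("sB", chrom="1", start=7100, end=9100, si=71, ei=91),
        ]
        regions = build_cnvrs(calls)
        assert [r.id for r in regions] == ["CNVR_1", "CNVR_2"]
        assert regions[0].chrom == "1"
        assert all(r.size == r.end - r.start + 1 for r in regions)

    def test_invariants_on_random_calls(self, rng):
        calls = []
        for i in range(60):
            si = int(rng.integers(0, 500))
            ln = int(rng.integers(10, 40))
            calls.append(
                call(
                    sample=f"s{rng.integers(8)}", chrom=str(rng.integers(1, 4)),
                    si=si, ei=si + ln, start=(si + 1) * 1000, end=(si + ln + 1) * 1000,
                    state=int(rng.choice([0, 1, 3, 4])),
                )
            )
        regions = build_cnvrs(calls)
        for r in regions:
            assert r.n_samples >= 2
            for c in r.calls:
                assert r.start <= c.start and c.end <= r.end
        # no two regions on one chromosome share a SNP index
        for chrom in {r.chrom for r in regions}:
            spans = sorted(
                (min(c.start_idx for c in r.calls), max(c.end_idx for c in r.calls))
                for r in regions
                if r.chrom == chrom
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2


class TestSummarize:
    def test_percentages_from_state_counts(self):
        counts = {0: 14, 1: 68, 3: 1550, 4: 99}
        calls = []
        i = 0
        for state, k in counts.items():
            for _ in range(k):
                calls.append(call(sample=f"s{i%7}", si=i * 50, ei=i * 50 + 10,
                                  start=i * 5000, end=i * 5000 + 1000, state=state))
                i += 1
        table, _ = summarize(calls, [])
        pct = dict(zip(table["state"], table["pct"]))
        assert pct[0] == pytest.approx(100 * 14 / 1731)
        assert pct[3] == pytest.approx(100 * 1550 / 1731)

    def test_full_chromosome_coverage(self):
        regions = build_cnvrs(
            [call("sA", start=1, end=1000), call("sB", start=1, end=1000, si=12, ei=22)]
        )
        _, cov = summarize([], regions, chrom_lengths={"1": 1000})
        assert cov["coverage"].iloc[0] == pytest.approx(1.0)

    def test_coverage_union_equals_sum_of_sizes_post_merge(self):
        regions = build_cnvrs(
            [
                call("sA", si=10, ei=20, start=1000, end=2000),
                call("sB", si=15, ei=25, start=1500, end=2500),
                call("sA", si=100, ei=120, start=10000, end=12000),
                call("sB", si=110, ei=130, start=11000, end=13000),
            ]
        )
        _, cov = summarize([], regions, chrom_lengths={"1": 20000})
        assert cov["covered_bp"].iloc[0] == sum(r.size for r in regions)

    def test_missing_length_gives_undefined_coverage(self):
        regions = build_cnvrs(
            [call("sA"), call("sB", si=12, ei=22, start=150, end=250)]
        )
        _, cov = summarize([], regions, chrom_lengths={})
        assert np.isnan(cov["coverage"].iloc[0])
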