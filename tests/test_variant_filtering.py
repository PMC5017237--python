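"""Triage filter stages: frequency, blacklist, indel confidence, end-proximity flag."""

import numpy as np
import pytest

from aortapanel.panel_model import Amplicon, PanelDefinition, PanelGene
from aortapanel.variant_filtering import (
    FalsePositiveList,
    FilterConfig,
    FilterInputError,
    GenotypeState,
    TriageStatus,
    VariantCall,
    amplicon_end_flag,
    blacklist_filter,
    indel_confidence,
    normalize_variant,
    population_frequency_filter,
    triage,
)

CFG = FilterConfig()


def call(pos=100, ref="A", alt="AT", depth=100, f=20, r=20, **kw):
    return VariantCall(
        chrom="toy", pos=pos, ref=ref, alt=alt, depth=depth,
        alt_forward=f, alt_reverse=r, **kw,
    )


class TestPopulationFrequencyFilter:
    @pytest.mark.parametrize(
        "maf, keep",
        [(0.002, True), (0.05, False), (None, True), (0.01, True), (0.0101, False)],
    )
    def test_threshold(self, maf, keep):
        assert population_frequency_filter(maf, CFG) is keep

    def test_out_of_range_rejected(self):
        with pytest.raises(FilterInputError):
            population_frequency_filter(1.5, CFG)


class TestIndelConfidence:
    def test_all_predicates_hold(self):
        ok, reasons = indel_confidence(call(depth=50, f=6, r=5), CFG)
        assert ok and reasons == []

    def test_low_depth_named(self):
        ok, reasons = indel_confidence(call(depth=15, f=4, r=4), CFG)
        assert not ok and reasons == ["depth"]

    def test_strand_failures_both_named(self):
        ok, reasons = indel_confidence(call(depth=100, f=9, r=3), CFG)
        assert not ok
        assert set(reasons) == {"strand_reads", "strand_ratio"}

    def test_zero_depth_short_circuits(self):
        ok, reasons = indel_confidence(call(depth=0, f=0, r=0), CFG)
        assert not ok and reasons == ["no coverage"]

    def test_boundaries_are_strict(self):
        # depth exactly 20, strand reads exactly 3, AF exactly 10% must all fail
        ok, reasons = indel_confidence(call(depth=20, f=5, r=5), CFG)
        assert "depth" in reasons
        ok, reasons = indel_confidence(call(depth=60, f=3, r=3), CFG)
        assert "strand_reads" in reasons and "allele_fraction" in reasons

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        cfg = CFG
        for _ in range(10_000):
            depth = int(rng.integers(0, 120))
            f = int(rng.integers(0, depth + 1))
            r = int(rng.integers(0, depth - f + 1))
            v = call(depth=depth, f=f, r=r)
            expected = (
                depth > 20
                and (f + r) / depth > 0.10
                and f > 3
                and r > 3
                and f / r > 0.7
                and r / f > 0.7
            ) if depth > 0 else False
            assert indel_confidence(v, cfg)[0] is expected, (depth, f, r)


class TestNormalizeAndBlacklist:
    REF = {"toy": "GATTTTC"}

    def test_left_alignment_in_repeat_tract(self):
        a = normalize_variant("toy", 2, "AT", "A", self.REF)
        b = normalize_variant("toy", 5, "TT", "T", self.REF)
        assert a == b == ("toy", 2, "AT", "A")
        # a naive string comparison would have treated them as different
        assert ("toy", 5, "TT", "T") != ("toy", 2, "AT", "A")

    def test_snv_is_unchanged(self):
        assert normalize_variant("toy", 3, "T", "G", self.REF) == ("toy", 3, "T", "G")

    def test_blacklist_membership_is_normalization_invariant(self):
        fpl = FalsePositiveList(keys=frozenset({("toy", 2, "AT", "A")}))
        hit = call(pos=5, ref="TT", alt="T")
        miss = call(pos=3, ref="T", alt="G")
        assert blacklist_filter(hit, fpl, self.REF)
        assert not blacklist_filter(miss, fpl, self.REF)


def toy_panel(amplicons):
    gene = PanelGene("FBN1", "15q21.1", "Marfan", 66, 106, 1.0)
    return PanelDefinition(genes=[gene], amplicons=amplicons)


class TestAmpliconEndFlag:
    def test_near_single_amplicon_end(self):
        panel = toy_panel([Amplicon("toy", 0, 100, "FBN1", "A1")])
        assert amplicon_end_flag(call(pos=99, ref="A", alt="G"), panel, CFG)

    def test_mid_amplicon_not_flagged(self):
        panel = toy_panel([Amplicon("toy", 0, 100, "FBN1", "A1")])
        assert not amplicon_end_flag(call(pos=50, ref="A", alt="G"), panel, CFG)

    def test_interior_of_any_overlapping_amplicon_rescues(self):
        panel = toy_panel(
            [
                Amplicon("toy", 0, 100, "FBN1", "A1"),
                Amplicon("toy", 90, 190, "FBN1", "A2"),
            ]
        )
        # 2 bases from A1's end but deep inside A2
        assert not amplicon_end_flag(call(pos=98, ref="A", alt="G"), panel, CFG)
        # within the margin of both
        assert amplicon_end_flag(call(pos=188, ref="A", alt="G"), panel, CFG)

    def test_off_target_rejected(self):
        panel = toy_panel([Amplicon("toy", 0, 100, "FBN1", "A1")])
        with pytest.raises(FilterInputError, match="outside"):
            amplicon_end_flag(call(pos=500, ref="A", alt="G"), panel, CFG)


class TestTriage:
    def mixed_calls(self):
        return [
            call(pos=10, ref="A", alt="G", population_maf=0.05),  # common SNV
            call(pos=20, ref="C", alt="CT"),  # blacklisted below
            call(pos=30, ref="G", alt="GA", depth=15, f=4, r=4),  # low-depth indel
            call(pos=40, ref="T", alt="C"),
            call(pos=50, ref="A", alt="AGG", depth=80, f=15, r=14),
            call(pos=60, ref="G", alt="T"),
        ]

    def test_mixed_toy_callset(self):
        fpl = FalsePositiveList(keys=frozenset({("toy", 20, "C", "CT")}))
        verdicts = triage(self.mixed_calls(), CFG, fpl)
        statuses = [v.status for v in verdicts]
        assert statuses == [
            TriageStatus.FREQUENCY_FILTERED,
            TriageStatus.BLACKLISTED,
            TriageStatus.DROP_INDEL,
            TriageStatus.RETAINED,
            TriageStatus.RETAINED,
            TriageStatus.RETAINED,
        ]
        assert verdicts[2].reasons == ["depth"]
        assert sum(v.retained for v in verdicts) == 3

    def test_empty_and_all_clean(self):
        assert triage([], CFG) == []
        clean = [call(pos=p, ref="A", alt="G") for p in (10, 20, 30)]
        verdicts = triage(clean, CFG)
        assert all(v.retained and not v.flags for v in verdicts)

    def test_order_independence_of_verdicts(self):
        fpl = FalsePositiveList(keys=frozenset({("toy", 20, "C", "CT")}))
        calls = self.mixed_calls()
        forward = {v.call.key(): v.status for v in triage(calls, CFG, fpl)}
        backward = {v.call.key(): v.status for v in triage(calls[::-1], CFG, fpl)}
        assert forward == backward

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(200):
            depth = int(rng.integers(1, 120))
            f = int(rng.integers(0, depth + 1))
            r = int(rng.integers(0, depth - f + 1))
            maf = float(rng.uniform(0, 0.05)) if rng.random() < 0.5 else None
            calls.append(call(pos=10 + i, depth=depth, f=f, r=r, population_maf=maf))

        def retained(cfg):
            return {v.call.key() for v in triage(calls, cfg) if v.retained}

        loose_maf = retained(FilterConfig(max_population_maf=0.04))
        tight_maf = retained(FilterConfig(max_population_maf=0.005))
        assert tight_maf <= loose_maf

        low_depth = retained(FilterConfig(min_depth=10))
        high_depth = retained(FilterConfig(min_depth=60))
        assert high_depth <= low_depth

    def test_nocall_records_bypass_indel_confidence(self):
        v = call(depth=5, f=1, r=1, genotype=GenotypeState.NOCALL)
        assert triage([v], CFG)[0].retained
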