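"""Stringent filter: barcode identity/quality, adapters, window quality."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idnaseq.filtering import (
    FilterConfig,
    FilterReport,
    barcode_assign,
    filter_pair,
    filter_stream,
    has_adapter,
    window_quality_pass,
)

from conftest import make_pair

ADAPTER = "CTGTCTCTTATACACATCT"


class TestBarcodeAssign:
    def test_exact_match_high_quality_assigned(self):
        p = make_pair(barcode="ACGTAC")
        assert barcode_assign(p, "ACGTAC", FilterConfig()) == "assigned"

    def test_single_mismatch_rejected_by_default(self):
        # default demultiplexers allow one mismatch; this method allows none
        p = make_pair(barcode="ACGTAC")
        assert barcode_assign(p, "ACGTAA", FilterConfig()) == "rejected_mismatch"
        assert (
            barcode_assign(p, "ACGTAA", FilterConfig(barcode_mismatches_allowed=1))
            == "assigned"
        )

    def test_single_base_qv29_rejected(self):
        # a single index base below QV 30 discards the whole pair
        p = make_pair(barcode="ACGTAC", index_qual=[40, 40, 29, 40, 40, 40])
        assert barcode_assign(p, "ACGTAC", FilterConfig()) == "rejected_quality"

    def test_qv30_boundary_accepted(self):
        p = make_pair(barcode="ACGTAC", index_qual=[30] * 6)
        assert barcode_assign(p, "ACGTAC", FilterConfig()) == "assigned"

    def test_length_mismatch_is_an_error(self):
        p = make_pair(barcode="ACGTAC")
        with pytest.raises(ValueError, match="barcode length mismatch"):
            barcode_assign(p, "ACGT", FilterConfig())


class TestAdapter:
    def test_full_adapter_internal_match(self):
        assert has_adapter("AAAA" + ADAPTER + "TTTT", [ADAPTER])

    def test_three_prime_anchored_prefix(self):
        # 8-base adapter prefix truncated by the end of the read
        seq = "A" * 40 + ADAPTER[:8]
        assert has_adapter(seq, [ADAPTER], min_overlap=8)
        assert not has_adapter(seq, [ADAPTER], min_overlap=9)

    def test_clean_sequence_and_empty_list(self):
        assert not has_adapter("ACGT" * 20, [ADAPTER])
        assert not has_adapter("ACGT" * 20, [])


class TestWindowQuality:
    @pytest.mark.parametrize(
        "qual,expected",
        [
            ([40] * 10, True),           # every window mean 40
            ([30, 30, 30, 29], False),   # single window mean 29.75 < 30
            ([29, 31, 31, 31, 31], True),  # window means 30.5 and 31
            ([30, 30, 30, 30], True),    # mean exactly 30 passes
            ([29, 31], True),            # shorter than window: one full-length window, mean 30
            ([29, 29], False),           # short window mean 29
        ],
    )
    def test_sliding_window_means(self, qual, expected):
        cfg = FilterConfig()
        assert window_quality_pass(np.asarray(qual, dtype=np.int16), cfg) is expected

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 41), min_size=1, max_size=60))
    def test_matches_direct_enumeration(self, qual):
        """Fast cumulative-sum path equals brute-force window enumeration."""
        cfg = FilterConfig()
        q = np.asarray(qual, dtype=np.int16)
        w = min(cfg.window_len, len(q))
        brute = all(
            np.mean(q[i : i + w]) >= cfg.window_min_mean_qv
            for i in range(len(q) - w + 1)
        )
        assert window_quality_pass(q, cfg) is brute

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(0, 41), min_size=1, max_size=60),
        st.integers(0, 20),
        st.integers(0, 20),
    )
    def test_monotone_in_threshold(self, qual, lo, hi):
        """Raising the window threshold never turns a fail into a pass."""
        lo, hi = sorted((lo, hi))
        q = np.asarray(qual, dtype=np.int16)
        pass_lo = window_quality_pass(q, FilterConfig(window_min_mean_qv=lo))
        pass_hi = window_quality_pass(q, FilterConfig(window_min_mean_qv=hi))
        assert pass_lo or not pass_hi


class TestFilterPair:
    def test_clean_pair_kept_unchanged(self):
        p = make_pair()
        kept, reason = filter_pair(p, p.index_seq, FilterConfig(adapters=(ADAPTER,)))
        assert reason is None
        assert kept is p

    def test_r2_window_failure(self):
        p = make_pair(r2_qual=[40, 40, 28, 28, 28, 28, 40, 40])
        kept, reason = filter_pair(p, p.index_seq, FilterConfig())
        assert kept is None and reason == "window_quality"

    def test_first_failing_check_wins(self):
        # fails both barcode quality and adapter; barcode quality is checked first
        p = make_pair(r1=ADAPTER + "ACGT", index_qual=[29] * 8)
        _, reason = filter_pair(p, p.index_seq, FilterConfig(adapters=(ADAPTER,)))
        assert reason == "barcode_quality"

    def test_adapter_checked_on_both_mates(self):
        p = make_pair(r2="AAAA" + ADAPTER)
        _, reason = filter_pair(p, p.index_seq, FilterConfig(adapters=(ADAPTER,)))
        assert reason == "adapter"

    def test_permissive_config_is_identity(self):
        # thresholds at 0, no adapters: every barcode-matched pair passes untouched
        p = make_pair(qv=2, barcode_qv=1)
        cfg = FilterConfig(barcode_min_qv=0, window_min_mean_qv=0, adapters=())
        kept, reason = filter_pair(p, p.index_seq, cfg)
        assert reason is None and kept is p

    def test_headcrop_tailcrop(self):
        p = make_pair(r1="AACGTACGTT", r2="GGACGTACCC")
        cfg = FilterConfig(headcrop=2, tailcrop=2)
        kept, _ = filter_pair(p, p.index_seq, cfg)
        assert kept.r1_seq == "CGTACG" and kept.r2_seq == "ACGTAC"
        assert len(kept.r1_qual) == 6


class TestFilterStream:
    def _mixed_stream(self):
        return [
            make_pair(read_id="ok"),
            make_pair(read_id="bc", barcode="TTTTTTTT"),
            make_pair(read_id="bq", index_qual=[29] * 8),
            make_pair(read_id="ad", r1="AAAA" + ADAPTER),
            make_pair(read_id="wq", r1_qual=[28] * 8),
            make_pair(read_id="ok2"),
        ]

    def test_report_conservation_identity(self):
        report = FilterReport("S1", "rep1")
        cfg = FilterConfig(adapters=(ADAPTER,))
        kept = list(filter_stream(self._mixed_stream(), "ACGTACGT", cfg, report))
        assert [p.read_id for p in kept] == ["ok", "ok2"]
        assert report.input_pairs == 6
        assert report.kept_pairs == 2
        assert report.removed_barcode_mismatch == 1
        assert report.removed_barcode_quality == 1
        assert report.removed_adapter == 1
        assert report.removed_window_quality == 1
        report.check_conservation()

    def test_determinism(self):
        cfg = FilterConfig(adapters=(ADAPTER,))
        a = [p.read_id for p in filter_stream(self._mixed_stream(), "ACGTACGT", cfg)]
        b = [p.read_id for p in filter_stream(self._mixed_stream(), "ACGTACGT", cfg)]
        assert a == b

    def test_raising_thresholds_never_keeps_more(self):
        stream = [
            make_pair(read_id=str(i), qv=q, barcode_qv=bq)
            for i, (q, bq) in enumerate([(40, 40), (31, 29), (29, 40), (33, 33), (25, 40)])
        ]
        kept_n = []
        for qv in (0, 26, 30, 32, 34, 41):
            cfg = FilterConfig(barcode_min_qv=qv, window_min_mean_qv=qv)
            kept_n.append(sum(1 for _ in filter_stream(list(stream), "ACGTACGT", cfg)))
        assert kept_n == sorted(kept_n, reverse=True)
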