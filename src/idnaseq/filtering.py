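"""Stringent read-pair filtering (discrimination pipeline, step 1).

Raw demultiplexed read pairs are refined by four checks applied in a fixed
order, and a pair failing any check is removed wholesale (whole-pair exact
matching downstream makes a surviving orphan mate useless):

1. barcode identity — zero mismatches against the expected barcode by
   default, stricter than the usual one-mismatch demultiplexing;
2. barcode quality — every index base must reach QV 30;
3. adapter content — any adapter occurring as a substring of either mate,
   or an adapter prefix of at least ``min_overlap`` bases anchored at the
   3' end;
4. sliding-window quality — no window of four consecutive bases on either
   mate may have mean quality below QV 30 (Trimmomatic SLIDINGWINDOW
   semantics, but the pair is dropped rather than trimmed).

Each removed pair is counted once, under its first failing check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .fastq_io import ReadPair

REMOVAL_REASONS = (
    "barcode_mismatch",
    "barcode_quality",
    "adapter",
    "window_quality",
)


@dataclass
class FilterConfig:
    """Thresholds of the stringent filter.

    Defaults are the published settings: no barcode mismatches, barcode
    minimum QV 30, mean QV 30 over sliding windows of 4 bases.  Head/tail
    cropping defaults to 0 — cropping belongs to the SNP-calling branch of
    the original analysis, and is exposed only for parity experiments.
    """

    barcode_mismatches_allowed: int = 0
    barcode_min_qv: int = 30
    window_len: int = 4
    window_min_mean_qv: float = 30.0
    adapters: tuple[str, ...] = ()
    min_overlap: int = 8
    headcrop: int = 0
    tailcrop: int = 0

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        for name in ("barcode_mismatches_allowed", "barcode_min_qv",
                     "window_min_mean_qv", "headcrop", "tailcrop", "min_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.adapters = tuple(a.upper() for a in self.adapters)


@dataclass
class FilterReport:
    """Per-(sample, duplicate) removal counters.

    Invariant: ``input_pairs == kept_pairs + sum(removed_*)`` — every pair
    is either kept or counted once under its first failing check.
    """

    sample_id: str = ""
    duplicate_id: str = ""
    input_pairs: int = 0
    removed_barcode_mismatch: int = 0
    removed_barcode_quality: int = 0
    removed_adapter: int = 0
    removed_window_quality: int = 0
    kept_pairs: int = 0

    def count(self, reason: Optional[str]) -> None:
        self.input_pairs += 1
        if reason is None:
            self.kept_pairs += 1
        elif reason in REMOVAL_REASONS:
            setattr(self, f"removed_{reason}", getattr(self, f"removed_{reason}") + 1)
        else:
            raise ValueError(f"unknown removal reason {reason!r}")

    @property
    def removed_total(self) -> int:
        return sum(getattr(self, f"removed_{r}") for r in REMOVAL_REASONS)

    def check_conservation(self) -> None:
        assert self.input_pairs == self.kept_pairs + self.removed_total, (
            "filter report conservation identity violated"
        )

    @staticmethod
    def tsv_columns() -> list[str]:
        return [f.name for f in fields(FilterReport)]


def barcode_assign(pair: ReadPair, expected_barcode: str, config: FilterConfig) -> str:
    """Classify a pair's index read: 'assigned', 'rejected_mismatch' or
    'rejected_quality'.

    Mismatch is Hamming distance above ``barcode_mismatches_allowed``
    (default 0); quality rejection is any single index base below
    ``barcode_min_qv`` (default QV 30).
    """
    if not expected_barcode:
        raise ValueError("expected barcode must be nonempty")
    if len(pair.index_seq) != len(expected_barcode):
        raise ValueError(
            f"barcode length mismatch for read {pair.read_id!r}: index read has "
            f"{len(pair.index_seq)} bases, expected barcode {len(expected_barcode)}"
        )
    mism = sum(a != b for a, b in zip(pair.index_seq, expected_barcode))
    if mism > config.barcode_mismatches_allowed:
        return "rejected_mismatch"
    if len(pair.index_qual) and pair.index_qual.min() < config.barcode_min_qv:
        return "rejected_quality"
    return "assigned"


def has_adapter(seq: str, adapters: Sequence[str], min_overlap: int = 8) -> bool:
    """True iff any adapter occurs within ``seq``, or an adapter prefix of
    length >= ``min_overlap`` is anchored at the 3' end (read-through into
    adapter truncated by the end of the read)."""
    if not adapters:
        return False
    for ad in adapters:
        if ad in seq:
            return True
        # 3'-anchored partial adapter: seq ends with a proper prefix of ad
        kmax = min(len(ad) - 1, len(seq))
        for k in range(min_overlap, kmax + 1):
            if seq.endswith(ad[:k]):
                return True
    return False


def window_quality_pass(qual: np.ndarray, config: FilterConfig) -> bool:
    """True iff no sliding window of ``window_len`` bases has mean quality
    below ``window_min_mean_qv``.

    Windows slide by one base and are full-length only; reads shorter than
    the window are judged on their single full-length window.
    """
    n = len(qual)
    if n == 0:
        raise ValueError("empty quality vector")
    # common case: every base already clears the mean threshold
    if qual.min() >= config.window_min_mean_qv:
        return True
    w = min(config.window_len, n)
    if w == n:
        return float(qual.mean()) >= config.window_min_mean_qv
    csum = np.cumsum(np.concatenate(([0], qual)))
    window_sums = csum[w:] - csum[:-w]
    return bool(window_sums.min() >= config.window_min_mean_qv * w)


def filter_pair(
    pair: ReadPair, expected_barcode: str, config: FilterConfig
) -> tuple[Optional[ReadPair], Optional[str]]:
    """Apply the full stringent filter to one pair.

    Returns ``(kept_pair, None)`` or ``(None, reason)`` where reason is the
    first failing check among barcode_mismatch, barcode_quality, adapter,
    window_quality.  Head/tail cropping (off by default) is applied to both
    mates of kept pairs only.
    """
    if expected_barcode:
        verdict = barcode_assign(pair, expected_barcode, config)
        if verdict == "rejected_mismatch":
            return None, "barcode_mismatch"
        if verdict == "rejected_quality":
            return None, "barcode_quality"
    if config.adapters and (
        has_adapter(pair.r1_seq, config.adapters, config.min_overlap)
        or has_adapter(pair.r2_seq, config.adapters, config.min_overlap)
    ):
        return None, "adapter"
    if not (
        window_quality_pass(pair.r1_qual, config)
        and window_quality_pass(pair.r2_qual, config)
    ):
        return None, "window_quality"
    if config.headcrop or config.tailcrop:
        h, t = config.headcrop, config.tailcrop
        end1 = len(pair.r1_seq) - t
        end2 = len(pair.r2_seq) - t
        if end1 <= h or end2 <= h:
            return None, "window_quality"  # cropped to nothing; counted with quality
        pair = ReadPair(
            read_id=pair.read_id,
            r1_seq=pair.r1_seq[h:end1],
            r1_qual=pair.r1_qual[h:end1],
            r2_seq=pair.r2_seq[h:end2],
            r2_qual=pair.r2_qual[h:end2],
            index_seq=pair.index_seq,
            index_qual=pair.index_qual,
        )
    return pair, None


def filter_stream(
    pairs: Iterable[ReadPair],
    expected_barcode: str,
    config: FilterConfig,
    report: Optional[FilterReport] = None,
) -> Iterator[ReadPair]:
    """Filter a stream of pairs, updating ``report`` counters in place."""
    for pair in pairs:
        kept, reason = filter_pair(pair, expected_barcode, config)
        if report is not None:
            report.count(reason)
        if kept is not None:
            yield kept
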