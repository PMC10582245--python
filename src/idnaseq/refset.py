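"""Reference and comprehensive read-set construction (steps 2-3).

The atom of all set operations is the :class:`PairKey`: a read pair's
canonical, strand-folded identity.  With ``fwd = r1 + '#' + r2`` and
``rev = revcomp(r2) + '#' + revcomp(r1)``, the key is the lexicographic
minimum of the two — so a fragment sequenced in either orientation maps to
the same key, and "searches including reverse complementary sequences"
reduce to plain set membership.

Per PCR duplicate, unique pairs are counted; pairs seen more than 10 times
(>= 11 identical copies over the whole paired length) form that duplicate's
high-quality (HQ) set; the intersection of the HQ sets across a sample's
duplicates is its super-high-quality (SHQ) reference; the union of
everything observed at least once is its comprehensive (query) set.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set

from .fastq_io import ReadPair

DEFAULT_MIN_COPIES = 11  # "over 10" identical copies, strictly
KEY_SEP = "#"

_RC = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; complement(N) = N."""
    return seq.translate(_RC)[::-1]


def canonical_key(r1_seq: str, r2_seq: str) -> str:
    """Strand-folded identity of a read pair.

    Invariant: ``canonical_key(r1, r2) == canonical_key(revcomp(r2), revcomp(r1))``.
    """
    if not _VALID.issuperset(r1_seq) or not _VALID.issuperset(r2_seq):
        bad = (set(r1_seq) | set(r2_seq)) - _VALID
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in read pair")
    fwd = r1_seq + KEY_SEP + r2_seq
    rev = revcomp(r2_seq) + KEY_SEP + revcomp(r1_seq)
    return fwd if fwd <= rev else rev


def key_of(pair: ReadPair) -> str:
    return canonical_key(pair.r1_seq, pair.r2_seq)


@dataclass
class UniqueReadCounts:
    """Multiset of canonical keys for one (sample, PCR duplicate) library."""

    sample_id: str
    duplicate_id: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())


@dataclass
class ReferenceSet:
    """A sample's SHQ reference: HQ keys shared by all its PCR duplicates."""

    sample_id: str
    shq: Set[str]
    provenance: List[str] = field(default_factory=list)
    min_copies: int = DEFAULT_MIN_COPIES


@dataclass
class ComprehensiveSet:
    """Every key observed at least once in any of a sample's duplicates."""

    sample_id: str
    keys: Set[str]


def count_unique(
    kept_pairs: Iterable[ReadPair],
    sample_id: str,
    duplicate_id: str,
    strand_pool: bool = True,
) -> UniqueReadCounts:
    """Count canonical-key multiplicities over an (already filtered) stream.

    With ``strand_pool`` (default), forward and reverse-complement
    observations of a fragment pool into one multiplicity before any
    threshold is applied.  ``strand_pool=False`` is a dialect switch that
    counts the two orientations separately and records, per canonical key,
    the multiplicity of its best single orientation — downstream copy
    thresholds then effectively apply per orientation.  (In that dialect the
    total-pairs conservation identity intentionally does not hold.)
    """
    if strand_pool:
        counts = Counter(key_of(p) for p in kept_pairs)
    else:
        oriented: Counter[str] = Counter(
            p.r1_seq + KEY_SEP + p.r2_seq for p in kept_pairs
        )
        counts = Counter()
        for fwd, n in oriented.items():
            r1, r2 = fwd.split(KEY_SEP)
            key = canonical_key(r1, r2)
            counts[key] = max(counts[key], n)
    return UniqueReadCounts(sample_id=sample_id, duplicate_id=duplicate_id,
                            counts=dict(counts))


def high_quality_set(counts: UniqueReadCounts, min_copies: int = DEFAULT_MIN_COPIES) -> Set[str]:
    """Keys with multiplicity >= ``min_copies`` (default 11, i.e. 'over 10')."""
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    return {k for k, n in counts.counts.items() if n >= min_copies}


def super_high_quality_set(
    hq_sets: Sequence[Set[str]],
    sample_id: str = "",
    provenance: Sequence[str] = (),
    min_copies: int = DEFAULT_MIN_COPIES,
    allow_single: bool = False,
) -> ReferenceSet:
    """Intersect per-duplicate HQ sets into the SHQ reference.

    At least two PCR duplicates are required; single-duplicate mode must be
    enabled explicitly (the reference is then unconfirmed by replication).
    """
    if len(hq_sets) < 2 and not allow_single:
        raise ValueError(
            f"need >=2 PCR duplicates to build a reference for sample "
            f"{sample_id or '?'} (got {len(hq_sets)})"
        )
    if not hq_sets:
        raise ValueError("no high-quality sets given")
    shq = set(hq_sets[0])
    for s in hq_sets[1:]:
        shq &= s
    return ReferenceSet(sample_id=sample_id, shq=shq,
                        provenance=list(provenance), min_copies=min_copies)


def comprehensive_set(counts_list: Sequence[UniqueReadCounts]) -> ComprehensiveSet:
    """Union of all keys seen at least once across a sample's duplicates."""
    if not counts_list:
        raise ValueError("no duplicate counts given")
    sample_ids = {c.sample_id for c in counts_list}
    if len(sample_ids) != 1:
        raise ValueError(f"counts from multiple samples: {sorted(sample_ids)}")
    keys: Set[str] = set()
    for c in counts_list:
        keys.update(c.counts)
    return ComprehensiveSet(sample_id=counts_list[0].sample_id, keys=keys)


def build_sample_sets(
    counts_list: Sequence[UniqueReadCounts],
    min_copies: int = DEFAULT_MIN_COPIES,
    allow_single: bool = False,
) -> tuple[ReferenceSet, ComprehensiveSet]:
    """SHQ reference + comprehensive set for one sample from its duplicates."""
    hq = [high_quality_set(c, min_copies) for c in counts_list]
    ref = super_high_quality_set(
        hq,
        sample_id=counts_list[0].sample_id,
        provenance=[c.duplicate_id for c in counts_list],
        min_copies=min_copies,
        allow_single=allow_single,
    )
    comp = comprehensive_set(counts_list)
    assert ref.shq <= comp.keys, "SHQ must be a subset of the comprehensive set"
    return ref, comp


# ---------------------------------------------------------------------------
# plain-text serialization: sorted keys, small '#'-prefixed header
# ---------------------------------------------------------------------------

def write_keyset(
    path: str | os.PathLike,
    sample_id: str,
    keys: Set[str],
    kind: str,
    provenance: Sequence[str] = (),
    min_copies: int | None = None,
) -> None:
    """Serialize a key set as a sorted plain-text list with header metadata.

    Byte-identical given identical inputs, so reruns are diffable.
    """
    from . import __version__

    with open(path, "wt") as fh:
        fh.write(f"##sample_id={sample_id}\n")
        fh.write(f"##kind={kind}\n")
        if provenance:
            fh.write(f"##duplicates={','.join(provenance)}\n")
        if min_copies is not None:
            fh.write(f"##min_copies={min_copies}\n")
        fh.write(f"##idnaseq_version={__version__}\n")
        for k in sorted(keys):
            fh.write(k + "\n")


def read_keyset(path: str | os.PathLike) -> tuple[dict, Set[str]]:
    """Read a serialized key set; returns (header metadata, keys)."""
    meta: dict = {}
    keys: Set[str] = set()
    with open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                k, _, v = line[2:].partition("=")
                meta[k] = v
            elif line:
                keys.add(line)
    return meta, keys
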