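"""Paired-end FASTQ input/output with index-read (barcode) association.

MIG-seq libraries arrive as positionally synchronized R1/R2 FASTQ files
(plain or gzipped, Phred+33), optionally accompanied by an I1 index-read
file carrying the demultiplexing barcode and its base qualities.  This
module streams those triples as :class:`ReadPair` records, decodes Phred+33
qualities, and round-trips records back to FASTQ.

Only Phred+33 is supported (the MiSeq dialect); encodings containing
characters below ``'!'`` are rejected rather than silently reinterpreted.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33
QV_MAX = 93

MANIFEST_COLUMNS = [
    "sample_id",
    "cultivar",
    "duplicate_id",
    "r1_path",
    "r2_path",
    "index_path",
    "barcode",
]


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records or desynchronized mate files."""


def decode_quality(qual_text: str) -> np.ndarray:
    """Decode a Phred+33 quality string to an integer vector.

    Each character maps to ``ord(c) - 33``.  Characters below ASCII 33
    (which would indicate a Phred+64 or corrupt file) raise ``ValueError``.
    """
    arr = np.frombuffer(qual_text.encode("ascii"), dtype=np.uint8).astype(np.int16)
    arr -= PHRED_OFFSET
    if arr.size and arr.min() < 0:
        raise ValueError("invalid quality encoding: character below ASCII 33 ('!')")
    return arr


def encode_quality(qual: Iterable[int]) -> str:
    """Inverse of :func:`decode_quality` (values must lie in [0, 93])."""
    vals = np.asarray(list(qual), dtype=np.int16)
    if vals.size and (vals.min() < 0 or vals.max() > QV_MAX):
        raise ValueError("quality values must lie in [0, 93]")
    return (vals + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")


@dataclass
class ReadPair:
    """One sequenced fragment: both mates plus the index (barcode) read.

    Sequences are uppercase DNA over ``{A, C, G, T, N}``; qualities are
    integer vectors of the same length as their sequence.
    """

    read_id: str
    r1_seq: str
    r1_qual: np.ndarray
    r2_seq: str
    r2_qual: np.ndarray
    index_seq: str = ""
    index_qual: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int16))

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"sequence/quality length mismatch in read {self.read_id!r}")
        if len(self.index_seq) != len(self.index_qual):
            raise ValueError(f"index sequence/quality length mismatch in read {self.read_id!r}")


def _open_text(path: str | os.PathLike, mode: str = "rt") -> IO[str]:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _barcode_from_header(title: str) -> str:
    """Illumina 'barcode in header' dialect: sequence after the last ':'."""
    token = title.rsplit(":", 1)[-1].strip()
    if token and all(c in "ACGTN" for c in token.upper()):
        return token.upper()
    return ""


def read_paired_fastq(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike,
    index_path: Optional[str | os.PathLike] = None,
    barcode_from_header: bool = True,
) -> Iterator[ReadPair]:
    """Stream synchronized R1/R2(/I1) FASTQ files as :class:`ReadPair`s.

    Records are matched positionally; a count mismatch between the files is
    a fatal error naming both files.  Memory use is bounded per record.

    When ``index_path`` is absent and ``barcode_from_header`` is true, the
    barcode is taken from the read header (sequence after the last ``':'``)
    with all qualities assumed QV 40, since real index qualities are then
    unavailable; a warning is logged once per file pair.
    """
    _header_warned = False
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        if index_path is not None:
            hi = _open_text(index_path)
            iti = FastqGeneralIterator(hi)
        else:
            hi, iti = None, None
        try:
            n = 0
            while True:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
                if rec1 is None and rec2 is None:
                    if iti is not None and next(iti, None) is not None:
                        raise FastqFormatError(
                            f"record count mismatch: index file {index_path} has more "
                            f"records than {r1_path}"
                        )
                    return
                if rec1 is None or rec2 is None:
                    raise FastqFormatError(
                        f"record count mismatch between {r1_path} and {r2_path} "
                        f"after {n} records"
                    )
                n += 1
                t1, s1, q1 = rec1
                t2, s2, q2 = rec2
                if iti is not None:
                    reci = next(iti, None)
                    if reci is None:
                        raise FastqFormatError(
                            f"record count mismatch: index file {index_path} has fewer "
                            f"records than {r1_path} (after {n - 1} records)"
                        )
                    _, si, qi = reci
                    idx_seq, idx_qual = si.upper(), decode_quality(qi)
                else:
                    idx_seq = _barcode_from_header(t1) if barcode_from_header else ""
                    idx_qual = np.full(len(idx_seq), 40, dtype=np.int16)
                    if idx_seq and not _header_warned:
                        logger.warning(
                            "no index file for %s: barcode taken from read headers, "
                            "index qualities assumed QV 40",
                            r1_path,
                        )
                        _header_warned = True
                yield ReadPair(
                    read_id=t1.split()[0],
                    r1_seq=s1.upper(),
                    r1_qual=decode_quality(q1),
                    r2_seq=s2.upper(),
                    r2_qual=decode_quality(q2),
                    index_seq=idx_seq,
                    index_qual=idx_qual,
                )
        except ValueError as exc:
            # Bio raises bare ValueError for malformed records; re-tag with context.
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(f"malformed FASTQ record near record {n + 1}: {exc}") from exc
        finally:
            if hi is not None:
                hi.close()


def write_paired_fastq(
    pairs: Iterable[ReadPair],
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike,
    index_path: Optional[str | os.PathLike] = None,
) -> int:
    """Write ReadPairs to R1/R2(/I1) FASTQ files; returns the record count."""
    n = 0
    with _open_text(r1_path, "wt") as h1, _open_text(r2_path, "wt") as h2:
        hi = _open_text(index_path, "wt") if index_path is not None else None
        try:
            for p in pairs:
                h1.write(f"@{p.read_id}\n{p.r1_seq}\n+\n{encode_quality(p.r1_qual)}\n")
                h2.write(f"@{p.read_id}\n{p.r2_seq}\n+\n{encode_quality(p.r2_qual)}\n")
                if hi is not None:
                    hi.write(f"@{p.read_id}\n{p.index_seq}\n+\n{encode_quality(p.index_qual)}\n")
                n += 1
        finally:
            if hi is not None:
                hi.close()
    return n


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Load a sample manifest TSV and validate its structure.

    Columns: sample_id, cultivar, duplicate_id, r1_path, r2_path,
    index_path (may be empty), barcode.  (sample_id, duplicate_id) must be
    unique.  Relative file paths are resolved against the manifest's
    directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    dup = df.duplicated(subset=["sample_id", "duplicate_id"])
    if dup.any():
        rows = df.loc[dup, ["sample_id", "duplicate_id"]].to_records(index=False).tolist()
        raise ValueError(f"manifest has duplicate (sample_id, duplicate_id) rows: {rows}")
    base = os.path.dirname(os.path.abspath(os.fspath(path)))
    for col in ("r1_path", "r2_path", "index_path"):
        df[col] = [
            os.path.join(base, p) if p and not os.path.isabs(p) else p for p in df[col]
        ]
    return df


def write_manifest(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)


def check_min_duplicates(manifest: pd.DataFrame, allow_single: bool = False) -> None:
    """Every sample needs >=2 PCR duplicates unless single-duplicate mode is on."""
    counts = manifest.groupby("sample_id")["duplicate_id"].nunique()
    short = counts[counts < 2].index.tolist()
    if short and not allow_single:
        raise ValueError(
            f"samples with fewer than 2 PCR duplicates: {short} "
            "(enable single-duplicate mode explicitly to proceed)"
        )
    if short:
        logger.warning(
            "single-duplicate mode: samples %s have one library; reference sets "
            "will not be duplicate-confirmed",
            short,
        )
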