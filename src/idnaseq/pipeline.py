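"""End-to-end orchestration: filter -> build -> compare.

Each stage reads and writes plain files so a reference panel can be built
once and queried later against new samples (the forensic use-case: compare
a suspicious sample's read set against stored references).  Every output
directory receives the resolved configuration before computation, so a run
is re-executable from its own outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .fastq_io import (
    check_min_duplicates,
    read_manifest,
    read_paired_fastq,
    write_manifest,
    write_paired_fastq,
)
from .filtering import FilterConfig, FilterReport, filter_stream
from .refset import (
    DEFAULT_MIN_COPIES,
    ComprehensiveSet,
    ReferenceSet,
    build_sample_sets,
    count_unique,
    read_keyset,
    write_keyset,
)
from .similarity import (
    GroupSummary,
    SimilarityMatrix,
    group_summary,
    render_outputs,
    similarity_matrix,
)

logger = logging.getLogger(__name__)


def _echo_config(out_dir: str, stage: str, payload: dict) -> None:
    os.makedirs(out_dir, exist_ok=True)
    payload = dict(payload, idnaseq_version=__version__)
    with open(os.path.join(out_dir, f"{stage}_config.json"), "wt") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_filter(
    manifest_path: str,
    config: FilterConfig,
    out_dir: str,
    allow_single: bool = False,
) -> Tuple[str, pd.DataFrame, List[FilterReport]]:
    """Stage 1: stringent filtering of every (sample, duplicate) library.

    Writes one filtered R1/R2 FASTQ pair per library, a filtered manifest
    and a ``filter_report.tsv``; returns (filtered manifest path, frame,
    per-library reports).  The report conservation identity
    (input = kept + removed) is asserted for every library.
    """
    manifest = read_manifest(manifest_path)
    check_min_duplicates(manifest, allow_single=allow_single)
    _echo_config(out_dir, "filter", dataclasses.asdict(config) | {"manifest": manifest_path})
    reports: List[FilterReport] = []
    out_rows = []
    for row in manifest.itertuples(index=False):
        for p in (row.r1_path, row.r2_path):
            if not os.path.exists(p):
                raise FileNotFoundError(
                    f"manifest row ({row.sample_id}, {row.duplicate_id}): missing file {p}"
                )
        if row.index_path and not os.path.exists(row.index_path):
            raise FileNotFoundError(
                f"manifest row ({row.sample_id}, {row.duplicate_id}): missing file {row.index_path}"
            )
        report = FilterReport(sample_id=row.sample_id, duplicate_id=row.duplicate_id)
        pairs = read_paired_fastq(row.r1_path, row.r2_path, row.index_path or None)
        kept = filter_stream(pairs, row.barcode, config, report)
        r1_out = os.path.join(out_dir, f"{row.sample_id}_{row.duplicate_id}_R1.filtered.fastq")
        r2_out = os.path.join(out_dir, f"{row.sample_id}_{row.duplicate_id}_R2.filtered.fastq")
        write_paired_fastq(kept, r1_out, r2_out)
        report.check_conservation()
        reports.append(report)
        logger.info(
            "filter %s/%s: %d in, %d kept, %d removed",
            row.sample_id, row.duplicate_id, report.input_pairs,
            report.kept_pairs, report.removed_total,
        )
        out_rows.append({
            "sample_id": row.sample_id, "cultivar": row.cultivar,
            "duplicate_id": row.duplicate_id,
            "r1_path": r1_out, "r2_path": r2_out,
            "index_path": "", "barcode": row.barcode,
        })
    report_df = pd.DataFrame([dataclasses.asdict(r) for r in reports],
                             columns=FilterReport.tsv_columns())
    report_df.to_csv(os.path.join(out_dir, "filter_report.tsv"), sep="\t", index=False)
    filtered_manifest = pd.DataFrame(out_rows)
    fm_path = os.path.join(out_dir, "manifest.filtered.tsv")
    write_manifest(filtered_manifest, fm_path)
    return fm_path, filtered_manifest, reports


def run_build(
    manifest_path: str,
    out_dir: str,
    min_copies: int = DEFAULT_MIN_COPIES,
    strand_pool: bool = True,
    allow_single: bool = False,
) -> Dict[str, Tuple[ReferenceSet, ComprehensiveSet]]:
    """Stage 2: per-sample SHQ reference and comprehensive sets.

    Reads filtered libraries (index files no longer needed), counts unique
    canonical keys per PCR duplicate, intersects per-duplicate high-quality
    sets into the SHQ reference and unions everything into the
    comprehensive set; serializes both per sample as sorted key lists.
    """
    manifest = read_manifest(manifest_path)
    check_min_duplicates(manifest, allow_single=allow_single)
    _echo_config(out_dir, "build", {
        "manifest": manifest_path, "min_copies": min_copies,
        "strand_pool": strand_pool,
    })
    sets: Dict[str, Tuple[ReferenceSet, ComprehensiveSet]] = {}
    for sample_id, group in manifest.groupby("sample_id", sort=True):
        counts = []
        for row in group.itertuples(index=False):
            pairs = read_paired_fastq(row.r1_path, row.r2_path,
                                      row.index_path or None, barcode_from_header=False)
            counts.append(count_unique(pairs, sample_id, row.duplicate_id,
                                       strand_pool=strand_pool))
        ref, comp = build_sample_sets(counts, min_copies=min_copies,
                                      allow_single=allow_single)
        write_keyset(os.path.join(out_dir, f"{sample_id}.shq.keys"),
                     sample_id, ref.shq, "shq",
                     provenance=ref.provenance, min_copies=min_copies)
        write_keyset(os.path.join(out_dir, f"{sample_id}.comprehensive.keys"),
                     sample_id, comp.keys, "comprehensive",
                     provenance=[c.duplicate_id for c in counts])
        logger.info("build %s: |SHQ|=%d, |comprehensive|=%d",
                    sample_id, len(ref.shq), len(comp.keys))
        if not ref.shq:
            logger.warning(
                "sample %s has an EMPTY SHQ reference (depth too low for the "
                ">%d-copy threshold?); it cannot serve as a comparison target",
                sample_id, min_copies - 1,
            )
        sets[sample_id] = (ref, comp)
    return sets


def load_sets(set_dir: str) -> Dict[str, Tuple[ReferenceSet, ComprehensiveSet]]:
    """Load serialized per-sample key sets from a build directory."""
    sets: Dict[str, Tuple[ReferenceSet, ComprehensiveSet]] = {}
    for fn in sorted(os.listdir(set_dir)):
        if not fn.endswith(".shq.keys"):
            continue
        sample_id = fn[: -len(".shq.keys")]
        meta, shq = read_keyset(os.path.join(set_dir, fn))
        _, comp = read_keyset(os.path.join(set_dir, f"{sample_id}.comprehensive.keys"))
        ref = ReferenceSet(
            sample_id=sample_id, shq=shq,
            provenance=meta.get("duplicates", "").split(",") if meta.get("duplicates") else [],
            min_copies=int(meta.get("min_copies", DEFAULT_MIN_COPIES)),
        )
        sets[sample_id] = (ref, ComprehensiveSet(sample_id=sample_id, keys=comp))
    if not sets:
        raise ValueError(f"no serialized key sets found in {set_dir}")
    return sets


def run_compare(
    sets: Dict[str, Tuple[ReferenceSet, ComprehensiveSet]],
    labels: Dict[str, str],
    out_dir: str,
    diagonal_dash: bool = False,
    heatmap: bool = True,
    transpose: bool = False,
) -> Tuple[SimilarityMatrix, List[GroupSummary]]:
    """Stage 3: all-vs-all similarity matrix, group summaries and renders.

    ``transpose`` swaps the query/target roles in the rendered matrix
    (rows become targets), for comparison against tables printed the other
    way around.
    """
    _echo_config(out_dir, "compare", {
        "samples": sorted(sets), "labels": labels,
        "diagonal_dash": diagonal_dash, "transpose": transpose,
    })
    sample_ids = sorted(sets)
    pairs = [(sets[s][1], sets[s][0]) for s in sample_ids]
    matrix = similarity_matrix(pairs, labels)
    if transpose:
        matrix = SimilarityMatrix(
            sample_ids=matrix.sample_ids,
            cultivar_labels=matrix.cultivar_labels,
            values=matrix.values.T.copy(),
            n_matched=matrix.n_matched.T.copy(),
            n_target=matrix.n_target.T.copy(),
        )
    summaries = []
    for mode in ("all", "same_cultivar", "different_cultivar"):
        try:
            summaries.append(group_summary(matrix, mode))
        except ValueError:
            logger.info("group %s: no pairs, skipped", mode)
    render_outputs(matrix, summaries, out_dir,
                   diagonal_dash=diagonal_dash, heatmap=heatmap)
    return matrix, summaries


def run_pipeline(
    manifest_path: str,
    config: FilterConfig,
    out_dir: str,
    min_copies: int = DEFAULT_MIN_COPIES,
    strand_pool: bool = True,
    allow_single: bool = False,
    heatmap: bool = True,
) -> Tuple[SimilarityMatrix, List[GroupSummary]]:
    """Run filter -> build -> compare, keeping intermediate artifacts."""
    filt_dir = os.path.join(out_dir, "filtered")
    build_dir = os.path.join(out_dir, "sets")
    cmp_dir = os.path.join(out_dir, "compare")
    fm_path, fm, _ = run_filter(manifest_path, config, filt_dir, allow_single=allow_single)
    sets = run_build(fm_path, build_dir, min_copies=min_copies,
                     strand_pool=strand_pool, allow_single=allow_single)
    labels = dict(zip(fm["sample_id"], fm["cultivar"]))
    return run_compare(sets, labels, cmp_dir, heatmap=heatmap)
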