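"""Exact-matching-rate similarity, pairwise matrices and group summaries.

The similarity of a query sample to a target sample is the fraction of the
TARGET's super-high-quality reference reads found exactly (strand-folded)
in the QUERY's comprehensive set:

    s(query, target) = |SHQ(target) ∩ Comp(query)| / |SHQ(target)|

The denominator belongs to the target, so the statistic is asymmetric —
s(q, t) and s(t, q) generally differ.  A sample queried against itself is
1.0 by construction (its comprehensive set contains its SHQ reference),
which is the method's definitional anchor.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .refset import ComprehensiveSet, ReferenceSet


class EmptyReferenceError(ValueError):
    """Target sample has no super-high-quality reference reads.

    Distinct from similarity 0: a sample without a reference cannot be a
    comparison target at all, and treating it as "no overlap" would corrupt
    group means.
    """


def similarity(query: ComprehensiveSet, target: ReferenceSet) -> float:
    """Exact matching rate of the target's SHQ reference within the query."""
    m, n = match_counts(query, target)
    return m / n


def match_counts(query: ComprehensiveSet, target: ReferenceSet) -> Tuple[int, int]:
    """(number of target SHQ keys found in query, target SHQ size)."""
    if not target.shq:
        raise EmptyReferenceError(
            f"target sample {target.sample_id!r} has no super high-quality "
            "reference reads"
        )
    return len(target.shq & query.keys), len(target.shq)


@dataclass
class SimilarityMatrix:
    """Asymmetric query x target matrix of exact matching rates.

    Row ``q`` is the query (comprehensive set), column ``t`` the target
    (SHQ reference).  ``n_matched``/``n_target`` hold the integer
    numerators and denominators so every rate is recomputable.
    """

    sample_ids: List[str]
    cultivar_labels: Dict[str, str]
    values: np.ndarray
    n_matched: np.ndarray
    n_target: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class GroupSummary:
    """Mean +/- sample s.d. of similarities over a group of ordered pairs."""

    group: str
    n_pairs: int
    mean: float
    sd: float


def similarity_matrix(
    samples: Sequence[Tuple[ComprehensiveSet, ReferenceSet]],
    labels: Mapping[str, str],
) -> SimilarityMatrix:
    """All ordered pairwise similarities, diagonal included.

    Every sample's SHQ must be nonempty; an empty reference is reported by
    sample id.  Needs at least two samples.
    """
    if len(samples) < 2:
        raise ValueError("need >=2 samples for a similarity matrix")
    ids = [comp.sample_id for comp, _ in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in matrix input")
    for comp, ref in samples:
        if comp.sample_id != ref.sample_id:
            raise ValueError(
                f"mismatched comprehensive/reference pair: {comp.sample_id} vs {ref.sample_id}"
            )
        if not ref.shq:
            raise EmptyReferenceError(
                f"target sample {ref.sample_id!r} has no super high-quality reference reads"
            )
    n = len(samples)
    vals = np.zeros((n, n))
    matched = np.zeros((n, n), dtype=np.int64)
    target_n = np.zeros((n, n), dtype=np.int64)
    for qi, (comp, _) in enumerate(samples):
        for ti, (_, ref) in enumerate(samples):
            m, d = match_counts(comp, ref)
            vals[qi, ti] = m / d
            matched[qi, ti] = m
            target_n[qi, ti] = d
    return SimilarityMatrix(
        sample_ids=ids,
        cultivar_labels={s: labels[s] for s in ids},
        values=vals,
        n_matched=matched,
        n_target=target_n,
    )


def group_summary(matrix: SimilarityMatrix, mode: str | Tuple[str, str]) -> GroupSummary:
    """Aggregate off-diagonal entries by cultivar relation.

    ``mode`` is one of ``'all'``, ``'same_cultivar'``, ``'different_cultivar'``
    or a ``(cultivar_a, cultivar_b)`` pair (both orientations pooled).
    Ordered pairs are used throughout because the statistic is asymmetric;
    the s.d. is the sample (n-1) standard deviation, 0.0 for a single pair.
    """
    ids = matrix.sample_ids
    cult = matrix.cultivar_labels
    picked: List[float] = []
    for qi, q in enumerate(ids):
        for ti, t in enumerate(ids):
            if qi == ti:
                continue
            cq, ct = cult[q], cult[t]
            if mode == "all":
                ok = True
            elif mode == "same_cultivar":
                ok = cq == ct
            elif mode == "different_cultivar":
                ok = cq != ct
            elif isinstance(mode, tuple) and len(mode) == 2:
                ok = (cq, ct) == mode or (ct, cq) == mode
            else:
                raise ValueError(f"unknown group mode {mode!r}")
            if ok:
                picked.append(float(matrix.values[qi, ti]))
    if not picked:
        raise ValueError(f"no pairs in group {mode!r}")
    arr = np.asarray(picked)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    label = mode if isinstance(mode, str) else f"{mode[0]}|{mode[1]}"
    return GroupSummary(group=label, n_pairs=arr.size, mean=float(arr.mean()), sd=sd)


def render_outputs(
    matrix: SimilarityMatrix,
    summaries: Sequence[GroupSummary],
    out_dir: str | os.PathLike,
    diagonal_dash: bool = False,
    heatmap: bool = True,
) -> Dict[str, str]:
    """Write the matrix and summaries as TSVs (plus an optional heatmap).

    Files written to ``out_dir``:

    - ``similarity_matrix.tsv`` — wide query x target matrix; the diagonal
      is rendered as ``-`` when ``diagonal_dash`` (tabular dialect of the
      published pairwise tables) though it is always stored as 1.0;
    - ``similarity_pairs.tsv`` — long form: query, target, cultivars,
      similarity, n_matched, n_target_shq;
    - ``group_summary.tsv`` — group label, n_pairs, mean, sd;
    - ``similarity_heatmap.png`` — darker = more shared sequences.

    Reruns on identical inputs produce byte-identical TSVs.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    wide = matrix.to_frame().round(6).astype(object)
    if diagonal_dash:
        for s in matrix.sample_ids:
            wide.loc[s, s] = "-"
    wide_path = os.path.join(out_dir, "similarity_matrix.tsv")
    wide.to_csv(wide_path, sep="\t", index_label="sample")
    paths["matrix"] = wide_path

    rows = []
    for qi, q in enumerate(matrix.sample_ids):
        for ti, t in enumerate(matrix.sample_ids):
            rows.append(
                {
                    "query": q,
                    "target": t,
                    "query_cultivar": matrix.cultivar_labels[q],
                    "target_cultivar": matrix.cultivar_labels[t],
                    "similarity": round(float(matrix.values[qi, ti]), 6),
                    "n_matched": int(matrix.n_matched[qi, ti]),
                    "n_target_shq": int(matrix.n_target[qi, ti]),
                }
            )
    long_path = os.path.join(out_dir, "similarity_pairs.tsv")
    pd.DataFrame(rows).to_csv(long_path, sep="\t", index=False)
    paths["pairs"] = long_path

    if summaries:
        sum_path = os.path.join(out_dir, "group_summary.tsv")
        pd.DataFrame(
            [
                {"group": s.group, "n_pairs": s.n_pairs,
                 "mean": round(s.mean, 6), "sd": round(s.sd, 6)}
                for s in summaries
            ]
        ).to_csv(sum_path, sep="\t", index=False)
        paths["summary"] = sum_path

    if heatmap:
        paths["heatmap"] = _plot_heatmap(matrix, os.path.join(out_dir, "similarity_heatmap.png"))
    return paths


def _plot_heatmap(matrix: SimilarityMatrix, path: str) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(matrix.sample_ids)
    fig, ax = plt.subplots(figsize=(max(4, 0.45 * n + 2),) * 2)
    im = ax.imshow(matrix.values, cmap="Greys", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(n), matrix.sample_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(n), matrix.sample_ids, fontsize=7)
    ax.set_xlabel("target (SHQ reference)")
    ax.set_ylabel("query (comprehensive set)")
    fig.colorbar(im, ax=ax, label="exact matching rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
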