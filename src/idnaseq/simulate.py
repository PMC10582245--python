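"""Synthetic MIG-seq-like cohort simulator with known ground truth.

Emulates the structure of a multiplexed reduced-representation sequencing
study of clonally propagated cultivars: a genealogy of cultivars (clones at
divergence 0, bud mutants at near-zero divergence, distinct lines, and
well-diverged cultivars), each sampled one or more times, each sample
sequenced as two independent PCR-duplicate libraries.

Reads are locus-anchored: every read pair from a locus is the identical
fragment before sequencing error — mate 1 is the first ``r1_len`` bases,
mate 2 the reverse complement of the last ``r2_len`` bases — which is what
makes the "more than 10 identical copies" reference threshold attainable,
as it is for fixed primer-anchored amplicons.  Per-locus depth is
negative-binomial (amplicon depth is overdispersed; the Poisson limit is
available via ``depth_dispersion=inf``).  Error bases are substituted i.i.d.
at ``seq_error_rate`` and tagged with a low quality value; a fraction of
pairs is emitted in flipped orientation (mates swapped, both
reverse-complemented) to exercise strand folding downstream.

Randomness is hierarchical: one global seed, with per-(sample, duplicate)
substreams derived deterministically from the ids, so any single library
can be regenerated in isolation.  Structural draws (locus dropout, depth)
use a separate substream from per-read draws (error, flip, adapter), so
changing the error or flip settings leaves the locus/depth realization
untouched.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fastq_io import ReadPair, write_paired_fastq, write_manifest, MANIFEST_COLUMNS
from .refset import revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_ADAPTER = "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC"  # Nextera-style mosaic end


@dataclass(frozen=True)
class CultivarNode:
    """One cultivar in the genealogy: its parent and per-base divergence
    (substitution probability per base) along the branch from the parent."""

    cultivar_id: str
    parent_id: Optional[str] = None
    divergence: float = 0.0


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    cultivar_id: str
    n_duplicates: int = 2


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe a small but realistic desk-scale MIG-seq run: 75+75
    base paired reads of 150-base amplicons (a 150-cycle kit), ~20 read
    pairs per locus per PCR duplicate with overdispersion, a 0.1% per-base
    error rate, light locus dropout and rare adapter read-through.
    """

    n_loci: int = 200
    locus_len: int = 150
    r1_len: int = 75
    r2_len: int = 75
    cultivar_tree: List[CultivarNode] = field(
        default_factory=lambda: [CultivarNode("C1")]
    )
    samples: List[SampleSpec] = field(
        default_factory=lambda: [SampleSpec("C1-a", "C1"), SampleSpec("C1-b", "C1")]
    )
    depth_mean: float = 20.0
    depth_dispersion: float = 5.0
    locus_dropout_prob: float = 0.02
    duplicate_dropout_prob: float = 0.0
    seq_error_rate: float = 0.001
    base_qv_high: int = 40
    base_qv_low: int = 14
    barcode_len: int = 8
    adapter: str = DEFAULT_ADAPTER
    adapter_contam_prob: float = 0.01
    flip_prob: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.locus_dropout_prob, self.duplicate_dropout_prob,
                  self.seq_error_rate, self.adapter_contam_prob, self.flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_loci, self.locus_len, self.r1_len, self.r2_len) <= 0:
            raise ValueError("n_loci and read/locus lengths must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.r1_len + self.r2_len > 2 * self.locus_len:
            raise ValueError("reads longer than the locus on both ends")
        self._validate_tree()

    def _validate_tree(self) -> None:
        ids = [n.cultivar_id for n in self.cultivar_tree]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cultivar ids in tree")
        roots = [n for n in self.cultivar_tree if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"cultivar tree must have exactly one root (got {len(roots)})")
        known = set()
        for n in self.cultivar_tree:  # parents must precede children: no cycles
            if n.parent_id is not None and n.parent_id not in known:
                raise ValueError(
                    f"cultivar {n.cultivar_id!r} listed before its parent {n.parent_id!r} "
                    "(tree must be in parent-first order and acyclic)"
                )
            known.add(n.cultivar_id)
        for s in self.samples:
            if s.cultivar_id not in known:
                raise ValueError(f"sample {s.sample_id!r} references unknown cultivar")


def _substream(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic named RNG substream: seed words from crc32 of the tokens."""
    words = [seed & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(words)


def simulate_genomes(config: SimulationConfig) -> Dict[str, List[str]]:
    """Per-cultivar locus sequences.

    The root's loci are uniform random sequences; each child copies its
    parent with i.i.d. per-base substitution at the branch divergence rate.
    Deterministic given ``config.rng_seed``.
    """
    genomes: Dict[str, np.ndarray] = {}
    for node in config.cultivar_tree:
        rng = _substream(config.rng_seed, "genome", node.cultivar_id)
        if node.parent_id is None:
            g = BASES[rng.integers(0, 4, size=(config.n_loci, config.locus_len))]
        else:
            g = genomes[node.parent_id].copy()
            if node.divergence > 0:
                mask = rng.random(g.shape) < node.divergence
                # substitute to one of the three OTHER bases
                idx = np.searchsorted(BASES, g[mask])
                shift = rng.integers(1, 4, size=mask.sum())
                g[mask] = BASES[(idx + shift) % 4]
        genomes[node.cultivar_id] = g
    return {
        cid: [row.tobytes().decode() for row in g] for cid, g in genomes.items()
    }


def pairwise_divergence(config: SimulationConfig) -> pd.DataFrame:
    """Expected per-base divergence between every ordered cultivar pair.

    The path sum of branch divergences through the genealogy (an additive
    upper bound; coincident substitutions make realized divergence very
    slightly lower).  Symmetric with a zero diagonal.
    """
    parent = {n.cultivar_id: n.parent_id for n in config.cultivar_tree}
    div = {n.cultivar_id: n.divergence for n in config.cultivar_tree}

    def path_to_root(c: str) -> Dict[str, float]:
        out, d = {}, 0.0
        while c is not None:
            out[c] = d
            d += div[c]
            c = parent[c]
        return out

    ids = list(parent)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    paths = {c: path_to_root(c) for c in ids}
    for a in ids:
        for b in ids:
            shared = set(paths[a]) & set(paths[b])
            mrca = min(shared, key=lambda c: paths[a][c] + paths[b][c])
            mat.loc[a, b] = paths[a][mrca] + paths[b][mrca]
    return mat


def _barcodes(config: SimulationConfig) -> Dict[str, str]:
    rng = _substream(config.rng_seed, "barcodes")
    out: Dict[str, str] = {}
    seen = set()
    for s in config.samples:
        while True:
            bc = "".join(BASES[rng.integers(0, 4, size=config.barcode_len)].astype(str))
            if bc not in seen:
                break
        seen.add(bc)
        out[s.sample_id] = bc
    return out


def _apply_errors(
    seq: str, rng: np.random.Generator, rate: float, qv_high: int, qv_low: int
) -> Tuple[str, np.ndarray]:
    qual = np.full(len(seq), qv_high, dtype=np.int16)
    if rate <= 0:
        return seq, qual
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq, qual
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    idx = np.searchsorted(BASES, arr[mask])
    shift = rng.integers(1, 4, size=mask.sum())
    arr[mask] = BASES[(idx + shift) % 4]
    qual[mask] = qv_low
    return arr.tobytes().decode(), qual


def simulate_duplicate_reads(
    genomes: Dict[str, List[str]],
    sample: SampleSpec,
    duplicate_id: str,
    barcode: str,
    config: SimulationConfig,
    sample_dropout_mask: np.ndarray,
) -> Iterator[ReadPair]:
    """Generate the read pairs of one PCR-duplicate library, in locus order."""
    loci = genomes[sample.cultivar_id]
    rng_struct = _substream(config.rng_seed, "lib", sample.sample_id, duplicate_id, "struct")
    rng_read = _substream(config.rng_seed, "lib", sample.sample_id, duplicate_id, "read")

    n = config.n_loci
    if config.duplicate_dropout_prob > 0:
        dup_drop = rng_struct.random(n) < config.duplicate_dropout_prob
    else:
        dup_drop = np.zeros(n, dtype=bool)
    if np.isfinite(config.depth_dispersion):
        k = config.depth_dispersion
        depths = rng_struct.negative_binomial(k, k / (k + config.depth_mean), size=n)
    else:
        depths = rng_struct.poisson(config.depth_mean, size=n)

    bc_qual = np.full(len(barcode), config.base_qv_high, dtype=np.int16)
    serial = 0
    for li, locus in enumerate(loci):
        if sample_dropout_mask[li] or dup_drop[li] or depths[li] == 0:
            continue
        r1_t = locus[: config.r1_len]
        r2_t = revcomp(locus[-config.r2_len:])
        for _ in range(int(depths[li])):
            r1, q1 = _apply_errors(r1_t, rng_read, config.seq_error_rate,
                                   config.base_qv_high, config.base_qv_low)
            r2, q2 = _apply_errors(r2_t, rng_read, config.seq_error_rate,
                                   config.base_qv_high, config.base_qv_low)
            if config.flip_prob and rng_read.random() < config.flip_prob:
                r1, r2 = revcomp(r2), revcomp(r1)
                q1, q2 = q2[::-1], q1[::-1]
            # adapter read-through happens in sequencing orientation, i.e.
            # after any strand flip, so the literal adapter lands at a 3' end
            if config.adapter and rng_read.random() < config.adapter_contam_prob:
                if rng_read.random() < 0.5:
                    r1 = r1 + config.adapter
                    q1 = np.concatenate([q1, np.full(len(config.adapter),
                                                     config.base_qv_high, dtype=np.int16)])
                else:
                    r2 = r2 + config.adapter
                    q2 = np.concatenate([q2, np.full(len(config.adapter),
                                                     config.base_qv_high, dtype=np.int16)])
            serial += 1
            yield ReadPair(
                read_id=f"{sample.sample_id}:{duplicate_id}:L{li}:{serial}",
                r1_seq=r1, r1_qual=q1, r2_seq=r2, r2_qual=q2,
                index_seq=barcode, index_qual=bc_qual.copy(),
            )


def simulate_library(
    genomes: Dict[str, List[str]],
    sample: SampleSpec,
    config: SimulationConfig,
    out_dir: str | os.PathLike,
    barcode: Optional[str] = None,
) -> List[dict]:
    """Write one sample's PCR-duplicate libraries as R1/R2/I1 FASTQ files.

    Locus dropout is decided once per sample (shared across duplicates),
    with optional extra per-duplicate dropout.  Returns manifest rows.
    """
    if sample.cultivar_id not in genomes:
        raise ValueError(f"cultivar {sample.cultivar_id!r} not in genomes")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if barcode is None:
        barcode = _barcodes(config)[sample.sample_id]
    rng_sample = _substream(config.rng_seed, "sample", sample.sample_id)
    sample_drop = rng_sample.random(config.n_loci) < config.locus_dropout_prob

    rows = []
    for d in range(1, sample.n_duplicates + 1):
        dup_id = f"rep{d}"
        r1 = os.path.join(out_dir, f"{sample.sample_id}_{dup_id}_R1.fastq")
        r2 = os.path.join(out_dir, f"{sample.sample_id}_{dup_id}_R2.fastq")
        i1 = os.path.join(out_dir, f"{sample.sample_id}_{dup_id}_I1.fastq")
        reads = simulate_duplicate_reads(genomes, sample, dup_id, barcode,
                                         config, sample_drop)
        write_paired_fastq(reads, r1, r2, i1)
        rows.append({
            "sample_id": sample.sample_id,
            "cultivar": sample.cultivar_id,
            "duplicate_id": dup_id,
            "r1_path": r1, "r2_path": r2, "index_path": i1,
            "barcode": barcode,
        })
    return rows


def simulate_cohort(
    config: SimulationConfig, out_dir: str | os.PathLike
) -> Tuple[str, pd.DataFrame]:
    """Simulate the whole cohort: FASTQ files, manifest TSV and truth tables.

    Returns (manifest path, manifest frame).  Truth written alongside:
    ``truth_divergence.tsv`` (ordered cultivar-pair path divergences) and
    ``truth_samples.tsv`` (sample → cultivar, barcode, loci retained).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    genomes = simulate_genomes(config)
    barcodes = _barcodes(config)
    rows: List[dict] = []
    truth_samples = []
    for sample in config.samples:
        rows.extend(simulate_library(genomes, sample, config, out_dir,
                                     barcode=barcodes[sample.sample_id]))
        rng_sample = _substream(config.rng_seed, "sample", sample.sample_id)
        drop = rng_sample.random(config.n_loci) < config.locus_dropout_prob
        truth_samples.append({
            "sample_id": sample.sample_id,
            "cultivar": sample.cultivar_id,
            "barcode": barcodes[sample.sample_id],
            "n_loci_retained": int((~drop).sum()),
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    write_manifest(manifest, manifest_path)
    pairwise_divergence(config).to_csv(
        os.path.join(out_dir, "truth_divergence.tsv"), sep="\t", index_label="cultivar")
    pd.DataFrame(truth_samples).to_csv(
        os.path.join(out_dir, "truth_samples.tsv"), sep="\t", index=False)
    return manifest_path, manifest


def expected_pair_similarity(divergence: float, r1_len: int, r2_len: int) -> float:
    """Closed-form asymptotic similarity between two cultivars.

    With per-base divergence ``d``, an error-free read pair covering
    ``r1_len + r2_len`` bases matches the other cultivar's locus exactly
    with probability ``(1 - d) ** (r1_len + r2_len)`` — the expected
    similarity under no error, no dropout and saturating depth.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    return (1.0 - divergence) ** (r1_len + r2_len)
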