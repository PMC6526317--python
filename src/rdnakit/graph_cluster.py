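"""Quality filtering, read similarity graphs and cluster homogeneity.

Reads become nodes of an undirected graph; two reads are connected when
their best local alignment (either strand) reaches at least
``min_identity`` percent identity over at least ``min_overlap_fraction``
of the shorter read's length.  Clusters are the connected components of
that graph.  This is a deliberate simplification of community-detection
based repeat clustering: connected components are deterministic and
sufficient to detect whether 35S and 5S reads co-cluster.

All-to-all alignment is accelerated by a shared-k-mer prefilter; at the
90 % identity threshold a qualifying pair of >=90-bp reads virtually
always shares an exact 13-mer, and an exhaustive all-pairs oracle guards
the prefilter in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from rdnakit._align import best_local_alignment, revcomp
from rdnakit.unit_model import ValidationError


@dataclass(frozen=True)
class GraphParams:
    """Edge rule for the read similarity graph.

    ``overlap_denominator`` selects whether the alignment span is measured
    against the shorter or the longer read; the classic rule does not pin
    this down, so both are supported ("shorter" is the default).
    """

    min_identity: float = 90.0
    min_overlap_fraction: float = 0.55
    both_strands: bool = True
    overlap_denominator: str = "shorter"
    kmer_size: int = 13

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValidationError("min_identity must be in (0, 100]")
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValidationError("min_overlap_fraction must be in (0, 1]")
        if self.overlap_denominator not in ("shorter", "longer"):
            raise ValidationError("overlap_denominator must be 'shorter' or 'longer'")


DEFAULT_PARAMS = GraphParams()


# --------------------------------------------------------------------------
# Quality filtering


def read_passes_quality(
    quals: Sequence[int], q_min: int = 20, max_low_fraction: float = 0.10
) -> bool:
    """A read fails iff strictly more than ``max_low_fraction`` of its bases
    are below Phred ``q_min``."""
    quals = np.asarray(quals)
    if quals.size == 0:
        return False
    return np.count_nonzero(quals < q_min) <= max_low_fraction * quals.size


def parse_fastq(path: str | Path):
    """Yield (name, sequence, phred qualities) from a Phred+33 FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValidationError(f"{path}: record {index}: {exc}") from exc
            yield title.split()[0], seq.upper(), [ord(c) - 33 for c in qual]
            index += 1


def filter_reads(
    fastq_in: str | Path,
    fastq_out: str | Path,
    q_min: int = 20,
    max_low_fraction: float = 0.10,
) -> tuple[int, int]:
    """Single-file quality filter; returns (kept, removed)."""
    kept = removed = 0
    with open(fastq_out, "w") as out:
        for name, seq, quals in parse_fastq(fastq_in):
            if read_passes_quality(quals, q_min, max_low_fraction):
                out.write(f"@{name}\n{seq}\n+\n{''.join(chr(q + 33) for q in quals)}\n")
                kept += 1
            else:
                removed += 1
    return kept, removed


def load_read_pairs(fastq1: str | Path, fastq2: str | Path):
    """Read two mate files into a list of (base name, mate1, mate2) where a
    mate is (name, seq, quals).  Mates are paired by file order; mismatched
    base names (before a ``/`` suffix) raise."""
    pairs = []
    for i, (m1, m2) in enumerate(
        itertools.zip_longest(parse_fastq(fastq1), parse_fastq(fastq2))
    ):
        if m1 is None or m2 is None:
            raise ValidationError("mate files have different numbers of records")
        b1, b2 = m1[0].split("/")[0], m2[0].split("/")[0]
        if b1 != b2:
            raise ValidationError(f"record {i}: mate names {b1!r} and {b2!r} differ")
        pairs.append((b1, m1, m2))
    return pairs


def filter_read_pairs(
    pairs,
    q_min: int = 20,
    max_low_fraction: float = 0.10,
    drop_pair_if_either_fails: bool = True,
):
    """Quality-filter mate pairs; by default a pair is dropped when either
    mate fails, preserving mate pairing in the output."""
    kept = []
    for base, m1, m2 in pairs:
        ok1 = read_passes_quality(m1[2], q_min, max_low_fraction)
        ok2 = read_passes_quality(m2[2], q_min, max_low_fraction)
        if drop_pair_if_either_fails:
            if ok1 and ok2:
                kept.append((base, m1, m2))
        elif ok1 or ok2:
            kept.append((base, m1 if ok1 else None, m2 if ok2 else None))
    return kept


# --------------------------------------------------------------------------
# Pairwise similarity and the graph


def pairwise_identity(
    a: str, b: str, params: GraphParams = DEFAULT_PARAMS
) -> tuple[float, float]:
    """Best local alignment of ``b`` (either strand) on ``a``.

    Returns (identity percent over alignment columns, alignment span as a
    fraction of the shorter -- or longer, per ``params`` -- read length).
    """
    if not a or not b:
        raise ValidationError("pairwise_identity requires non-empty sequences")
    hit = best_local_alignment(a, b, both_strands=params.both_strands)
    if hit.columns == 0:
        return 0.0, 0.0
    denom = min(len(a), len(b)) if params.overlap_denominator == "shorter" else max(len(a), len(b))
    return hit.identity, hit.columns / denom


def is_edge(identity: float, overlap: float, params: GraphParams = DEFAULT_PARAMS) -> bool:
    return identity >= params.min_identity and overlap >= params.min_overlap_fraction


def _candidate_pairs(reads: Mapping[str, str], params: GraphParams):
    """Unordered read pairs sharing at least one canonical k-mer."""
    k = params.kmer_size
    buckets: dict[str, list[str]] = {}
    for rid, seq in reads.items():
        seen = set()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if params.both_strands:
                km = min(km, revcomp(km))
            if km not in seen:
                seen.add(km)
                buckets.setdefault(km, []).append(rid)
    pairs = set()
    for ids in buckets.values():
        if len(ids) > 1:
            pairs.update(itertools.combinations(ids, 2))
    return pairs


def build_similarity_graph(
    reads: Mapping[str, str],
    params: GraphParams = DEFAULT_PARAMS,
    exhaustive: bool = False,
) -> nx.Graph:
    """Similarity graph over ``reads`` (id -> sequence).

    ``exhaustive=True`` disables the k-mer prefilter and aligns every pair;
    it is the oracle mode used to validate the prefilter.
    """
    graph = nx.Graph()
    graph.add_nodes_from(reads)
    if exhaustive:
        candidates = itertools.combinations(sorted(reads), 2)
    else:
        candidates = sorted(_candidate_pairs(reads, params))
    for u, v in candidates:
        identity, overlap = pairwise_identity(reads[u], reads[v], params)
        if is_edge(identity, overlap, params):
            graph.add_edge(u, v, identity=identity, overlap=overlap)
    return graph


@dataclass
class ClusterProfile:
    """A read cluster with optional genome proportion and pair-identity histogram."""

    member_reads: frozenset[str]
    genome_proportion: float | None = None
    similarity_histogram: np.ndarray | None = None

    @property
    def size(self) -> int:
        return len(self.member_reads)


def cluster_reads(graph: nx.Graph) -> list[ClusterProfile]:
    """Connected components, sorted by (size desc, smallest read id)."""
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [ClusterProfile(member_reads=c) for c in comps]


def cluster_genome_proportion(cluster: ClusterProfile, n_total_reads: int) -> float:
    """GP of a cluster: member reads / total reads analysed."""
    if n_total_reads <= 0:
        raise ValidationError("n_total_reads must be positive")
    if cluster.size > n_total_reads:
        raise ValidationError("cluster larger than the total read count")
    return cluster.size / n_total_reads


HIST_BINS = np.arange(0.0, 101.0, 1.0)  # 1-point bins over [0, 100]


def homogeneity_histogram(
    reads: Mapping[str, str], params: GraphParams = DEFAULT_PARAMS
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pairwise percent identities within a cluster.

    Every unordered pair is scored once (no self comparisons, reciprocal
    duplicates collapsed); pairs whose alignment span fails the overlap
    criterion are excluded.  Returns (counts over 1-point bins, identities).
    """
    identities = pair_identities(reads, params)
    counts, _ = np.histogram(np.clip(identities, 0, 100 - 1e-9), bins=HIST_BINS)
    return counts, identities


def pair_identities(
    reads: Mapping[str, str], params: GraphParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Percent identities of all unordered read pairs passing the overlap rule."""
    ids = sorted(reads)
    vals = []
    for u, v in itertools.combinations(ids, 2):
        identity, overlap = pairwise_identity(reads[u], reads[v], params)
        if overlap >= params.min_overlap_fraction:
            vals.append(identity)
    return np.asarray(vals, dtype=float)


def mean_pair_identity(reads: Mapping[str, str], params: GraphParams = DEFAULT_PARAMS) -> float:
    vals = pair_identities(reads, params)
    return float(vals.mean()) if vals.size else float("nan")


# --------------------------------------------------------------------------
# Tabular export


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_a\tread_b\tidentity\toverlap\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['identity']:.3f}\t{d['overlap']:.4f}\n")


def write_cluster_membership(clusters: Sequence[ClusterProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tread\n")
        for i, c in enumerate(clusters):
            for rid in sorted(c.member_reads):
                fh.write(f"{i}\t{rid}\n")


def write_histogram(counts: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_low\tbin_high\tcount\n")
        for lo, hi, c in zip(HIST_BINS[:-1], HIST_BINS[1:], counts):
            fh.write(f"{lo:.0f}\t{hi:.0f}\t{int(c)}\n")
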