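"""Shared local-alignment and k-mer utilities.

All identity computations in the package go through :func:`best_local_alignment`
so that "identity" always means matches / alignment columns (gap columns
included) and spans are measured consistently on both sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=4)
def _aligner(match: int = 1, mismatch: int = -2, gap_open: int = -5, gap_extend: int = -2):
    # BLAST-like penalties: random-sequence alignments stay short, so a
    # >=50-column local alignment implies genuine homology rather than a
    # gappy chain of chance matches
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


@dataclass(frozen=True)
class LocalHit:
    """Summary of one local alignment of ``query`` against ``target``."""

    score: float
    matches: int
    columns: int  # aligned columns including gap columns
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str  # orientation of the query relative to the target
    blocks: tuple[tuple[int, int, int], ...]  # (target_start, query_start, length)

    @property
    def identity(self) -> float:
        """Percent identity: matches / alignment columns * 100."""
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


_EMPTY = LocalHit(0.0, 0, 0, 0, 0, 0, 0, "+", ())


def _score_alignment(aln, target: str, query: str, strand: str) -> LocalHit:
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return _EMPTY
    tb = np.asarray(t_blocks)
    qb = np.asarray(q_blocks)
    t_arr = np.frombuffer(target.encode(), dtype=np.uint8)
    q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
    matches = 0
    columns = 0
    blocks = []
    for (ts, te), (qs, qe) in zip(tb, qb):
        matches += int(np.count_nonzero(t_arr[ts:te] == q_arr[qs:qe]))
        columns += int(te - ts)
        blocks.append((int(ts), int(qs), int(te - ts)))
    # internal gaps contribute columns equal to the larger coordinate jump
    for i in range(1, len(tb)):
        columns += int(max(tb[i, 0] - tb[i - 1, 1], qb[i, 0] - qb[i - 1, 1]))
    return LocalHit(
        score=float(aln.score),
        matches=matches,
        columns=columns,
        target_start=int(tb[0, 0]),
        target_end=int(tb[-1, 1]),
        query_start=int(qb[0, 0]),
        query_end=int(qb[-1, 1]),
        strand=strand,
        blocks=tuple(blocks),
    )


def best_local_alignment(target: str, query: str, both_strands: bool = True) -> LocalHit:
    """Best-scoring local alignment of ``query`` (either strand) on ``target``.

    On a forward/reverse score tie the forward orientation is kept; query
    coordinates of a reverse hit refer to the reverse-complemented query.
    """
    al = _aligner()
    if not target or not query:
        return _EMPTY
    try:
        fwd = _score_alignment(al.align(target, query)[0], target, query, "+")
    except IndexError:  # no alignment with positive score
        fwd = _EMPTY
    if not both_strands:
        return fwd
    rc = revcomp(query)
    try:
        rev = _score_alignment(al.align(target, rc)[0], target, rc, "-")
    except IndexError:
        rev = _EMPTY
    return rev if rev.score > fwd.score else fwd


# --------------------------------------------------------------------------
# k-mer prefilters


def kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Strand-symmetric k-mer set: each k-mer stored as min(kmer, revcomp)."""
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        out.add(min(km, revcomp(km)))
    return out
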