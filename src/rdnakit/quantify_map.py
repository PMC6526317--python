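"""Read mapping, genome proportion / copy number estimation and SNP calling.

The central quantities follow the standard low-coverage recipe:

* genome proportion  GP = (mapped reads) / (total reads analysed)
* copy number        CN = GP x genome size (bp/1C) / reference length (bp)

so CN is copies per haploid (1C) genome.  The reference for GP/CN is the
trimmed gene region (a 120-bp 5S gene, ~1800-bp 18S gene), not the whole
repeat unit.  Because a read counts as mapped when at least half of it
aligns, the window of qualifying read start positions has the same width
as the reference itself and the estimator is unbiased for tandem copies
(see docs/methods.md).

SNPs are threshold-called from a substitution-only pileup: a site/allele
is reported iff depth >= ``min_depth``, alternate count >= ``min_alt_count``
and alternate frequency >= ``min_freq``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rdnakit._align import LocalHit, best_local_alignment, kmers, revcomp
from rdnakit.unit_model import RdnaUnitModel, ValidationError

_BASE_TO_COL = {"A": 0, "C": 1, "G": 2, "T": 3}
_COLS = "ACGT"


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read: best local hit of the read on the reference."""

    read_id: str
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    aligned_length: int  # aligned read bases
    read_length: int
    oriented_read: str  # read sequence in reference orientation
    blocks: tuple[tuple[int, int, int], ...]  # (ref_start, read_start, length)


# --------------------------------------------------------------------------
# Mapping


def _reference_parts(reference) -> tuple[str, str]:
    if isinstance(reference, RdnaUnitModel):
        return reference.name, reference.sequence
    if isinstance(reference, tuple):
        return reference
    return "reference", str(reference)


def map_reads(
    reads: Mapping[str, str],
    reference: RdnaUnitModel | tuple[str, str] | str,
    min_identity: float = 90.0,
    min_read_fraction: float = 0.8,
    kmer_size: int = 12,
) -> list[AlignmentRecord]:
    """Map each read to its best location on either strand of the reference.

    A read is mapped iff its best local alignment reaches ``min_identity``
    percent identity over at least ``min_read_fraction`` of the read length.
    Ties between strands keep '+'.  A shared-k-mer prefilter skips reads
    that cannot reach the identity threshold.
    """
    ref_name, ref_seq = _reference_parts(reference)
    if not ref_seq:
        raise ValidationError("empty reference")
    ref_kmers = kmers(ref_seq, kmer_size)
    ref_kmers_rc = kmers(revcomp(ref_seq), kmer_size)
    records: list[AlignmentRecord] = []
    for rid in sorted(reads):
        seq = reads[rid]
        if len(seq) < kmer_size:
            continue
        read_km = kmers(seq, kmer_size)
        try_fwd = not read_km.isdisjoint(ref_kmers)
        try_rev = not read_km.isdisjoint(ref_kmers_rc)
        if not (try_fwd or try_rev):
            continue
        # '+' is evaluated first; on a score tie the earlier (leftmost-strand
        # preference: '+', then smaller ref_start) candidate is kept
        best: LocalHit | None = None
        best_strand = "+"
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            if (strand == "+" and not try_fwd) or (strand == "-" and not try_rev):
                continue
            hit = best_local_alignment(ref_seq, oriented, both_strands=False)
            if (
                best is None
                or hit.score > best.score
                or (hit.score == best.score and hit.target_start < best.target_start)
            ):
                best, best_strand = hit, strand
        if best is None or best.columns == 0:
            continue
        if best.identity < min_identity:
            continue
        if best.query_span < min_read_fraction * len(seq):
            continue
        oriented = seq if best_strand == "+" else revcomp(seq)
        records.append(
            AlignmentRecord(
                read_id=rid,
                ref_name=ref_name,
                ref_start=best.target_start,
                ref_end=best.target_end,
                strand=best_strand,
                identity=best.identity,
                aligned_length=best.query_span,
                read_length=len(seq),
                oriented_read=oriented,
                blocks=best.blocks,
            )
        )
    return records


# --------------------------------------------------------------------------
# GP / CN


def estimate_gp(n_mapped: int, n_total: int) -> float:
    """Genome proportion: mapped reads / total reads analysed."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_mapped <= n_total:
        raise ValidationError("need 0 <= n_mapped <= n_total")
    return n_mapped / n_total


def estimate_copy_number(gp: float, genome_size: float, ref_length: float) -> float:
    """Copy number per 1C: GP x genome size / reference length."""
    if ref_length <= 0:
        raise ValidationError("ref_length must be positive")
    if gp < 0:
        raise ValidationError("gp must be >= 0")
    return gp * genome_size / ref_length


@dataclass(frozen=True)
class CopyNumberEstimate:
    gp: float
    cn: float
    genome_size: float
    ref_length: float
    n_mapped: int = 0
    n_total: int = 0

    @classmethod
    def from_counts(
        cls, n_mapped: int, n_total: int, genome_size: float, ref_length: float
    ) -> "CopyNumberEstimate":
        gp = estimate_gp(n_mapped, n_total)
        return cls(
            gp=gp,
            cn=estimate_copy_number(gp, genome_size, ref_length),
            genome_size=genome_size,
            ref_length=ref_length,
            n_mapped=n_mapped,
            n_total=n_total,
        )

    def to_dict(self) -> dict:
        return {
            "gp": self.gp,
            "gp_percent": 100.0 * self.gp,
            "cn": self.cn,
            "genome_size": self.genome_size,
            "ref_length": self.ref_length,
            "n_mapped": self.n_mapped,
            "n_total": self.n_total,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# --------------------------------------------------------------------------
# Pileup, SNPs, consensus


def build_pileup(
    alignments: Iterable[AlignmentRecord],
    reference: RdnaUnitModel | tuple[str, str] | str,
) -> np.ndarray:
    """Per-position A/C/G/T counts (shape L x 4) from aligned read blocks.

    Reads are strand-normalized (reverse hits contribute their reverse
    complement); insertions and N bases are ignored.
    """
    _, ref_seq = _reference_parts(reference)
    counts = np.zeros((len(ref_seq), 4), dtype=np.int64)
    for rec in alignments:
        read = rec.oriented_read
        for ref_start, read_start, length in rec.blocks:
            seg = np.frombuffer(
                read[read_start : read_start + length].encode(), dtype=np.uint8
            )
            pos = np.arange(ref_start, ref_start + length)
            for b, col in zip(b"ACGT", range(4)):
                sel = seg == b
                if sel.any():
                    np.add.at(counts[:, col], pos[sel], 1)
    return counts


@dataclass(frozen=True)
class SnpParams:
    """Thresholds for high-confidence intragenomic SNPs.

    Defaults: an alternate allele is reported when seen in at least 40
    reads, at a site with at least 200 mapped reads, at a frequency of at
    least 20 %.  For low-coverage samples ``min_depth=100`` is the stated
    alternative.
    """

    min_freq: float = 0.20
    min_depth: int = 200
    min_alt_count: int = 40

    def __post_init__(self) -> None:
        if not 0 < self.min_freq <= 1:
            raise ValidationError("min_freq must be in (0, 1]")
        if self.min_alt_count > self.min_depth:
            raise ValidationError("min_alt_count cannot exceed min_depth")


def call_snps(
    pileup: np.ndarray,
    reference: RdnaUnitModel | tuple[str, str] | str,
    params: SnpParams = SnpParams(),
) -> pd.DataFrame:
    """Threshold SNP calling; one row per qualifying alternate allele.

    Columns: position, ref_base, alt_base, depth, alt_count, frequency,
    subregion (empty when the reference carries no annotation).
    """
    model = reference if isinstance(reference, RdnaUnitModel) else None
    _, ref_seq = _reference_parts(reference)
    depth = pileup.sum(axis=1)
    rows = []
    eligible = np.nonzero(depth >= params.min_depth)[0]
    for pos in eligible:
        ref_base = ref_seq[pos]
        d = int(depth[pos])
        for col, alt in enumerate(_COLS):
            if alt == ref_base:
                continue
            c = int(pileup[pos, col])
            if c >= params.min_alt_count and c / d >= params.min_freq:
                rows.append(
                    (
                        int(pos),
                        ref_base,
                        alt,
                        d,
                        c,
                        c / d,
                        model.label_at(int(pos)) or "" if model else "",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "position",
            "ref_base",
            "alt_base",
            "depth",
            "alt_count",
            "frequency",
            "subregion",
        ],
    )


def snp_density_by_subregion(snps: pd.DataFrame, model: RdnaUnitModel) -> pd.DataFrame:
    """SNPs per kb for each subregion label (instances of a label pooled)."""
    if len(snps) and snps["position"].max() >= len(model):
        raise ValidationError("SNP position outside the unit model")
    rows = []
    labels = sorted({s.label for s in model.subregions})
    for label in labels:
        subs = model.subregions_by_label(label)
        length = sum(s.length for s in subs)
        n = 0
        if len(snps):
            for s in subs:
                n += int(
                    ((snps["position"] >= s.start) & (snps["position"] < s.end)).sum()
                )
        rows.append((label, n, length, 1000.0 * n / length))
    return pd.DataFrame(rows, columns=["label", "n_snps", "length_bp", "snps_per_kb"])


def consensus_from_pileup(
    pileup: np.ndarray, reference: RdnaUnitModel | tuple[str, str] | str
) -> str:
    """Majority-base consensus; zero-depth positions keep the reference base.

    Ties keep the reference base when it is among the tied alleles,
    otherwise the alphabetically first tied base.
    """
    _, ref_seq = _reference_parts(reference)
    out = []
    depth = pileup.sum(axis=1)
    for pos, ref_base in enumerate(ref_seq):
        if depth[pos] == 0:
            out.append(ref_base)
            continue
        row = pileup[pos]
        best = row.max()
        tied = [b for b, c in zip(_COLS, row) if c == best]
        out.append(ref_base if ref_base in tied else tied[0])
    return "".join(out)


# --------------------------------------------------------------------------
# SAM export (minimal mandatory fields, for inspection)


def _cigar(rec: AlignmentRecord) -> str:
    parts = []
    read_len = rec.read_length
    first_read = rec.blocks[0][1]
    if first_read:
        parts.append(f"{first_read}S")
    prev_ref_end = prev_read_end = None
    for ref_start, read_start, length in rec.blocks:
        if prev_ref_end is not None:
            dq = read_start - prev_read_end
            dt = ref_start - prev_ref_end
            if dq:
                parts.append(f"{dq}I")
            if dt:
                parts.append(f"{dt}D")
        parts.append(f"{length}M")
        prev_ref_end = ref_start + length
        prev_read_end = read_start + length
    tail = read_len - prev_read_end
    if tail:
        parts.append(f"{tail}S")
    return "".join(parts)


def write_sam(
    records: Sequence[AlignmentRecord],
    reference: RdnaUnitModel | tuple[str, str] | str,
    path: str | Path,
) -> None:
    ref_name, ref_seq = _reference_parts(reference)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{len(ref_seq)}\n")
        for rec in records:
            flag = 16 if rec.strand == "-" else 0
            fh.write(
                f"{rec.read_id}\t{flag}\t{ref_name}\t{rec.ref_start + 1}\t60\t"
                f"{_cigar(rec)}\t*\t0\t0\t{rec.oriented_read}\t*\n"
            )
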