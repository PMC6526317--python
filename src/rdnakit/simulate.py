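"""Synthetic tandem-array genomes and paired-end read simulation.

The generator emulates the statistical structure of shallow plant
whole-genome sequencing runs (90-100 bp paired reads at ~0.05-0.09x
coverage) over genomes carrying rDNA tandem arrays.  Array architecture is
controlled per array:

* ``per_copy_sub_rate`` -- independent substitutions applied to every copy
  relative to the master unit, emulating poorly homogenized arrays;
* ``pseudogene_events`` -- a 5'-truncated, extra-diverged haplotype of a
  target subregion that is shared by the affected copies, emulating the
  amplification of a single pseudogenized unit within the array.

Mutations are substitution-only (plus the structured pseudogene deletions);
read errors are substitutions at a uniform per-base rate; fragment starts
are uniform over the genome with no GC bias.  All randomness flows from a
single integer seed and outputs are byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rdnakit._align import revcomp
from rdnakit.unit_model import RdnaUnitModel, Subregion, ValidationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T byte values

GENOME_ID = "synthetic_genome"


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. random sequence of length ``n`` at G+C fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``.

    A mutated base is replaced by one of the three other bases uniformly;
    N positions are left untouched.
    """
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    if idx.size:
        shifts = rng.integers(1, 4, size=idx.size)
        for i, s in zip(idx, shifts):
            b = arr[i]
            if b in _BASE_INDEX:
                arr[i] = _BASES[(_BASE_INDEX[b] + s) % 4]
    return arr.tobytes().decode()


# --------------------------------------------------------------------------
# Array construction


@dataclass(frozen=True)
class PseudogeneEvent:
    """Pseudogenization of one subregion across a subset of array copies.

    The event builds a single diverged haplotype (5' deletion of
    ``five_prime_deletion`` bp followed by substitutions at
    ``extra_mut_rate``) and splices it into every affected copy, so the
    pseudogene copies share their mutations -- the signature of a
    pseudogenized unit amplified by concerted evolution rather than of
    independent decay.  ``copy_indices=None`` selects alternate copies
    (1, 3, 5, ...), interspersing pseudogenes between functional genes.
    """

    target_label: str = "5S"
    five_prime_deletion: int = 40
    extra_mut_rate: float = 0.0
    copy_indices: tuple[int, ...] | None = None
    occurrence: int = 0  # which subregion with target_label, in unit order

    def affected(self, n_copies: int) -> set[int]:
        if self.copy_indices is not None:
            return {i for i in self.copy_indices if 0 <= i < n_copies}
        return set(range(1, n_copies, 2))


@dataclass(frozen=True)
class ArraySpec:
    """One tandem array: a unit model, copy count and heterogeneity controls."""

    unit: RdnaUnitModel
    n_copies: int
    per_copy_sub_rate: float = 0.0
    pseudogene_events: tuple[PseudogeneEvent, ...] = ()
    insertion_locus: int | None = None

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValidationError("n_copies must be >= 1")
        if not 0.0 <= self.per_copy_sub_rate <= 1.0:
            raise ValidationError("per_copy_sub_rate must be in [0, 1]")
        for ev in self.pseudogene_events:
            subs = self.unit.subregions_by_label(ev.target_label)
            if ev.occurrence >= len(subs):
                raise ValidationError(
                    f"{self.unit.name}: no {ev.target_label!r} subregion "
                    f"#{ev.occurrence} for pseudogene event"
                )
            sub = subs[ev.occurrence]
            if not 0 <= ev.five_prime_deletion < sub.length:
                raise ValidationError(
                    f"{self.unit.name}: 5' deletion of {ev.five_prime_deletion} bp "
                    f"not shorter than target subregion {ev.target_label} "
                    f"({sub.length} bp)"
                )

    @property
    def length(self) -> int:
        total = 0
        for i in range(self.n_copies):
            d = sum(
                ev.five_prime_deletion
                for ev in self.pseudogene_events
                if i in ev.affected(self.n_copies)
            )
            total += len(self.unit) - d
        return total


@dataclass(frozen=True)
class CopyTruth:
    """Ground truth for one copy of a simulated array."""

    copy_index: int
    start: int  # array-local coordinates, 0-based half-open
    end: int
    identity_to_master: float
    status: str  # "functional" | "pseudogene"
    five_prime_deletion: int
    subregions: tuple[Subregion, ...]  # copy-local coordinates
    events_applied: tuple[str, ...] = ()  # target labels of applied events


def build_array(
    spec: ArraySpec, rng: np.random.Generator
) -> tuple[str, list[CopyTruth]]:
    """Concatenate ``n_copies`` mutated copies of the master unit.

    Returns the array sequence and per-copy truth (coordinates, realized
    identity to the master, functional/pseudogene status).
    """
    unit = spec.unit
    master = unit.sequence
    # one shared haplotype per event
    haplotypes = []
    for ev in spec.pseudogene_events:
        sub = unit.subregions_by_label(ev.target_label)[ev.occurrence]
        hap = mutate(master[sub.start + ev.five_prime_deletion : sub.end], ev.extra_mut_rate, rng)
        haplotypes.append((ev, sub, hap))
    # deletions applied right-to-left so earlier coordinates stay valid
    haplotypes.sort(key=lambda t: -t[1].start)

    pieces: list[str] = []
    truth: list[CopyTruth] = []
    offset = 0
    for i in range(spec.n_copies):
        seq = master
        ref = master  # master with the same deletions, for identity bookkeeping
        subs = list(unit.subregions)
        fpd = 0
        applied: list[str] = []
        for ev, sub, hap in haplotypes:
            if i not in ev.affected(spec.n_copies):
                continue
            d = ev.five_prime_deletion
            seq = seq[: sub.start] + hap + seq[sub.end :]
            ref = ref[: sub.start] + ref[sub.start + d : sub.end] + ref[sub.end :]
            fpd += d
            applied.append(ev.target_label)
            # a pseudogenized gene subregion is relabelled; spacer targets keep
            # their label (a diverged NTS is variant, not a pseudogene)
            new_label = "5S_pseudo" if ev.target_label == "5S" else ev.target_label
            new_subs = []
            for s in subs:
                if (s.start, s.end) == (sub.start, sub.end):
                    new_subs.append(Subregion(new_label, s.start, s.end - d, s.strand))
                elif s.start >= sub.end:
                    new_subs.append(Subregion(s.label, s.start - d, s.end - d, s.strand))
                else:
                    new_subs.append(s)
            subs = new_subs
        seq = mutate(seq, spec.per_copy_sub_rate, rng)
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        b = np.frombuffer(ref.encode(), dtype=np.uint8)
        identity = float(np.count_nonzero(a == b) / a.size)
        status = "pseudogene" if "5S" in applied else "functional"
        truth.append(
            CopyTruth(
                copy_index=i,
                start=offset,
                end=offset + len(seq),
                identity_to_master=identity,
                status=status,
                five_prime_deletion=fpd,
                subregions=tuple(subs),
                events_applied=tuple(applied),
            )
        )
        pieces.append(seq)
        offset += len(seq)
    return "".join(pieces), truth


# --------------------------------------------------------------------------
# Genome assembly


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """A desk-scale genome: i.i.d. background plus planted tandem arrays."""

    genome_size: int
    arrays: tuple[ArraySpec, ...]
    gc_background: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size < 1:
            raise ValidationError("genome_size must be positive")
        if sum(a.length for a in self.arrays) > self.genome_size:
            raise ValidationError("arrays do not fit in the genome")


def plant_arrays(spec: SyntheticGenomeSpec) -> tuple[str, pd.DataFrame]:
    """Build the genome sequence and a truth table of planted intervals.

    Arrays replace background sequence at their insertion loci.  Arrays with
    ``insertion_locus=None`` are spread evenly over the genome.  The truth
    table is BED-like: genome coordinates for every array, copy and copy
    subregion, with copy rows carrying identity-to-master and status.
    """
    rng = np.random.default_rng(spec.seed)
    built = [build_array(a, rng) for a in spec.arrays]

    loci: list[int] = []
    n = len(spec.arrays)
    for k, (aspec, (seq, _)) in enumerate(zip(spec.arrays, built)):
        if aspec.insertion_locus is not None:
            locus = int(aspec.insertion_locus)
        else:
            locus = int(round(spec.genome_size * (k + 1) / (n + 1) - len(seq) / 2))
            locus = max(0, min(locus, spec.genome_size - len(seq)))
        if locus < 0 or locus + len(seq) > spec.genome_size:
            raise ValidationError(
                f"array {k} ({aspec.unit.name}) at locus {locus} exceeds genome bounds"
            )
        loci.append(locus)
    order = sorted(range(n), key=lambda k: loci[k])
    prev_end = 0
    for k in order:
        if loci[k] < prev_end:
            raise ValidationError(f"array {k} overlaps the previous array")
        prev_end = loci[k] + len(built[k][0])

    genome = list(random_dna(spec.genome_size, spec.gc_background, rng))
    rows = []
    for k, ((seq, copies), aspec) in enumerate(zip(built, spec.arrays)):
        locus = loci[k]
        genome[locus : locus + len(seq)] = seq
        rows.append(
            (GENOME_ID, locus, locus + len(seq),
             f"array{k}:{aspec.unit.name}", 1.0, "+", "array",
             aspec.unit.arrangement, "")
        )
        for c in copies:
            rows.append(
                (GENOME_ID, locus + c.start, locus + c.end,
                 f"{aspec.unit.name}.copy{c.copy_index}", round(c.identity_to_master, 4),
                 "+", "copy", aspec.unit.arrangement, c.status)
            )
            for s in c.subregions:
                rows.append(
                    (GENOME_ID, locus + c.start + s.start, locus + c.start + s.end,
                     f"{aspec.unit.name}.copy{c.copy_index}.{s.label}", 1.0,
                     s.strand, "subregion", s.label, c.status)
                )
    truth = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "feature", "label", "status"],
    )
    return "".join(genome), truth


def write_genome_fasta(genome: str, path: str | Path, name: str = GENOME_ID) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i : i + 80] + "\n")


def load_genome_fasta(path: str | Path) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"{path}: expected one genome record, found {len(records)}")
    return str(records[0].seq).upper()


def write_truth_bed(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def load_truth_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class ReadSimSpec:
    """Paired-end sequencing design (defaults follow a 90-bp/170-bp HiSeq run)."""

    coverage: float = 0.05
    read_length: int = 90
    insert_size: int = 170
    error_rate: float = 0.003
    seed: int = 0
    quality: int = 40
    degraded_fraction: float = 0.0  # fraction of reads planted with low-quality bases
    degraded_base_fraction: float = 0.15
    degraded_quality: int = 10

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValidationError("coverage must be > 0")
        if self.insert_size < self.read_length:
            raise ValidationError("insert_size must be >= read_length")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValidationError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    frag_start: int
    frag_strand: str


def simulate_reads(genome: str, spec: ReadSimSpec) -> list[ReadPair]:
    """Sample ``round(coverage * G / (2 * read_length))`` read pairs.

    Fragments of ``insert_size`` start uniformly on either strand; mate 1
    is the fragment's 5' end, mate 2 the reverse complement of its 3' end.
    Substitution errors are applied per base at ``error_rate``; qualities
    are a constant Phred ``quality`` except in planted degraded reads.
    """
    g = len(genome)
    if g == 0:
        raise ValidationError("genome is empty")
    if spec.read_length > g:
        raise ValidationError("read_length exceeds genome length")
    if spec.insert_size > g:
        raise ValidationError("insert_size exceeds genome length")
    rng = np.random.default_rng(spec.seed)
    n_pairs = int(round(spec.coverage * g / (2 * spec.read_length)))
    starts = rng.integers(0, g - spec.insert_size + 1, size=n_pairs)
    flip = rng.random(n_pairs) < 0.5
    rl = spec.read_length
    base_qual = chr(33 + spec.quality) * rl
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        s = int(starts[i])
        frag = genome[s : s + spec.insert_size]
        strand = "F"
        if flip[i]:
            frag = revcomp(frag)
            strand = "R"
        r1, r2 = frag[:rl], revcomp(frag[-rl:])
        if spec.error_rate > 0:
            r1 = mutate(r1, spec.error_rate, rng)
            r2 = mutate(r2, spec.error_rate, rng)
        q1 = q2 = base_qual
        if spec.degraded_fraction > 0:
            for which in (1, 2):
                if rng.random() < spec.degraded_fraction:
                    n_low = int(np.ceil(spec.degraded_base_fraction * rl))
                    pos = rng.choice(rl, size=n_low, replace=False)
                    q = np.full(rl, 33 + spec.quality, dtype=np.uint8)
                    q[pos] = 33 + spec.degraded_quality
                    if which == 1:
                        q1 = q.tobytes().decode()
                    else:
                        q2 = q.tobytes().decode()
        pairs.append(
            ReadPair(f"sim{i:07d}_pos{s}_{strand}", r1, r2, q1, q2, s, strand)
        )
    return pairs


def write_fastq_pairs(pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_positions(pairs: Iterable[ReadPair], insert_size: int, read_length: int):
    """Genome intervals covered by each mate (for truth intersection)."""
    out = {}
    for p in pairs:
        s, e = p.frag_start, p.frag_start + insert_size
        if p.frag_strand == "F":
            out[p.name + "/1"] = (s, s + read_length)
            out[p.name + "/2"] = (e - read_length, e)
        else:
            out[p.name + "/1"] = (e - read_length, e)
            out[p.name + "/2"] = (s, s + read_length)
    return out
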