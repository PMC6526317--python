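"""Unit-level structural analysis of rDNA.

Four analyses that together resolve how an rDNA unit is built and how the
35S and 5S gene families are arranged:

* tandem-subrepeat detection in spacer regions (ITS1/NTS) by exhaustive
  period scoring of the self-match profile;
* classification of annotated 5S copies into functional genes vs
  pseudogenes by local alignment to a canonical 120-bp gene, with
  structural truncation outranking sequence identity;
* in-silico restriction digestion with IUPAC recognition sites, including
  a tandem-circularized topology that models an idealized long array (the
  computational analogue of a Southern monomer ladder), plus
  alignment-based probe assignment to fragments;
* S-type vs L-type arrangement inference combining read co-clustering,
  cross-mate mapping and digest co-hybridization evidence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from rdnakit._align import best_local_alignment, revcomp
from rdnakit.unit_model import (
    CanonicalGeneSet,
    RdnaUnitModel,
    ValidationError,
    gc_content,
)

logger = logging.getLogger(__name__)

#: standard recognition sequences for the enzymes used in rDNA Southern work
DEFAULT_ENZYMES: dict[str, str] = {
    "BamHI": "GGATCC",
    "EcoRI": "GAATTC",
    "NcoI": "CCATGG",
    "StuI": "AGGCCT",
    "BstNI": "CCWGG",
}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


# --------------------------------------------------------------------------
# Tandem subrepeats


@dataclass(frozen=True)
class SubrepeatReport:
    """A tandem-periodic span: period, fractional copy number and motif."""

    period: int
    copy_number: float
    span: tuple[int, int]
    consensus_motif: str
    gc_content: float
    match_fraction: float

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0]


def detect_subrepeats(
    seq: str,
    min_period: int = 10,
    max_period: int | None = None,
    min_copies: float = 1.8,
    min_match_fraction: float = 0.85,
    window_threshold: float = 0.75,
) -> list[SubrepeatReport]:
    """Find maximal tandem-periodic spans by exhaustive period scoring.

    For every candidate period ``p`` the boolean self-match profile
    ``m[i] = (seq[i] == seq[i+p])`` is smoothed over a window of ``p`` and
    thresholded; maximal runs that keep an exact match fraction of at least
    ``min_match_fraction`` and amount to at least ``min_copies`` copies are
    reported.  Overlapping reports at harmonic periods are collapsed to the
    smallest period.  Copy number is span/period, to one decimal.
    """
    n = len(seq)
    if n < 2 * min_period:
        raise ValidationError("sequence shorter than twice the minimum period")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if max_period is None:
        max_period = n // 2
    candidates: list[SubrepeatReport] = []
    for p in range(min_period, max_period + 1):
        m = (arr[:-p] == arr[p:]).astype(np.float64)
        w = min(p, m.size)
        smoothed = np.convolve(m, np.ones(w) / w, mode="valid")
        good = smoothed >= window_threshold
        if not good.any():
            continue
        # merge window starts into runs over the match profile
        idx = np.nonzero(good)[0]
        run_start = idx[0]
        prev = idx[0]
        runs = []
        for i in idx[1:]:
            if i > prev + 1:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for s0, s1 in runs:
            s, e = s0, min(s1 + w, m.size)  # interval on the match profile
            # smoothing drags the interval into flanking noise; refine the
            # boundaries on the raw profile before scoring
            k = min(8, p)
            while e - s >= k and m[s : s + k].mean() < 0.8:
                s += 1
            while e - s >= k and m[e - k : e].mean() < 0.8:
                e -= 1
            while s < e and not m[s]:
                s += 1
            while e > s and not m[e - 1]:
                e -= 1
            if e <= s:
                continue
            frac = float(m[s:e].mean())
            span = (s, e + p)
            copies = round((span[1] - span[0]) / p, 1)
            if copies < min_copies or frac < min_match_fraction:
                continue
            # floor on the matched run keeps single lucky windows in random
            # sequence from qualifying at small periods
            if (e - s) < max(16, min_period):
                continue
            motif = _consensus_motif(seq[span[0] : span[1]], p)
            candidates.append(
                SubrepeatReport(
                    period=p,
                    copy_number=copies,
                    span=span,
                    consensus_motif=motif,
                    gc_content=gc_content(seq[span[0] : span[1]]),
                    match_fraction=frac,
                )
            )
    return _dedupe_harmonics(candidates)


def _consensus_motif(span_seq: str, period: int) -> str:
    chunks = [span_seq[i : i + period] for i in range(0, len(span_seq), period)]
    motif = []
    for col in range(period):
        bases = [c[col] for c in chunks if col < len(c)]
        counts = {b: bases.count(b) for b in set(bases)}
        motif.append(max(sorted(counts), key=counts.get))
    return "".join(motif)


def _dedupe_harmonics(candidates: list[SubrepeatReport]) -> list[SubrepeatReport]:
    """Keep the smallest period among reports whose spans overlap substantially."""
    accepted: list[SubrepeatReport] = []
    for cand in sorted(candidates, key=lambda r: (r.period, -r.span_length)):
        shadowed = False
        for acc in accepted:
            lo = max(cand.span[0], acc.span[0])
            hi = min(cand.span[1], acc.span[1])
            if hi - lo > 0.5 * min(cand.span_length, acc.span_length):
                shadowed = True
                break
        if not shadowed:
            accepted.append(cand)
    accepted.sort(key=lambda r: r.span)
    return accepted


# --------------------------------------------------------------------------
# 5S gene / pseudogene classification


@dataclass(frozen=True)
class FiveSCopyCall:
    """Classification of one annotated 5S copy against the canonical gene."""

    start: int
    end: int
    annotated_label: str
    cls: str  # "functional" | "pseudogene"
    length: int
    identity_to_canonical: float
    five_prime_deletion: int
    has_bamhi_site: bool


def classify_5s_copies(
    unit: RdnaUnitModel,
    canonical: CanonicalGeneSet,
    min_identity: float = 90.0,
    min_length: int = 120,
    max_five_prime_trim: int = 10,
) -> list[FiveSCopyCall]:
    """Score every annotated 5S/5S_pseudo subregion against the canonical gene.

    A copy is functional iff it is full-length (``min_length``), reaches
    ``min_identity`` percent identity and has no 5' truncation.  Structural
    truncation outranks identity: a full-length 95 % copy is functional, an
    80-bp 99 % copy is a pseudogene.  ``five_prime_deletion`` is the length
    of the canonical prefix left unaligned by the best local alignment;
    values below ``max_five_prime_trim`` are treated as alignment trimming
    of terminal mismatches, not structural truncation.
    """
    if "5S" not in canonical:
        raise ValidationError("canonical gene set lacks a 5S entry")
    gene = canonical["5S"]
    calls = []
    for sub in unit.subregions:
        if sub.label not in ("5S", "5S_pseudo"):
            continue
        copy_seq = unit.subregion_sequence(sub)
        hit = best_local_alignment(copy_seq, gene, both_strands=True)
        identity = hit.identity
        five_prime_deletion = hit.query_start if hit.columns else len(gene)
        functional = (
            sub.length >= min_length
            and identity >= min_identity
            and five_prime_deletion < max_five_prime_trim
        )
        calls.append(
            FiveSCopyCall(
                start=sub.start,
                end=sub.end,
                annotated_label=sub.label,
                cls="functional" if functional else "pseudogene",
                length=sub.length,
                identity_to_canonical=identity,
                five_prime_deletion=five_prime_deletion,
                has_bamhi_site="GGATCC" in copy_seq,
            )
        )
    return calls


# --------------------------------------------------------------------------
# In-silico digestion


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment; ``end > array length`` encodes a wrap-around
    fragment of a tandem-circularized array."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DigestResult:
    enzyme: str
    recognition: str
    topology: str  # "linear" | "tandem-circularized"
    array_length: int
    fragments: list[Fragment]
    probe_hits: dict[int, set[str]] = field(default_factory=dict)

    @property
    def fragment_lengths(self) -> list[int]:
        return sorted(f.length for f in self.fragments)


def _site_regex(recognition: str) -> re.Pattern:
    try:
        pat = "".join(_IUPAC[c] for c in recognition.upper())
    except KeyError as exc:
        raise ValidationError(f"invalid IUPAC code in recognition sequence: {exc}")
    return re.compile(f"(?=({pat}))")


def find_cut_positions(
    array: str, recognition: str, cut_offset: int = 0
) -> list[int]:
    """Cut positions for every site match on either strand (overlaps included).

    The cut is placed ``cut_offset`` bases after the site start (default at
    the site start -- fragment sizes shift by at most the site length, which
    is irrelevant at gel resolution).
    """
    if len(recognition) < 4:
        raise ValidationError("recognition sequence must be at least 4 bp")
    fwd = _site_regex(recognition)
    cuts = {m.start() + cut_offset for m in fwd.finditer(array)}
    rc = revcomp(recognition)
    if rc != recognition.upper():
        rev = _site_regex(rc)
        cuts.update(m.start() + cut_offset for m in rev.finditer(array))
    return sorted(c for c in cuts if 0 <= c <= len(array))


def digest_array(
    array: str,
    enzyme: tuple[str, str],
    topology: str = "linear",
    cut_offset: int = 0,
) -> DigestResult:
    """Complete digest of ``array``; fragments lie between consecutive cuts.

    ``tandem-circularized`` joins the two terminal fragments, modelling an
    effectively infinite tandem array: with one site per repeat unit this
    reproduces the monomer ladder of a genomic Southern digest.
    """
    name, recognition = enzyme
    if topology not in ("linear", "tandem-circularized"):
        raise ValidationError("topology must be 'linear' or 'tandem-circularized'")
    n = len(array)
    cuts = find_cut_positions(array, recognition, cut_offset)
    fragments: list[Fragment] = []
    if topology == "linear":
        bounds = [0] + [c for c in cuts if 0 < c < n] + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b > a:
                fragments.append(Fragment(a, b))
    else:
        inner = [c for c in cuts if 0 <= c < n]
        if not inner:
            fragments.append(Fragment(0, n))
        else:
            for a, b in zip(inner[:-1], inner[1:]):
                fragments.append(Fragment(a, b))
            # wrap-around fragment joining the two ends
            fragments.append(Fragment(inner[-1], n + inner[0]))
    return DigestResult(
        enzyme=name,
        recognition=recognition,
        topology=topology,
        array_length=n,
        fragments=fragments,
    )


def fragment_sequence(frag: Fragment, array: str) -> str:
    n = len(array)
    if frag.end <= n:
        return array[frag.start : frag.end]
    return array[frag.start :] + array[: frag.end - n]


def assign_probes(
    digest: DigestResult,
    array: str,
    probes: Mapping[str, str],
    min_probe_identity: float = 90.0,
    min_probe_span: int = 50,
) -> dict[int, set[str]]:
    """Hybridize probes to fragments by local alignment.

    A probe hits a fragment iff some local alignment of at least
    ``min_probe_span`` columns at ``min_probe_identity`` percent identity
    lies within the fragment.  Hits are stored on ``digest.probe_hits``
    (fragment index -> probe names) and returned.
    """
    for name, probe in probes.items():
        if len(probe) > len(array):
            raise ValidationError(f"probe {name!r} is longer than the array")
    hits: dict[int, set[str]] = {}
    for i, frag in enumerate(digest.fragments):
        if frag.length < min_probe_span:
            continue
        frag_seq = fragment_sequence(frag, array)
        for name, probe in probes.items():
            hit = best_local_alignment(frag_seq, probe, both_strands=True)
            if hit.columns >= min_probe_span and hit.identity >= min_probe_identity:
                hits.setdefault(i, set()).add(name)
    digest.probe_hits = hits
    return hits


def cohybridizing_fragments(digest: DigestResult, probe_a: str, probe_b: str) -> list[int]:
    """Fragment indices hit by both probes (the Southern co-hybridization signal)."""
    return sorted(
        i for i, names in digest.probe_hits.items() if {probe_a, probe_b} <= names
    )


def write_digest_tsv(digest: DigestResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_index\tstart\tend\tlength\tprobes\n")
        for i, frag in enumerate(digest.fragments):
            probes = ",".join(sorted(digest.probe_hits.get(i, ())))
            fh.write(f"{i}\t{frag.start}\t{frag.end}\t{frag.length}\t{probes}\n")


# --------------------------------------------------------------------------
# Arrangement inference


@dataclass(frozen=True)
class LinkageReport:
    """Evidence summary and the S/L arrangement call.

    Decision rule: L iff 35S and 5S reads co-cluster, OR the cross-mate
    fraction reaches its threshold, OR a digest fragment co-hybridizes with
    both probes; S iff all available evidence is negative and both gene
    families were detected; ambiguous otherwise.
    """

    co_cluster: bool
    cross_mate_fraction: float
    digest_cohybridization: bool | None
    arrangement_call: str  # "S" | "L" | "ambiguous"
    families_detected: frozenset[str]
    n_informative_pairs: int
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "co_cluster": self.co_cluster,
            "cross_mate_fraction": self.cross_mate_fraction,
            "digest_cohybridization": self.digest_cohybridization,
            "arrangement_call": self.arrangement_call,
            "families_detected": sorted(self.families_detected),
            "n_informative_pairs": self.n_informative_pairs,
            "warnings": list(self.warnings),
        }


def cross_mate_fraction(
    mate_labels: Iterable[tuple[frozenset[str] | set[str], frozenset[str] | set[str]]],
) -> tuple[float, int]:
    """Fraction of informative pairs with one mate in 26S and the other in 5S.

    A pair is informative when both mates carry at least one gene-family
    label (26S or 5S).  Returns (fraction, informative pair count).
    """
    informative = 0
    cross = 0
    for l1, l2 in mate_labels:
        a = {l for l in l1 if l in ("26S", "5S")}
        b = {l for l in l2 if l in ("26S", "5S")}
        if not a or not b:
            continue
        informative += 1
        if ("26S" in a and "5S" in b) or ("5S" in a and "26S" in b):
            cross += 1
    return (cross / informative if informative else 0.0), informative


def infer_arrangement(
    cluster_families: Sequence[set[str] | frozenset[str]],
    mate_labels: Iterable[tuple[set[str], set[str]]] = (),
    digest_cohyb: bool | None = None,
    cross_mate_threshold: float = 0.05,
    min_family_reads: int = 3,
) -> LinkageReport:
    """Combine the three evidence channels into an S/L arrangement call.

    ``cluster_families``: per read cluster, the gene families ("35S", "5S")
    its reads were assigned to.  ``mate_labels``: per read pair, the
    subregion labels each mate mapped to.  ``digest_cohyb``: whether any
    in-silico digest fragment was hit by both the 26S and the 5S probe
    (None when digestion evidence is unavailable).

    A gene family counts as detected when some cluster was assigned it or
    when at least ``min_family_reads`` mates mapped to one of its
    subregions -- sparse samples may yield too few overlapping reads to
    cluster yet still map unambiguously.
    """
    from rdnakit.unit_model import LABELS_35S

    warnings: list[str] = []
    families: set[str] = set()
    for fams in cluster_families:
        families |= set(fams)
    mate_labels = list(mate_labels)
    fam_counts = {"35S": 0, "5S": 0}
    for l1, l2 in mate_labels:
        for labels in (l1, l2):
            if set(labels) & LABELS_35S:
                fam_counts["35S"] += 1
            if set(labels) & {"5S", "5S_pseudo"}:
                fam_counts["5S"] += 1
    families |= {fam for fam, n in fam_counts.items() if n >= min_family_reads}
    co_cluster = any({"35S", "5S"} <= set(fams) for fams in cluster_families)
    cmf, informative = cross_mate_fraction(mate_labels)
    evidence_l = [co_cluster, cmf >= cross_mate_threshold]
    if digest_cohyb is not None:
        evidence_l.append(digest_cohyb)
    if not families:
        warnings.append("no rDNA reads detected; arrangement cannot be called")
        call = "ambiguous"
    elif any(evidence_l):
        call = "L"
    elif {"35S", "5S"} <= families:
        call = "S"
    else:
        missing = sorted({"35S", "5S"} - families)
        warnings.append(f"gene families not detected: {missing}; call is ambiguous")
        call = "ambiguous"
    for w in warnings:
        logger.warning(w)
    return LinkageReport(
        co_cluster=co_cluster,
        cross_mate_fraction=cmf,
        digest_cohybridization=digest_cohyb,
        arrangement_call=call,
        families_detected=frozenset(families),
        n_informative_pairs=informative,
        warnings=tuple(warnings),
    )
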