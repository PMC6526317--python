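"""Desk-scale genome archetypes used as test and demonstration fixtures.

Three bundles encode the organizational patterns seen across plant rDNA:

* ``s_heterogeneous`` -- S-type genome with separate 35S and 5S arrays;
  the 5S unit carries a diverged, BamHI-free pseudogene inside its NTS and
  the array is poorly homogenized (high per-copy substitution rate).
* ``l_homogeneous`` -- L-type genome with a single linked 35S-5S unit:
  ITS1 carries a GC-rich 71-bp tandem subrepeat, the 5S gene is followed by
  two 5'-truncated pseudogene copies separated by 9-bp spacers, and the
  array is highly homogenized.
* ``s_sparse`` -- S-type genome with few rDNA copies sequenced at lower
  coverage.

Units are length-scaled (hundreds of bp per gene instead of kilobases) so
pipelines run in seconds; the 5S gene is kept at its natural 120 bp.  All
sequences derive deterministically from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rdnakit.simulate import (
    ArraySpec,
    ReadSimSpec,
    SyntheticGenomeSpec,
    mutate,
    random_dna,
)
from rdnakit.unit_model import CanonicalGeneSet, RdnaUnitModel, Subregion

#: scaled gene lengths (bp); the 5S gene keeps its natural length
GENE_LENGTHS = {"18S": 300, "5.8S": 60, "26S": 500, "5S": 120}

_BAMHI = "GGATCC"
_STUI = "AGGCCT"


def _scrub(seq: str, sites: tuple[str, ...] = (_BAMHI, _STUI)) -> str:
    """Destroy accidental occurrences of restriction sites in random sequence."""
    changed = True
    while changed:
        changed = False
        for site in sites:
            i = seq.find(site)
            if i >= 0:
                mid = i + len(site) // 2
                repl = "A" if seq[mid] != "A" else "C"
                seq = seq[:mid] + repl + seq[mid + 1 :]
                changed = True
    return seq


def _random_segment(n: int, rng: np.random.Generator, gc: float = 0.45) -> str:
    return _scrub(random_dna(n, gc, rng))


def make_canonical_genes(rng: np.random.Generator) -> CanonicalGeneSet:
    """Synthetic canonical gene set (stand-ins for real rRNA genes).

    The 120-bp 5S gene carries a BamHI site in its first half, mirroring
    the conserved site of functional plant 5S genes; other genes are
    scrubbed of the bundled enzymes' sites.
    """
    genes = {}
    for label in ("18S", "5.8S", "26S"):
        genes[label] = _random_segment(GENE_LENGTHS[label], rng, gc=0.52)
    five_s = _random_segment(GENE_LENGTHS["5S"], rng, gc=0.55)
    five_s = five_s[:50] + _BAMHI + five_s[56:]
    genes["5S"] = five_s
    return CanonicalGeneSet(genes)


def default_probes(canonical: CanonicalGeneSet) -> dict[str, str]:
    """Hybridization probes: the 5S gene and a 120-bp window of the 26S gene."""
    return {"26S": canonical["26S"][:120], "5S": canonical["5S"]}


def make_subrepeat_motif(rng: np.random.Generator, period: int = 71, gc: float = 0.73) -> str:
    return _scrub(random_dna(period, gc, rng))


def _tandem(motif: str, copies: float) -> str:
    full = int(copies)
    frac = int(round((copies - full) * len(motif)))
    return motif * full + motif[:frac]


def make_35s_unit(
    name: str,
    canonical: CanonicalGeneSet,
    rng: np.random.Generator,
    its1_length: int = 250,
    its1_subrepeat: tuple[str, float] | None = None,
    its2_length: int = 100,
    igs_length: int = 290,
) -> RdnaUnitModel:
    """A scaled 18S-ITS1-5.8S-ITS2-26S(-IGS) unit without a 5S insertion."""
    its1 = _random_segment(its1_length, rng, gc=0.5)
    if its1_subrepeat is not None:
        motif, copies = its1_subrepeat
        block = _tandem(motif, copies)
        # subrepeat block close to the ITS1 3' terminus
        pad = 20
        its1 = its1[: its1_length - len(block) - pad] + block + its1[-pad:]
    parts = [
        ("18S", canonical["18S"]),
        ("ITS1", its1),
        ("5.8S", canonical["5.8S"]),
        ("ITS2", _random_segment(its2_length, rng, gc=0.5)),
        ("26S", canonical["26S"]),
        ("IGS", _random_segment(igs_length, rng, gc=0.42)),
    ]
    return _assemble(name, parts, "S_35S")


def make_5s_unit_with_pseudogene(
    name: str,
    canonical: CanonicalGeneSet,
    rng: np.random.Generator,
    nts1_length: int = 209,
    pseudo_deletion: int = 16,
    pseudo_divergence: float = 0.17,
    nts2_length: int = 194,
) -> RdnaUnitModel:
    """A 5S unit with an NTS-embedded diverged pseudogene (627 bp by default).

    The pseudogene is a 5'-truncated, heavily substituted 5S copy with its
    BamHI site destroyed, so only the functional gene cuts -- the array
    digests to a monomer ladder with one rung per unit.
    """
    gene = canonical["5S"]
    pseudo = mutate(gene[pseudo_deletion:], pseudo_divergence, rng)
    pseudo = _scrub(pseudo, (_BAMHI,))
    parts = [
        ("5S", gene),
        ("NTS", _random_segment(nts1_length, rng, gc=0.4)),
        ("5S_pseudo", pseudo),
        ("NTS", _random_segment(nts2_length, rng, gc=0.4)),
    ]
    return _assemble(name, parts, "S_5S")


def make_simple_5s_unit(
    name: str,
    canonical: CanonicalGeneSet,
    rng: np.random.Generator,
    nts_length: int = 230,
) -> RdnaUnitModel:
    """A plain 5S + NTS unit (functional gene only)."""
    parts = [
        ("5S", canonical["5S"]),
        ("NTS", _random_segment(nts_length, rng, gc=0.4)),
    ]
    return _assemble(name, parts, "S_5S")


def make_l_unit(
    name: str,
    canonical: CanonicalGeneSet,
    rng: np.random.Generator,
    its1_length: int = 400,
    subrepeat_copies: float = 2.8,
    pseudo_deletion: int = 40,
    pseudo_divergence: float = 0.05,
) -> RdnaUnitModel:
    """A linked 35S-5S unit: ...26S-[StuI]-5S-NTS-pseudo-NTS-pseudo-IGS.

    StuI sites flank the 5S block (one in the short 26S->5S spacer, one in
    the distal IGS), so StuI separates the two gene families onto different
    fragments; a single-cut enzyme (BamHI, in the functional 5S gene) leaves
    them on a common fragment.  The two pseudogene copies carry a 5'
    deletion and are scrubbed of BamHI sites; the NTS spacers are 9 bp.
    """
    motif = make_subrepeat_motif(rng)
    gene = canonical["5S"]
    pseudo1 = _scrub(mutate(gene[pseudo_deletion:], pseudo_divergence, rng), (_BAMHI,))
    pseudo2 = _scrub(mutate(gene[pseudo_deletion:], pseudo_divergence, rng), (_BAMHI,))
    linker = "AG" + _STUI + "TA"  # 10-bp 26S->5S spacer with a StuI site
    igs2 = _random_segment(200, rng, gc=0.42)
    igs2 = igs2[:100] + _STUI + igs2[106:]  # second StuI site, distal IGS
    parts = [
        ("18S", canonical["18S"]),
        ("ITS1", _build_its1(its1_length, motif, subrepeat_copies, rng)),
        ("5.8S", canonical["5.8S"]),
        ("ITS2", _random_segment(100, rng, gc=0.5)),
        ("26S", canonical["26S"]),
        ("IGS", linker),
        ("5S", gene),
        ("NTS", "ATTTTTATC"),
        ("5S_pseudo", pseudo1),
        ("NTS", "CATTTTATC"),
        ("5S_pseudo", pseudo2),
        ("IGS", igs2),
    ]
    return _assemble(name, parts, "L_linked")


def _build_its1(length: int, motif: str, copies: float, rng: np.random.Generator) -> str:
    block = _tandem(motif, copies)
    pad = 20
    head = _random_segment(length - len(block) - pad, rng, gc=0.5)
    return head + block + _random_segment(pad, rng, gc=0.5)


def _assemble(name: str, parts, arrangement: str) -> RdnaUnitModel:
    subs = []
    seq = []
    offset = 0
    for label, s in parts:
        subs.append(Subregion(label, offset, offset + len(s)))
        seq.append(s)
        offset += len(s)
    return RdnaUnitModel(
        name=name, sequence="".join(seq), subregions=tuple(subs), arrangement=arrangement
    )


# --------------------------------------------------------------------------
# Bundles


@dataclass(frozen=True)
class ArchetypeBundle:
    name: str
    genome_spec: SyntheticGenomeSpec
    read_spec: ReadSimSpec
    units: tuple[RdnaUnitModel, ...]
    canonical: CanonicalGeneSet
    probes: dict[str, str]
    arrangement_truth: str  # "S" | "L"


ARCHETYPE_NAMES = ("s_heterogeneous", "l_homogeneous", "s_sparse")


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def make_archetype(name: str, seed: int) -> ArchetypeBundle:
    """Build one archetype bundle deterministically from ``seed``."""
    rng = np.random.default_rng([seed, ARCHETYPE_NAMES.index(name)])
    canonical = make_canonical_genes(rng)
    probes = default_probes(canonical)
    genome_size = 150_000
    if name == "s_heterogeneous":
        unit_35s = make_35s_unit("gm35S", canonical, rng)
        unit_5s = make_5s_unit_with_pseudogene("gm5S", canonical, rng)
        arrays = (
            ArraySpec(unit_35s, n_copies=12, per_copy_sub_rate=0.002, insertion_locus=20_000),
            ArraySpec(unit_5s, n_copies=30, per_copy_sub_rate=0.02, insertion_locus=120_000),
        )
        coverage, truth = 1.0, "S"
    elif name == "l_homogeneous":
        unit_l = make_l_unit("eaL", canonical, rng)
        arrays = (
            ArraySpec(unit_l, n_copies=20, per_copy_sub_rate=0.002, insertion_locus=50_000),
        )
        coverage, truth = 1.0, "L"
    elif name == "s_sparse":
        unit_35s = make_35s_unit("wm35S", canonical, rng, its1_length=150, igs_length=200)
        unit_5s = make_simple_5s_unit("wm5S", canonical, rng)
        # few copies of each family relative to the other archetypes, but
        # enough read support that both families remain detectable
        arrays = (
            ArraySpec(unit_35s, n_copies=6, per_copy_sub_rate=0.002, insertion_locus=20_000),
            ArraySpec(unit_5s, n_copies=20, per_copy_sub_rate=0.002, insertion_locus=120_000),
        )
        coverage, truth = 0.5, "S"
    else:
        raise ValueError(f"unknown archetype {name!r}; choose from {ARCHETYPE_NAMES}")
    genome_spec = SyntheticGenomeSpec(
        genome_size=genome_size,
        arrays=arrays,
        gc_background=0.40,
        seed=_child_seed(seed, 100 + ARCHETYPE_NAMES.index(name)),
    )
    read_spec = ReadSimSpec(
        coverage=coverage,
        read_length=90,
        insert_size=300,
        error_rate=0.003,
        seed=_child_seed(seed, 200 + ARCHETYPE_NAMES.index(name)),
    )
    return ArchetypeBundle(
        name=name,
        genome_spec=genome_spec,
        read_spec=read_spec,
        units=tuple(a.unit for a in arrays),
        canonical=canonical,
        probes=probes,
        arrangement_truth=truth,
    )
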