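"""Data model and I/O for annotated rDNA repeat units.

An :class:`RdnaUnitModel` is one repeat unit of a ribosomal DNA tandem
array -- for 35S rDNA typically 18S-ITS1-5.8S-ITS2-26S(-IGS), for 5S rDNA
a 120-bp gene plus its non-transcribed spacer (NTS), and for linked
(L-type) organizations a single unit carrying both gene families.  Units
are stored linearly; tandem context is reconstructed by the simulator and
the digestion code.

Coordinates are 0-based half-open throughout.  The on-disk annotation
dialect is a BED-like TSV (name, start, end, label, strand).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUBREGION_LABELS = frozenset(
    {"18S", "ITS1", "5.8S", "ITS2", "26S", "IGS", "5S", "NTS", "5S_pseudo"}
)
#: subregions that belong to the 35S (18S-5.8S-26S) transcription unit
LABELS_35S = frozenset({"18S", "ITS1", "5.8S", "ITS2", "26S"})
ARRANGEMENTS = ("S_35S", "S_5S", "L_linked")
DNA_ALPHABET = frozenset("ACGTN")

#: default reference gene lengths used for copy-number estimation
DEFAULT_REF_LENGTH_5S = 120
DEFAULT_REF_LENGTH_18S = 1800


class ValidationError(ValueError):
    """Raised when a model, annotation row or sequence violates an invariant."""


def clean_sequence(seq: str, context: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it only contains A/C/G/T/N."""
    s = str(seq).upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValidationError(
            f"{context}: non-ACGTN characters {sorted(bad)!r} are not accepted"
        )
    return s


@dataclass(frozen=True)
class Subregion:
    """A labelled interval of a repeat unit (0-based, half-open)."""

    label: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.label not in SUBREGION_LABELS:
            raise ValidationError(
                f"subregion label {self.label!r} not in {sorted(SUBREGION_LABELS)}"
            )
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise ValidationError(f"subregion {self.label}: coordinates must be integers")
        if self.end <= self.start or self.start < 0:
            raise ValidationError(
                f"subregion {self.label}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"subregion {self.label}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RdnaUnitModel:
    """An annotated rDNA repeat unit used as reference and simulation template.

    ``arrangement`` distinguishes the unit's role: ``S_35S`` (a 35S unit of
    an S-type genome, no 5S inside), ``S_5S`` (a 5S+NTS unit), and
    ``L_linked`` (a single unit carrying both 26S and 5S sequences).
    """

    name: str
    sequence: str
    subregions: tuple[Subregion, ...]
    arrangement: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_sequence(self.sequence, self.name))
        subs = tuple(sorted(self.subregions, key=lambda s: (s.start, s.end)))
        object.__setattr__(self, "subregions", subs)
        if self.arrangement not in ARRANGEMENTS:
            raise ValidationError(
                f"{self.name}: arrangement {self.arrangement!r} not in {ARRANGEMENTS}"
            )
        n = len(self.sequence)
        if n == 0:
            raise ValidationError(f"{self.name}: empty sequence")
        prev: Subregion | None = None
        for sub in subs:
            if sub.end > n:
                raise ValidationError(
                    f"{self.name}: subregion {sub.label} [{sub.start}, {sub.end}) "
                    f"exceeds unit length {n}"
                )
            if prev is not None and sub.start < prev.end:
                raise ValidationError(
                    f"{self.name}: subregions {prev.label} [{prev.start}, {prev.end}) and "
                    f"{sub.label} [{sub.start}, {sub.end}) overlap"
                )
            prev = sub
        labels = {s.label for s in subs}
        if self.arrangement == "L_linked" and not {"26S", "5S"} <= labels:
            raise ValidationError(
                f"{self.name}: an L_linked unit must contain both 26S and 5S subregions"
            )
        if self.arrangement == "S_35S" and "5S" in labels:
            raise ValidationError(
                f"{self.name}: an S_35S unit must not contain a 5S subregion"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(s.label for s in self.subregions)

    def subregions_by_label(self, label: str) -> tuple[Subregion, ...]:
        return tuple(s for s in self.subregions if s.label == label)

    def subregion(self, label: str) -> Subregion:
        """First subregion with ``label``; KeyError if absent."""
        subs = self.subregions_by_label(label)
        if not subs:
            raise KeyError(f"{self.name}: no subregion labelled {label!r}")
        return subs[0]

    def subregion_sequence(self, sub: Subregion) -> str:
        seq = self.sequence[sub.start : sub.end]
        if sub.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def label_at(self, position: int) -> str | None:
        """Label of the subregion covering ``position`` (None in gaps)."""
        for sub in self.subregions:
            if sub.start <= position < sub.end:
                return sub.label
        return None

    # ---- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sequence": self.sequence,
            "arrangement": self.arrangement,
            "subregions": [
                {"label": s.label, "start": s.start, "end": s.end, "strand": s.strand}
                for s in self.subregions
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RdnaUnitModel":
        return cls(
            name=d["name"],
            sequence=d["sequence"],
            arrangement=d["arrangement"],
            subregions=tuple(Subregion(**s) for s in d["subregions"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RdnaUnitModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CanonicalGeneSet:
    """Reference coding sequences (e.g. a functional 120-bp 5S rRNA gene)."""

    genes: Mapping[str, str]

    def __post_init__(self) -> None:
        cleaned = {}
        for label, seq in dict(self.genes).items():
            cleaned[label] = clean_sequence(seq, f"canonical gene {label}")
            if not cleaned[label]:
                raise ValidationError(f"canonical gene {label}: empty sequence")
        if "5S" in cleaned and len(cleaned["5S"]) != DEFAULT_REF_LENGTH_5S:
            raise ValidationError(
                f"canonical 5S gene must be {DEFAULT_REF_LENGTH_5S} bp, "
                f"got {len(cleaned['5S'])}"
            )
        object.__setattr__(self, "genes", cleaned)

    def __getitem__(self, label: str) -> str:
        return self.genes[label]

    def __contains__(self, label: str) -> bool:
        return label in self.genes

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=label, description="")
            for label, seq in sorted(self.genes.items())
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CanonicalGeneSet":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


# --------------------------------------------------------------------------
# File I/O


def load_unit_model(
    unit_fasta: str | Path,
    annotation_table: str | Path,
    arrangement: str | None = None,
) -> RdnaUnitModel:
    """Load a unit from a single-record FASTA and a BED-like annotation TSV.

    The TSV columns are (name, start, end, label, strand); ``arrangement``
    may be stated in a ``#arrangement=...`` header line or passed explicitly.
    """
    records = list(SeqIO.parse(str(unit_fasta), "fasta"))
    if len(records) != 1:
        raise ValidationError(
            f"{unit_fasta}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    subregions = []
    for i, line in enumerate(Path(annotation_table).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#arrangement=") and arrangement is None:
                arrangement = line.split("=", 1)[1].strip()
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValidationError(f"{annotation_table}:{i}: expected >=4 columns: {line!r}")
        name, start, end, label = fields[:4]
        strand = fields[4] if len(fields) > 4 else "+"
        if name != rec.id:
            raise ValidationError(
                f"{annotation_table}:{i}: row names {name!r}, FASTA record is {rec.id!r}"
            )
        try:
            subregions.append(Subregion(label, int(start), int(end), strand))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{annotation_table}:{i}: {exc}") from exc
    if arrangement is None:
        raise ValidationError(
            f"{annotation_table}: no '#arrangement=' header and no arrangement argument"
        )
    try:
        return RdnaUnitModel(
            name=rec.id,
            sequence=str(rec.seq),
            subregions=tuple(subregions),
            arrangement=arrangement,
        )
    except ValidationError as exc:
        raise ValidationError(f"{unit_fasta}: {exc}") from exc


def write_unit_model(
    model: RdnaUnitModel, unit_fasta: str | Path, annotation_table: str | Path
) -> None:
    """Write the FASTA + BED-like TSV pair read back by :func:`load_unit_model`."""
    SeqIO.write(
        [SeqRecord(Seq(model.sequence), id=model.name, description="")],
        str(unit_fasta),
        "fasta",
    )
    lines = [f"#arrangement={model.arrangement}"]
    for s in model.subregions:
        lines.append(f"{model.name}\t{s.start}\t{s.end}\t{s.label}\t{s.strand}")
    Path(annotation_table).write_text("\n".join(lines) + "\n")


def subregion_lengths(model: RdnaUnitModel) -> pd.DataFrame:
    """One row per subregion with its length in bp (annotation order)."""
    return pd.DataFrame(
        [(s.label, s.start, s.end, s.length) for s in model.subregions],
        columns=["label", "start", "end", "length"],
    )


def gc_content(seq: str) -> float:
    """G+C fraction of ``seq`` (N excluded from the denominator)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt
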