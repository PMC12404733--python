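"""Mature tRNA reference universe.

Loads isodecoder sequences (FASTA) together with a per-isodecoder annotation
table, groups them into anticodon families, and derives the ADAT target
families (anticodon starting with A at the wobble position 34) and their
ADAT-dependent codons from wobble-pairing rules.

Coordinates are 0-based, half-open throughout.  "Position 34" is realised as
the annotated index of the anticodon's first base, not inferred from secondary
structure.  The internal nucleotide alphabet is DNA (U is normalised to T on
load); codons are rendered as RNA (U) only in exported reports.

Wobble read-sets used for codon decoding (anticodon base 34 vs codon base 3):

======  ==================  =========================================
base34  reads (codon 3rd)   note
======  ==================  =========================================
A (=I)  T, C, A             ANN anticodons are fully edited to inosine
G       C, T                standard G:U wobble
C       G                   strict Watson-Crick
T       A, G, T             modified-U wobble in 4-codon boxes
======  ==================  =========================================

Under these rules and the packaged standard eukaryotic cytoplasmic anticodon
table, every ADAT family has exactly one *dependent* codon -- the C-ending
codon of its box -- because G34 anticodons are absent from the boxes decoded
by ANN tRNAs in eukaryotic genomes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

NUCS = "ACGT"

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: codon third-position bases readable by each anticodon wobble (34) base
WOBBLE_READS = {
    "A": ("T", "C", "A"),  # A34 in ANN families is deaminated to inosine
    "G": ("C", "T"),
    "C": ("G",),
    "T": ("A", "G", "T"),
}


class ReferenceError(ValueError):
    """Raised when the reference FASTA/annotation pair is inconsistent."""


def _normalize(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set(NUCS)
    if bad:
        raise ReferenceError(f"non-ACGT(U) characters in sequence: {sorted(bad)}")
    return seq


def to_rna(codon: str) -> str:
    """Render a DNA codon/anticodon in RNA alphabet for reports."""
    return codon.replace("T", "U")


@dataclass(frozen=True)
class IsodecoderRecord:
    """One mature tRNA transcript.

    mod_sites lists annotated modified positions as (0-based index, label);
    the wobble position of ANN families is *not* listed here -- it is derived
    from the anticodon annotation.
    """

    id: str
    sequence: str
    amino_acid: str
    anticodon: str
    anticodon_start: int
    genome: str  # "nuclear" | "mitochondrial"
    mod_sites: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"{self.id}: empty sequence")
        s, a = self.anticodon_start, self.anticodon
        if len(a) != 3:
            raise ReferenceError(f"{self.id}: anticodon {a!r} is not a 3-mer")
        if s < 0 or s + 3 >= len(self.sequence):
            raise ReferenceError(
                f"{self.id}: anticodon_start {s} out of range for length "
                f"{len(self.sequence)}"
            )
        if self.sequence[s : s + 3] != a:
            raise ReferenceError(
                f"{self.id}: annotated anticodon {a} not found at position {s} "
                f"(sequence has {self.sequence[s:s+3]})"
            )
        if self.genome not in ("nuclear", "mitochondrial"):
            raise ReferenceError(f"{self.id}: genome flag {self.genome!r}")

    @property
    def wobble_index(self) -> int:
        """0-based index of the anticodon's first base (Sprinzl 34)."""
        return self.anticodon_start

    @property
    def is_ann(self) -> bool:
        """ADAT substrate: nuclear-encoded with A at the wobble position."""
        return self.genome == "nuclear" and self.anticodon[0] == "A"

    @property
    def family_key(self) -> tuple[str, str]:
        return (self.amino_acid, self.anticodon)


def wobble_index(record: IsodecoderRecord) -> int:
    """Linear 0-based index standing in for Sprinzl position 34."""
    return record.wobble_index


@dataclass(frozen=True)
class AnticodonFamily:
    key: tuple[str, str]  # (amino_acid, anticodon)
    members: tuple[str, ...]
    is_adat_target: bool

    @property
    def label(self) -> str:
        return f"{self.key[0]}-{self.key[1]}"


@dataclass(frozen=True)
class CodonSet:
    family_key: tuple[str, str]
    decoded_codons: tuple[str, ...]
    dependent_codons: tuple[str, ...]


@dataclass
class ReferenceSet:
    """Validated isodecoder records grouped into anticodon families."""

    records: dict[str, IsodecoderRecord]
    families: dict[tuple[str, str], AnticodonFamily] = field(init=False)

    def __post_init__(self) -> None:
        fams: dict[tuple[str, str], list[str]] = {}
        for rec in self.records.values():
            fams.setdefault(rec.family_key, []).append(rec.id)
        self.families = {}
        for key in sorted(fams):
            members = tuple(sorted(fams[key]))
            # mitochondrial records never form ADAT targets
            nuclear = any(self.records[m].genome == "nuclear" for m in members)
            self.families[key] = AnticodonFamily(
                key=key,
                members=members,
                is_adat_target=nuclear and key[1][0] == "A",
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def nuclear_records(self) -> list[IsodecoderRecord]:
        return [r for r in self.records.values() if r.genome == "nuclear"]

    def ann_records(self) -> list[IsodecoderRecord]:
        return [r for r in self.records.values() if r.is_ann]

    def family_of(self, iso_id: str) -> AnticodonFamily:
        return self.families[self.records[iso_id].family_key]

    def anticodon_table(self) -> pd.DataFrame:
        """Distinct (amino_acid, anticodon) pairs of nuclear records."""
        rows = sorted(
            {(r.amino_acid, r.anticodon) for r in self.nuclear_records()}
        )
        return pd.DataFrame(rows, columns=["amino_acid", "anticodon"])


def _parse_mod_sites(cell: object) -> tuple[tuple[int, str], ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        pos, _, label = item.partition(":")
        out.append((int(pos), label))
    return tuple(out)


def load_reference(
    fasta_source, annotation_source, append_cca: bool = True
) -> ReferenceSet:
    """Load a tRNA reference (FASTA) with its annotation table (TSV).

    The annotation TSV must carry a header with columns id, amino_acid,
    anticodon, anticodon_start, genome, mod_sites (semicolon-separated
    ``pos:label`` pairs, may be empty).  Every FASTA record needs exactly one
    annotation row.  U is normalised to T; when *append_cca* is set, a 3'CCA
    tail is appended to sequences that lack one.
    """
    annot = pd.read_csv(annotation_source, sep="\t", dtype={"mod_sites": str})
    required = {"id", "amino_acid", "anticodon", "anticodon_start", "genome"}
    missing = required - set(annot.columns)
    if missing:
        raise ReferenceError(f"annotation table missing columns: {sorted(missing)}")
    dup = annot["id"][annot["id"].duplicated()]
    if len(dup):
        raise ReferenceError(f"duplicate annotation rows for: {sorted(set(dup))}")
    annot = annot.set_index("id")

    records: dict[str, IsodecoderRecord] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        if rec.id not in annot.index:
            raise ReferenceError(f"no annotation row for FASTA record {rec.id!r}")
        row = annot.loc[rec.id]
        seq = _normalize(str(rec.seq))
        if append_cca and not seq.endswith("CCA"):
            seq = seq + "CCA"
        records[rec.id] = IsodecoderRecord(
            id=rec.id,
            sequence=seq,
            amino_acid=str(row["amino_acid"]),
            anticodon=_normalize(str(row["anticodon"])),
            anticodon_start=int(row["anticodon_start"]),
            genome=str(row["genome"]),
            mod_sites=_parse_mod_sites(row.get("mod_sites")),
        )
    extra = set(annot.index) - set(records)
    if extra:
        raise ReferenceError(f"annotation rows without FASTA record: {sorted(extra)}")
    if not records:
        raise ReferenceError("empty reference")
    return ReferenceSet(records=records)


# ---------------------------------------------------------------------------
# ADAT targets and dependent codons
# ---------------------------------------------------------------------------

def packaged_anticodon_table() -> pd.DataFrame:
    """The shipped standard eukaryotic cytoplasmic anticodon table."""
    ref = importlib.resources.files("wobbleseq.data") / "anticodon_table.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def classify_adat_targets(source) -> list[AnticodonFamily]:
    """ADAT target families (anticodon first base A), sorted by (aa, anticodon).

    *source* may be a ReferenceSet (nuclear records only are considered) or an
    anticodon DataFrame with columns amino_acid/anticodon.
    """
    if isinstance(source, ReferenceSet):
        table = source.anticodon_table()
        fams = source.families
        out = [
            fams[(aa, ac)]
            for aa, ac in table.itertuples(index=False)
            if fams[(aa, ac)].is_adat_target
        ]
        return sorted(out, key=lambda f: f.key)
    table = source
    out = []
    for aa, ac in sorted(
        table[["amino_acid", "anticodon"]].itertuples(index=False)
    ):
        ac = _normalize(ac)
        if ac[0] == "A":
            out.append(AnticodonFamily(key=(aa, ac), members=(), is_adat_target=True))
    return out


def codons_read_by(anticodon: str) -> set[str]:
    """All codons an anticodon can decode under the module's wobble rules."""
    anticodon = _normalize(anticodon)
    stem = COMPLEMENT[anticodon[2]] + COMPLEMENT[anticodon[1]]
    return {stem + third for third in WOBBLE_READS[anticodon[0]]}


def enumerate_dependent_codons(
    family: AnticodonFamily, full_anticodon_table: pd.DataFrame
) -> CodonSet:
    """Decoded and ADAT-dependent codons of an ADAT target family.

    Decoded codons are those whose first two bases are Watson-Crick complements
    of anticodon bases 36-35 and whose third base is readable by inosine
    (T, C or A).  Dependent codons are the decoded codons read by no other
    anticodon in *full_anticodon_table* under the wobble rules.
    """
    if not family.is_adat_target:
        raise ValueError(f"{family.label} is not an ADAT target family")
    anticodon = family.key[1]
    decoded = sorted(codons_read_by(anticodon))
    others = [
        _normalize(ac)
        for ac in full_anticodon_table["anticodon"]
        if _normalize(ac) != anticodon
    ]
    covered: set[str] = set()
    for ac in others:
        covered |= codons_read_by(ac)
    dependent = tuple(c for c in decoded if c not in covered)
    return CodonSet(
        family_key=family.key,
        decoded_codons=tuple(decoded),
        dependent_codons=dependent,
    )


def dependent_codon_table(
    anticodon_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """CodonSet export for every ADAT family (RNA rendering): family, decoded,
    dependent."""
    table = anticodon_table if anticodon_table is not None else packaged_anticodon_table()
    rows = []
    for fam in classify_adat_targets(table):
        cs = enumerate_dependent_codons(fam, table)
        rows.append(
            {
                "family": fam.label,
                "decoded": ",".join(to_rna(c) for c in cs.decoded_codons),
                "dependent": ",".join(to_rna(c) for c in cs.dependent_codons),
            }
        )
    return pd.DataFrame(rows)


def write_codon_sets(path: str | Path, anticodon_table=None) -> None:
    dependent_codon_table(anticodon_table).to_csv(path, sep="\t", index=False)
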