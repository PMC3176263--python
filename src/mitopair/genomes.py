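"""Domain types and I/O for annotated circular mitochondrial genomes.

Coordinates are 1-based and inclusive at both ends throughout the package,
the convention of published mitogenome annotation tables.  Each feature span
is linear (no feature wraps through the origin), although the molecule
itself is circular; circularity enters only through :func:`extract_region`
and the occupancy logic in :mod:`mitopair.annotation`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "UR", "LUR")
INCOMPLETE_STOP = "T--"

#: Column order of the feature-table TSV dialect.
TSV_COLUMNS = (
    "Type", "Name", "Starts", "Stops", "Length",
    "Strand", "Anticodon", "StartCodon", "StopCodon",
)


class ParseError(ValueError):
    """Malformed input file (names the offending line)."""


class ConsistencyError(ValueError):
    """Input violates a declared invariant (names the offending feature)."""


class UnsupportedFeatureError(ValueError):
    """GenBank feature uses a location we deliberately do not support."""


def _clean_seq(seq: str, *, context: str = "sequence") -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_DNA:
            raise ParseError(
                f"{context}: non-IUPAC symbol {ch!r} at position {i + 1}"
            )
    return seq


@dataclass
class GenomeRecord:
    """A single (usually circular) mitochondrial genome.

    ``sequence`` is optional: statistics that only need coordinates can run
    on a record that carries just ``length``.
    """

    id: str
    length: int
    sequence: str | None = None
    lineage_type: str = "unspecified"  # F, M or unspecified
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConsistencyError(f"genome {self.id}: non-positive length")
        if self.lineage_type not in ("F", "M", "unspecified"):
            raise ConsistencyError(
                f"genome {self.id}: lineage_type must be F, M or unspecified"
            )
        if self.sequence is not None:
            self.sequence = _clean_seq(self.sequence, context=f"genome {self.id}")
            if len(self.sequence) != self.length:
                raise ConsistencyError(
                    f"genome {self.id}: sequence length {len(self.sequence)} "
                    f"!= declared length {self.length}"
                )


@dataclass
class Feature:
    """One annotated feature (gene, tRNA, rRNA or unassigned region)."""

    ftype: str
    name: str
    start: int
    stop: int
    strand: str = "H"
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ConsistencyError(f"{self.name}: unknown feature type {self.ftype!r}")
        if self.start < 1 or self.stop < self.start:
            raise ConsistencyError(
                f"{self.name}: invalid span {self.start}..{self.stop}"
            )
        if self.strand not in ("H", "L"):
            raise ConsistencyError(f"{self.name}: strand must be H or L")
        if self.anticodon is not None and self.ftype != "tRNA":
            raise ConsistencyError(f"{self.name}: anticodon on non-tRNA feature")
        if (self.start_codon or self.stop_codon) and self.ftype != "CDS":
            raise ConsistencyError(f"{self.name}: start/stop codon on non-CDS feature")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    @property
    def has_incomplete_stop(self) -> bool:
        return self.stop_codon is not None and "-" in self.stop_codon


@dataclass
class FeatureTable:
    """Ordered annotation of one genome (sorted by start, ties by stop desc)."""

    genome_id: str
    genome_length: int
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, -f.stop))
        for f in self.features:
            if f.stop > self.genome_length:
                raise ConsistencyError(
                    f"{f.name}: stop {f.stop} beyond genome length {self.genome_length}"
                )

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_type(self, *ftypes: str) -> list[Feature]:
        return [f for f in self.features if f.ftype in ftypes]

    @property
    def cds(self) -> list[Feature]:
        return self.of_type("CDS")

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def without_unassigned(self) -> "FeatureTable":
        """Copy with UR/LUR rows stripped (input to UR inference)."""
        return FeatureTable(
            self.genome_id,
            self.genome_length,
            [dataclasses.replace(f) for f in self.features if f.ftype not in ("UR", "LUR")],
        )


@dataclass(frozen=True)
class GeneticCode:
    """A translation table (DNA alphabet, stop = '*')."""

    code_id: int
    codon_to_aa: dict
    start_codons: frozenset

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ConsistencyError("genetic code must map all 64 codons")

    @classmethod
    def from_table(cls, code_id: int = 5) -> "GeneticCode":
        """Build from NCBI translation-table number (default 5, invertebrate mito)."""
        table = CodonTable.unambiguous_dna_by_id[code_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(code_id, mapping, frozenset(table.start_codons))

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper().replace("U", "T")]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == "*"

    @property
    def sense_codons(self) -> list[str]:
        return [c for c, aa in self.codon_to_aa.items() if aa != "*"]


INVERTEBRATE_MITO = GeneticCode.from_table(5)


# ---------------------------------------------------------------------------
# feature-table TSV dialect
# ---------------------------------------------------------------------------

_TYPE_ALIASES = {"GENE": "CDS", "CDS": "CDS", "TRNA": "tRNA", "RRNA": "rRNA",
                 "UR": "UR", "LUR": "LUR"}


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read the 9-column tab-separated annotation dialect.

    Header row is required; ``#`` lines are comments.  The directives
    ``# genome_id:`` and ``# genome_length:`` are honoured when present,
    otherwise the id is the file stem and the length is the maximum stop.
    A declared Length cell is cross-validated against the coordinates.
    """
    path = Path(path)
    genome_id = path.stem
    genome_length = None
    features: list[Feature] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip("# ").strip()
                if body.lower().startswith("genome_id:"):
                    genome_id = body.split(":", 1)[1].strip()
                elif body.lower().startswith("genome_length:"):
                    genome_length = int(body.split(":", 1)[1])
                continue
            cells = line.split("\t")
            if not header_seen:
                got = [c.strip().replace(" ", "") for c in cells]
                if got[:9] != list(TSV_COLUMNS):
                    raise ParseError(
                        f"{path}:{lineno}: expected header {TSV_COLUMNS}, got {cells}"
                    )
                header_seen = True
                continue
            cells = (cells + [""] * 9)[:9]
            typ_raw, name, starts, stops, length, strand, anticodon, startc, stopc = (
                c.strip() for c in cells
            )
            ftype = _TYPE_ALIASES.get(typ_raw.upper())
            if ftype is None:
                raise ParseError(f"{path}:{lineno}: unknown feature type {typ_raw!r}")
            try:
                start, stop = int(starts), int(stops)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from exc
            if length:
                declared = int(length)
                if declared != stop - start + 1:
                    raise ConsistencyError(
                        f"{name}: declared length {declared} != "
                        f"{stop}-{start}+1 = {stop - start + 1}"
                    )
            features.append(
                Feature(
                    ftype=ftype,
                    name=name,
                    start=start,
                    stop=stop,
                    strand=strand or "H",
                    anticodon=anticodon or None,
                    start_codon=startc or None,
                    stop_codon=stopc or None,
                )
            )
    if not header_seen:
        raise ParseError(f"{path}: missing header row")
    if genome_length is None:
        genome_length = max(f.stop for f in features)
    return FeatureTable(genome_id, genome_length, features)


def write_feature_table(ft: FeatureTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# genome_id: {ft.genome_id}\n")
        fh.write(f"# genome_length: {ft.genome_length}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for f in ft:
            fh.write(
                "\t".join(
                    [
                        "GENE" if f.ftype == "CDS" else f.ftype,
                        f.name,
                        str(f.start),
                        str(f.stop),
                        str(f.length),
                        f.strand if f.ftype not in ("UR", "LUR") else "",
                        f.anticodon or "",
                        f.start_codon or "",
                        f.stop_codon or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeRecord:
    """Read a single-record FASTA into a GenomeRecord (uppercased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    seq = _clean_seq(str(rec.seq), context=f"{path}:{rec.id}")
    return GenomeRecord(id=rec.id, length=len(seq), sequence=seq)


def write_fasta(record: GenomeRecord, path: str | Path) -> None:
    if record.sequence is None:
        raise ValueError(f"genome {record.id} carries no sequence")
    SeqIO.write(
        SeqRecord(Seq(record.sequence), id=record.id, description=""),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# GenBank import
# ---------------------------------------------------------------------------

def import_genbank_features(path: str | Path) -> tuple[GenomeRecord, FeatureTable]:
    """Read a GenBank flat file (single record, simple locations only).

    Coordinates are converted to 1-based inclusive.  ``complement()`` maps to
    strand L.  ``join()`` / multi-interval locations raise
    :class:`UnsupportedFeatureError` rather than being silently mangled.
    A CDS whose 3' end is truncated by 1-2 nt (partial location, or span not
    a codon multiple) is recorded with the incomplete-stop token.
    Unannotated gaps are NOT materialized here; that is the job of
    :func:`mitopair.annotation.infer_unassigned_regions`.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq).upper()
    genome = GenomeRecord(id=rec.id, length=len(seq), sequence=seq)
    type_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    features: list[Feature] = []
    for gb in rec.features:
        ftype = type_map.get(gb.type)
        if ftype is None:
            continue
        if isinstance(gb.location, CompoundLocation):
            raise UnsupportedFeatureError(
                f"{gb.type} at {gb.location}: join()/multi-interval locations "
                "are not supported"
            )
        start = int(gb.location.start) + 1
        stop = int(gb.location.end)
        strand = "L" if gb.location.strand == -1 else "H"
        name = (
            gb.qualifiers.get("gene", [None])[0]
            or gb.qualifiers.get("product", [None])[0]
            or f"{gb.type}_{start}"
        )
        anticodon = None
        start_codon = stop_codon = None
        if ftype == "tRNA":
            anti = gb.qualifiers.get("anticodon", [None])[0]
            if anti and len(anti) == 3:
                anticodon = anti.upper().replace("U", "T")
        if ftype == "CDS":
            span = stop - start + 1
            partial_3p = str(gb.location.end).startswith(">") or span % 3 != 0
            if partial_3p and span % 3 in (1, 2):
                tail = span % 3
                tail_seq = seq[stop - tail:stop] if strand == "H" else str(
                    Seq(seq[start - 1:start - 1 + tail]).reverse_complement()
                )
                stop_codon = tail_seq + "-" * (3 - tail)
        features.append(
            Feature(ftype=ftype, name=name, start=start, stop=stop, strand=strand,
                    anticodon=anticodon, start_codon=start_codon,
                    stop_codon=stop_codon)
        )
    return genome, FeatureTable(rec.id, len(seq), features)


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def extract_region(
    genome: GenomeRecord, start: int, stop: int, circular_wrap: bool = False
) -> str:
    """1-based inclusive slice; with ``circular_wrap`` a stop beyond the end
    wraps through position 1."""
    if genome.sequence is None:
        raise ValueError(f"genome {genome.id} carries no sequence")
    n = genome.length
    if start < 1 or stop < start:
        raise IndexError(f"invalid region {start}..{stop}")
    if stop <= n:
        return genome.sequence[start - 1:stop]
    if not circular_wrap:
        raise IndexError(f"region {start}..{stop} outside 1..{n} (wrap disabled)")
    if start > n:
        raise IndexError(f"region start {start} beyond genome length {n}")
    return genome.sequence[start - 1:] + genome.sequence[: stop - n]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class CodonExtraction:
    """Codons of one CDS (terminal complete stop retained)."""

    codons: list[str]
    translation: str
    incomplete_stop: str | None  # e.g. "T--" when the stop is polyadenylation-completed
    warnings: list[str] = field(default_factory=list)

    @property
    def n_codons(self) -> int:
        return len(self.codons)


def cds_codon_count(feature: Feature) -> int:
    """Codon count implied by the annotated span alone.

    floor(span/3): the terminal complete stop codon is included, a trailing
    1-2 nt incomplete stop is excluded.  On the published annotations this
    reproduces every printed per-gene residue count.
    """
    if feature.ftype != "CDS":
        raise ValueError(f"{feature.name}: not a CDS")
    return feature.length // 3


def extract_cds_codons(
    genome: GenomeRecord,
    feature: Feature,
    code: GeneticCode = INVERTEBRATE_MITO,
    exclude_stops: bool = False,
) -> CodonExtraction:
    """Split a CDS span into codons and translate it.

    A span that is not a codon multiple ends in a 1-2 nt partial codon: it is
    excluded from the codon list and recorded as the incomplete-stop token
    (completion by polyadenylation).  With ``exclude_stops`` the terminal
    complete stop codon is dropped from the returned list as well.
    An internal stop yields a warning record, not a failure, so the function
    can audit questionable annotations.
    """
    if feature.ftype != "CDS":
        raise ValueError(f"{feature.name}: not a CDS")
    if feature.length < 6:
        raise ValueError(f"{feature.name}: span {feature.length} nt too short for a CDS")
    raw = extract_region(genome, feature.start, feature.stop, circular_wrap=True)
    if feature.strand == "L":
        raw = reverse_complement(raw)
    n_codons = len(raw) // 3
    rem = len(raw) % 3
    codons = [raw[i * 3:(i + 1) * 3] for i in range(n_codons)]
    incomplete = raw[n_codons * 3:] + "-" * (3 - rem) if rem else None
    if exclude_stops and codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    translation = "".join(code.translate(c) for c in codons)
    warnings = [
        f"{feature.name}: internal stop codon at codon {i + 1}"
        for i, aa in enumerate(translation[:-1])
        if aa == "*"
    ]
    return CodonExtraction(codons, translation, incomplete, warnings)
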