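"""Codon counting and codon-usage-bias statistics.

All per-codon bookkeeping uses the RNA alphabet (U not T) because that is how
codon-usage tables are conventionally printed; DNA input is accepted
everywhere.  Stop codons are included in counts and totals by default — the
published per-genome totals this package reproduces are stop-inclusive — and
every operation takes an ``include_stops``/pre-filtered table where exclusion
is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genomes import GeneticCode, INVERTEBRATE_MITO

RNA_BASES = "UCAG"
ALL_CODONS = tuple(a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES)


def _rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


@dataclass
class CodonCountTable:
    """64-codon counts for one genome (stop codons included)."""

    label: str
    counts: dict
    excluded: int = 0  # codons dropped for ambiguity symbols

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            key = _rna(codon)
            if key not in full:
                raise ValueError(f"{self.label}: invalid codon {codon!r}")
            if n < 0:
                raise ValueError(f"{self.label}: negative count for {codon}")
            full[key] += n
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def without_stops(self, code: GeneticCode = INVERTEBRATE_MITO) -> "CodonCountTable":
        kept = {c: n for c, n in self.counts.items() if not code.is_stop(c)}
        return CodonCountTable(self.label, kept, self.excluded)


def count_codons(
    cds_codon_lists: Iterable[Sequence[str]],
    include_stops: bool = True,
    code: GeneticCode = INVERTEBRATE_MITO,
    label: str = "",
) -> CodonCountTable:
    """Aggregate codon counts across the coding genes of one genome.

    Codons containing ambiguity symbols are excluded and tallied in
    ``excluded``; with ``include_stops=False`` stop codons are dropped too.
    """
    counts: dict = {}
    excluded = 0
    for codons in cds_codon_lists:
        for codon in codons:
            key = _rna(codon)
            if any(b not in RNA_BASES for b in key):
                excluded += 1
                continue
            if not include_stops and code.is_stop(key):
                continue
            counts[key] = counts.get(key, 0) + 1
    return CodonCountTable(label, counts, excluded)


@dataclass
class FamilyMarginals:
    """Sums of codon counts over the standard reporting margins."""

    family: dict  # "XY" -> {third base -> count}, 16 families
    third_base: dict  # NNU/NNC/NNA/NNG totals
    first_by_third: dict  # "XNY" -> count, 16 cells
    second_position: dict  # NUN/NCN/NAN/NGN
    total: int

    def percent(self, count: int) -> float:
        return 100.0 * count / self.total


def family_marginals(t: CodonCountTable) -> FamilyMarginals:
    family = {
        a + b: {c: t.counts[a + b + c] for c in RNA_BASES}
        for a in RNA_BASES
        for b in RNA_BASES
    }
    third = {
        f"NN{c}": sum(t.counts[x + y + c] for x in RNA_BASES for y in RNA_BASES)
        for c in RNA_BASES
    }
    first_by_third = {
        f"{a}N{c}": sum(t.counts[a + b + c] for b in RNA_BASES)
        for a in RNA_BASES
        for c in RNA_BASES
    }
    second = {
        f"N{b}N": sum(t.counts[a + b + c] for a in RNA_BASES for c in RNA_BASES)
        for b in RNA_BASES
    }
    return FamilyMarginals(family, third, first_by_third, second, t.total)


def at_ending_fraction(t: CodonCountTable) -> float:
    """Percent of codons ending in A or U (printed to one decimal)."""
    if t.total == 0:
        raise ValueError(f"{t.label}: empty codon table")
    m = family_marginals(t)
    return m.percent(m.third_base["NNU"] + m.third_base["NNA"])


@dataclass(frozen=True)
class NntNncResult:
    ratio: float | None  # None marks an infinite ratio (no NNC usage)
    pct_t: float
    pct_c: float
    families: tuple  # the XY families where XYU and XYC are synonymous


def nnt_nnc_ratio(
    t: CodonCountTable, code: GeneticCode = INVERTEBRATE_MITO
) -> NntNncResult:
    """T-ending over C-ending usage across NNY-synonymous families.

    A family XY qualifies when XYU and XYC encode the same amino acid (all 16
    do under the invertebrate mitochondrial code).  Percentages are of the
    full codon total, matching the convention of published third-position
    composition figures.
    """
    fams = tuple(
        a + b
        for a in RNA_BASES
        for b in RNA_BASES
        if code.translate(a + b + "U") == code.translate(a + b + "C")
    )
    nnu = sum(t.counts[f + "U"] for f in fams)
    nnc = sum(t.counts[f + "C"] for f in fams)
    ratio = None if nnc == 0 else nnu / nnc
    return NntNncResult(
        ratio=ratio,
        pct_t=100.0 * nnu / t.total,
        pct_c=100.0 * nnc / t.total,
        families=fams,
    )


def degeneracy_classes(code: GeneticCode = INVERTEBRATE_MITO) -> dict:
    """Classify each first-two-base family as 4FD, 2FD or mixed.

    4FD: all four third bases encode one amino acid.  2FD: the pyrimidine
    pair and the purine pair each encode one amino acid (two two-fold sets;
    stop counts as a 'product' here, e.g. the UAR stop pair).  Anything else
    is mixed.  Derived purely from the code so the classification carries
    over to other translation tables.
    """
    out = {}
    for a in RNA_BASES:
        for b in RNA_BASES:
            fam = a + b
            aas = [code.translate(fam + c) for c in RNA_BASES]
            partition = {
                "UC": {aas[0], aas[1]},
                "AG": {aas[2], aas[3]},
            }
            if len(set(aas)) == 1:
                cls = "4FD"
            elif len(partition["UC"]) == 1 and len(partition["AG"]) == 1:
                cls = "2FD"
            else:
                cls = "mixed"
            out[fam] = {"class": cls, "aa": tuple(aas)}
    return out


@dataclass(frozen=True)
class UsageRanking:
    most_used: tuple  # (codon, count), ties flagged
    least_used: tuple
    ties_most: bool
    ties_least: bool
    ranking: tuple  # all (codon, count) most->least, ties lexicographic


def most_least_used(t: CodonCountTable) -> UsageRanking:
    """Deterministic usage ranking; ties broken lexicographically and flagged."""
    present = [(c, n) for c, n in t.counts.items() if n > 0]
    if not present:
        raise ValueError(f"{t.label}: empty codon table")
    ranking = tuple(sorted(present, key=lambda kv: (-kv[1], kv[0])))
    top, bottom = ranking[0], ranking[-1]
    ties_most = sum(1 for _, n in present if n == top[1]) > 1
    ties_least = sum(1 for _, n in present if n == bottom[1]) > 1
    return UsageRanking(top, bottom, ties_most, ties_least, ranking)


_DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _anticodon_to_codon(anticodon_dna: str) -> str:
    """Exact Watson-Crick decoding: codon = reverse complement of anticodon."""
    rc = "".join(_DNA_COMPLEMENT[b] for b in reversed(anticodon_dna.upper()))
    return _rna(rc)


@dataclass(frozen=True)
class AnticodonMatch:
    anticodon: str  # DNA, as annotated
    exact_codon: str  # RNA codon read by strict Watson-Crick pairing
    amino_acid: str
    synonymous_set: tuple  # codons in the same family encoding the same aa
    modal_codon: str
    matches: bool
    tie: bool


def anticodon_mismatches(
    t: CodonCountTable,
    anticodons: Iterable[str],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> tuple[list[AnticodonMatch], list[str]]:
    """Compare each tRNA's strict Watson-Crick codon to its family's modal codon.

    For every annotated anticodon, the served synonymous set is the group of
    codons sharing the first two bases AND the amino acid of the decoded
    codon (the 2FD pair or 4FD quartet).  Wobble is deliberately not
    modelled: the comparison is exact complement versus modal usage.
    Returns (per-tRNA records, families with no serving tRNA).
    """
    records = []
    served = set()
    for anti in anticodons:
        codon = _anticodon_to_codon(anti)
        aa = code.translate(codon)
        fam = codon[:2]
        syn = tuple(
            fam + c for c in RNA_BASES if code.translate(fam + c) == aa
        )
        served.update(syn)
        modal = max(syn, key=lambda c: (t.counts[c], c))
        tie = sum(1 for c in syn if t.counts[c] == t.counts[modal]) > 1
        records.append(
            AnticodonMatch(
                anticodon=anti.upper(),
                exact_codon=codon,
                amino_acid=aa,
                synonymous_set=syn,
                modal_codon=min(c for c in syn if t.counts[c] == t.counts[modal]),
                matches=t.counts[codon] == t.counts[modal],
                tie=tie,
            )
        )
    unserved = sorted(
        {
            c
            for c in ALL_CODONS
            if not code.is_stop(c) and c not in served and t.counts[c] > 0
        }
    )
    return records, unserved
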