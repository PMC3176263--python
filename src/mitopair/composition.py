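"""Base composition, A+T content and strand-skew statistics.

Skews follow the H-strand convention: GC skew = (G-C)/(G+C) and
AT skew = (A-T)/(A+T), where the base counts are taken on the strand that
carries all the genes.  In the genomes this package was built around that
strand is G-rich (positive GC skew) and T-rich (negative AT skew).
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import infer_unassigned_regions
from .genomes import FeatureTable, GenomeRecord, extract_region

_BASES = "TCAG"


@dataclass
class CompositionProfile:
    """Counts (or percentage weights) of T/C/A/G for one labelled region.

    ``counts`` may be fractional when the profile was built from printed
    percentages; every derived statistic is scale-invariant.
    """

    label: str
    counts: dict
    #: False when the profile was built from printed percentages: those are
    #: already normalized (up to printed rounding) and are reported verbatim
    #: rather than renormalized by their imperfect sum.
    normalize: bool = True

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def percent(self, base: str) -> float:
        if not self.normalize:
            return self.counts[base]
        return 100.0 * self.counts[base] / self.total

    @property
    def percentages(self) -> dict:
        return {b: self.percent(b) for b in _BASES}

    @property
    def at_content(self) -> float:
        return self.percent("A") + self.percent("T")

    @property
    def gc_skew(self) -> float | None:
        g, c = self.counts["G"], self.counts["C"]
        return None if g + c == 0 else (g - c) / (g + c)

    @property
    def at_skew(self) -> float | None:
        a, t = self.counts["A"], self.counts["T"]
        return None if a + t == 0 else (a - t) / (a + t)

    def rounded(self) -> dict:
        """Reporting view: percentages to 1 decimal, skews to 2."""
        out = {f"%{b}": round(self.percent(b), 1) for b in _BASES}
        out["A+T"] = round(self.at_content, 1)
        out["GC skew"] = None if self.gc_skew is None else round(self.gc_skew, 2)
        out["AT skew"] = None if self.at_skew is None else round(self.at_skew, 2)
        return out


def composition_profile(seq: str, label: str = "") -> CompositionProfile:
    """Count A/C/G/T over a sequence; IUPAC ambiguity symbols are excluded
    from both numerators and denominators."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in _BASES}
    if sum(counts.values()) == 0:
        raise ValueError(f"{label or 'sequence'}: no unambiguous bases")
    return CompositionProfile(label, counts)


def profile_from_percentages(
    pT: float, pC: float, pA: float, pG: float, label: str = "", tol: float = 0.75
) -> CompositionProfile:
    """Build a profile directly from printed percentage rows.

    Skews and A+T content are scale-invariant, so percentages serve as
    fractional counts.  The four values must sum to 100 within ``tol``;
    the default slack of 0.75 accommodates published tables whose
    independently rounded cells can drift up to 0.6 from 100.
    """
    total = pT + pC + pA + pG
    if any(p < 0 for p in (pT, pC, pA, pG)) or abs(total - 100.0) > tol:
        raise ValueError(f"{label}: percentages sum to {total}, expected 100 +/- {tol}")
    return CompositionProfile(
        label, {"T": pT, "C": pC, "A": pA, "G": pG}, normalize=False
    )


def per_region_composition(
    genome: GenomeRecord, ft: FeatureTable
) -> list[CompositionProfile]:
    """One profile per annotated feature plus the standard aggregate rows:
    all URs+LUR, all rRNA genes, all proteins, and the complete genome."""
    if genome.sequence is None:
        raise ValueError(f"genome {genome.id} carries no sequence")

    def span_seq(f) -> str:
        return extract_region(genome, f.start, f.stop, circular_wrap=True)

    profiles = [composition_profile(span_seq(f), f.name) for f in ft]

    ur_rows = ft.of_type("UR", "LUR")
    if not ur_rows:
        from .annotation import unassigned_to_features

        ur_rows = unassigned_to_features(
            infer_unassigned_regions(ft), ft.genome_length
        )
    aggregates = [
        ("all URs/LUR", ur_rows),
        ("all rRNA genes", ft.of_type("rRNA")),
        ("all proteins", ft.of_type("CDS")),
    ]
    for label, rows in aggregates:
        if rows:
            profiles.append(
                composition_profile("".join(span_seq(f) for f in rows), label)
            )
    profiles.append(composition_profile(genome.sequence, "complete"))
    return profiles
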