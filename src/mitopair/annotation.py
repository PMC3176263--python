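"""Statistics derivable from feature coordinates alone.

Unassigned-region (UR) inference, feature overlaps, tRNA clustering,
start/stop-codon tabulation, shared gene boundaries between circular gene
orders, and whole-genome summaries.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from .genomes import (
    INCOMPLETE_STOP,
    Feature,
    FeatureTable,
    GenomeRecord,
    extract_cds_codons,
)

#: Smallest gap materialized as a UR.  The published annotations leave a
#: single 1-nt gap (between trnR and trnS(AGN)) unannotated in both genomes
#: while annotating every gap of 4 nt and above, so gaps of a single
#: nucleotide are treated as annotation slack, not unassigned regions.
DEFAULT_MIN_GAP = 2


@dataclass(frozen=True)
class UnassignedRegion:
    index: int  # ordinal in genome order (UR-1, UR-2, ...)
    start: int
    stop: int
    is_lur: bool = False

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    @property
    def name(self) -> str:
        return "LUR" if self.is_lur else f"UR-{self.index}"


@dataclass(frozen=True)
class OverlapRecord:
    feature_a: str
    feature_b: str
    overlap_len: int


@dataclass(frozen=True)
class TrnaCluster:
    members: tuple

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GenomeSummary:
    genome_id: str
    genome_length: int
    counts: dict
    total_unassigned: int
    start_codons: dict
    stop_codons: dict


def _coverage_runs(ft: FeatureTable) -> list[tuple[int, int]]:
    """Maximal uncovered runs on the circular genome, as (start, stop) spans.

    The run spanning the origin is returned as a single region whose stop
    exceeds genome_length (wrapped span); callers may normalize.
    """
    n = ft.genome_length
    covered = bytearray(n)
    for f in ft.of_type("CDS", "tRNA", "rRNA"):
        covered[f.start - 1:f.stop] = b"\x01" * (f.stop - f.start + 1)
    runs: list[tuple[int, int]] = []
    pos = 0
    while pos < n:
        if covered[pos]:
            pos += 1
            continue
        end = pos
        while end < n and not covered[end]:
            end += 1
        runs.append((pos + 1, end))  # 1-based inclusive
        pos = end
    # merge a run ending at n with a run starting at 1 (circular wrap)
    if len(runs) >= 2 and runs[0][0] == 1 and runs[-1][1] == n:
        first, last = runs[0], runs[-1]
        runs = runs[1:-1]
        runs.append((last[0], n + first[1]))  # wrapped span
    elif len(runs) == 1 and runs[0] == (1, n):
        pass  # fully uncovered genome: single run
    return runs


def infer_unassigned_regions(
    ft: FeatureTable, min_gap: int = DEFAULT_MIN_GAP
) -> list[UnassignedRegion]:
    """Derive URs as maximal runs of positions covered by no gene/tRNA/rRNA.

    Computed on the circular genome (a run spanning the origin is one UR).
    Any UR/LUR rows already present are ignored and re-derived.  Regions are
    numbered in genome order starting with the first gap after the feature
    covering position 1; the single longest region (ties to the smaller
    start) is flagged as the LUR.
    """
    ft = ft.without_unassigned()
    if not ft.features:
        raise ValueError("cannot infer unassigned regions from an empty feature table")
    runs = [r for r in _coverage_runs(ft) if r[1] - r[0] + 1 >= min_gap]
    if not runs:
        return []
    runs.sort()
    # numbering starts after the feature covering position 1; since runs are
    # sorted by start and position 1 is covered whenever a wrapped run exists,
    # plain start order already matches the published numbering.
    lur_idx = max(range(len(runs)), key=lambda i: (runs[i][1] - runs[i][0], -runs[i][0]))
    regions = []
    ordinal = 0
    for i, (a, b) in enumerate(runs):
        is_lur = i == lur_idx
        if not is_lur:
            ordinal += 1
        regions.append(UnassignedRegion(0 if is_lur else ordinal, a, b, is_lur))
    return regions


def unassigned_to_features(regions: list[UnassignedRegion], genome_length: int) -> list[Feature]:
    """Materialize inferred URs as Feature rows (wrapped spans are split)."""
    out = []
    for r in regions:
        ftype = "LUR" if r.is_lur else "UR"
        if r.stop <= genome_length:
            out.append(Feature(ftype=ftype, name=r.name, start=r.start, stop=r.stop))
        else:
            out.append(Feature(ftype=ftype, name=r.name, start=r.start, stop=genome_length))
            out.append(Feature(ftype=ftype, name=r.name + "(wrap)", start=1,
                               stop=r.stop - genome_length))
    return out


def detect_overlaps(ft: FeatureTable) -> list[OverlapRecord]:
    """All unordered pairs of gene/tRNA/rRNA features sharing >= 1 position.

    Feature spans are linear (none wraps the origin), so two spans can only
    share positions in linear coordinates; triple overlaps emit one record
    per pair.
    """
    feats = ft.of_type("CDS", "tRNA", "rRNA")
    records = []
    for a, b in combinations(feats, 2):
        olap = min(a.stop, b.stop) - max(a.start, b.start) + 1
        if olap >= 1:
            records.append(OverlapRecord(a.name, b.name, olap))
    return records


def trna_clusters(ft: FeatureTable) -> tuple[list[TrnaCluster], list[str]]:
    """Maximal circular runs of >= 2 tRNAs interrupted only by URs.

    Any CDS, rRNA or the LUR breaks a run.  If the table carries no UR/LUR
    rows they are inferred first, so that the LUR can act as a breaker.
    Returns (clusters, unclustered tRNA names).
    """
    elements: list[Feature] = list(ft.of_type("CDS", "tRNA", "rRNA"))
    lur_rows = ft.of_type("LUR")
    if not lur_rows:
        inferred = infer_unassigned_regions(ft)
        elements += unassigned_to_features(inferred, ft.genome_length)
    else:
        elements += ft.of_type("UR", "LUR")
    elements.sort(key=lambda f: (f.start, -f.stop))

    # rotate so that the walk starts at a breaker; a run never spans the seam then
    breakers = [i for i, f in enumerate(elements) if f.ftype in ("CDS", "rRNA", "LUR")]
    if not breakers:
        trnas = [f.name for f in elements if f.ftype == "tRNA"]
        return ([TrnaCluster(tuple(trnas))] if len(trnas) >= 2 else []), (
            trnas if len(trnas) < 2 else []
        )
    k = breakers[0]
    ordered = elements[k:] + elements[:k]

    clusters: list[TrnaCluster] = []
    unclustered: list[str] = []
    run: list[str] = []

    def flush() -> None:
        nonlocal run
        if len(run) >= 2:
            clusters.append(TrnaCluster(tuple(run)))
        else:
            unclustered.extend(run)
        run = []

    for f in ordered:
        if f.ftype == "tRNA":
            run.append(f.name)
        elif f.ftype == "UR":
            continue  # URs of any length join runs
        else:  # CDS, rRNA or LUR
            flush()
    flush()
    return clusters, unclustered


def tabulate_start_stop(
    ft: FeatureTable, genome: GenomeRecord | None = None
) -> tuple[dict, dict]:
    """Counts of start and stop codons over the CDS features.

    Codons are read from the annotation when present, else from ``genome``.
    Incomplete stops are tokenized as ``T--`` (any 1-2 nt partial).
    """
    starts: Counter = Counter()
    stops: Counter = Counter()
    for f in ft.cds:
        start_c, stop_c = f.start_codon, f.stop_codon
        if (start_c is None or stop_c is None) and genome is not None:
            ext = extract_cds_codons(genome, f)
            start_c = start_c or ext.codons[0]
            stop_c = stop_c or (ext.incomplete_stop or ext.codons[-1])
        if start_c is None or stop_c is None:
            raise ValueError(
                f"{f.name}: CDS lacks codon annotation and no sequence was supplied"
            )
        starts[start_c.upper()] += 1
        stops[INCOMPLETE_STOP if "-" in stop_c else stop_c.upper()] += 1
    return dict(starts), dict(stops)


def shared_boundaries(
    order_a: list[str],
    order_b: list[str],
    ignore_types: set | None = None,
    trna_prefix: str = "trn",
    circular: bool = True,
) -> tuple[int, list[tuple[str, str]]]:
    """Ordered gene adjacencies common to two (circular) gene orders.

    tRNAs (names starting with ``trna_prefix``) are removed before comparing,
    the convention for gene-boundary comparisons between mitogenomes.
    ``ignore_types`` may supply additional exact names to drop.
    """
    def prune(order: list[str]) -> list[str]:
        out = [
            g
            for g in order
            if not g.startswith(trna_prefix) and g not in (ignore_types or set())
        ]
        if len(out) != len(set(out)):
            dupes = [g for g, c in Counter(out).items() if c > 1]
            raise ValueError(f"duplicate gene names: {dupes}; disambiguate first")
        return out

    a, b = prune(order_a), prune(order_b)

    def adjacencies(order: list[str]) -> set:
        if len(order) < 2:
            return set()
        pairs = list(zip(order, order[1:]))
        if circular:
            pairs.append((order[-1], order[0]))
        return set(pairs)

    shared = sorted(adjacencies(a) & adjacencies(b))
    return len(shared), shared


def gene_order(ft: FeatureTable, types: tuple = ("CDS", "rRNA")) -> list[str]:
    """Gene names in genome order, restricted to the given feature types."""
    return [f.name for f in ft if f.ftype in types]


def summarize_genome(ft: FeatureTable, genome: GenomeRecord | None = None) -> GenomeSummary:
    """Aggregate counts, unassigned total and codon tabulations for one genome."""
    counts = Counter(f.ftype for f in ft)
    ur_rows = ft.of_type("UR", "LUR")
    if ur_rows:
        total_unassigned = sum(f.length for f in ur_rows)
    else:
        total_unassigned = sum(r.length for r in infer_unassigned_regions(ft))
    try:
        starts, stops = tabulate_start_stop(ft, genome)
    except ValueError:
        starts, stops = {}, {}
    return GenomeSummary(
        genome_id=ft.genome_id,
        genome_length=ft.genome_length,
        counts=dict(counts),
        total_unassigned=total_unassigned,
        start_codons=starts,
        stop_codons=stops,
    )
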