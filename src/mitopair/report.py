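"""Tabular report assembly: DataFrames shaped like the standard published
layouts (annotation, composition, codon usage, divergence, repeat distances)
plus a text gene map.  Rounding happens here, at the reporting layer only;
the library returns full precision."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import (
    detect_overlaps,
    infer_unassigned_regions,
    summarize_genome,
    tabulate_start_stop,
    trna_clusters,
)
from .codon_usage import (
    CodonCountTable,
    at_ending_fraction,
    family_marginals,
    most_least_used,
    nnt_nnc_ratio,
)
from .composition import CompositionProfile, per_region_composition
from .genomes import FeatureTable, GenomeRecord


def annotation_report(ft: FeatureTable, genome: GenomeRecord | None = None) -> dict:
    """Annotation-statistics block: feature rows, URs, overlaps, clusters,
    codon tabulations, summary."""
    regions = infer_unassigned_regions(ft)
    clusters, unclustered = trna_clusters(ft)
    summary = summarize_genome(ft, genome)
    feature_rows = pd.DataFrame(
        [
            {
                "Type": f.ftype,
                "Name": f.name,
                "Starts": f.start,
                "Stops": f.stop,
                "Length": f.length,
                "Strand": f.strand if f.ftype not in ("UR", "LUR") else "",
                "Anticodon": f.anticodon or "",
                "StartCodon": f.start_codon or "",
                "StopCodon": f.stop_codon or "",
            }
            for f in ft
        ]
    )
    ur_rows = pd.DataFrame(
        [
            {"Name": r.name, "Starts": r.start, "Stops": r.stop, "Length": r.length}
            for r in regions
        ]
    )
    overlap_rows = pd.DataFrame(
        [
            {"FeatureA": o.feature_a, "FeatureB": o.feature_b, "Overlap": o.overlap_len}
            for o in detect_overlaps(ft)
        ]
    )
    cluster_rows = pd.DataFrame(
        [{"Members": " ".join(c.members), "Size": c.size} for c in clusters]
    )
    return {
        "features": feature_rows,
        "unassigned": ur_rows,
        "overlaps": overlap_rows,
        "trna_clusters": cluster_rows,
        "unclustered_trnas": unclustered,
        "summary": summary,
    }


def composition_report(genome: GenomeRecord, ft: FeatureTable) -> pd.DataFrame:
    profiles = per_region_composition(genome, ft)
    rows = []
    for p in profiles:
        r = {"Region": p.label, "Length": int(p.total)}
        r.update(p.rounded())
        rows.append(r)
    return pd.DataFrame(rows)


def codon_report(t: CodonCountTable) -> dict:
    m = family_marginals(t)
    codon_rows = pd.DataFrame(
        [
            {"Codon": c, "Count": n, "Percent": round(100.0 * n / t.total, 1)}
            for c, n in sorted(t.counts.items())
        ]
    )
    aggregates = {
        **m.first_by_third,
        **m.second_position,
        **m.third_base,
        "Total": t.total,
    }
    nny = nnt_nnc_ratio(t)
    ranking = most_least_used(t)
    stats = {
        "at_ending_percent": round(at_ending_fraction(t), 1),
        "nnt_nnc_ratio": None if nny.ratio is None else round(nny.ratio, 1),
        "third_pos_pct_T": round(nny.pct_t, 1),
        "third_pos_pct_C": round(nny.pct_c, 1),
        "most_used": ranking.most_used,
        "least_used": ranking.least_used,
    }
    return {"codons": codon_rows, "aggregates": aggregates, "stats": stats}


def repeat_distance_report(pd_matrix: np.ndarray, se_matrix: np.ndarray,
                           labels: list) -> pd.DataFrame:
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "UnitA": labels[i],
                    "UnitB": labels[j],
                    "pD": round(float(pd_matrix[i, j]), 3),
                    "SE": round(float(se_matrix[i, j]), 3),
                }
            )
    return pd.DataFrame(rows)


def text_gene_map(ft: FeatureTable, width: int = 72) -> str:
    """One-line-per-feature text map with a proportional position gutter."""
    lines = [f"{ft.genome_id}  ({ft.genome_length:,} bp, circular)"]
    for f in ft:
        offset = int((f.start - 1) / ft.genome_length * width)
        glyph = {"CDS": "=", "tRNA": "-", "rRNA": "~", "UR": ".", "LUR": "#"}[f.ftype]
        lines.append(
            f"{f.start:>7}..{f.stop:<7} {' ' * offset}{glyph * 2} {f.name}"
        )
    return "\n".join(lines)
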