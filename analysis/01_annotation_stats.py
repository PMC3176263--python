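#!/usr/bin/env python
"""Annotation-derived statistics of the two sex-linked genomes.

Re-derives, from the packaged annotation tables alone: unassigned regions
(including each genome's LUR), feature overlaps, tRNA clusters, start/stop
codon usage, and whole-genome summaries.  Writes tables under
results/annotation/ and prints the headline numbers.
"""

import json
from pathlib import Path

import pandas as pd

from mitopair import fixtures
from mitopair.annotation import (
    detect_overlaps,
    infer_unassigned_regions,
    summarize_genome,
    tabulate_start_stop,
    trna_clusters,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "annotation"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    for tag, table in (("F", fixtures.feature_table_f()),
                       ("M", fixtures.feature_table_m())):
        regs = infer_unassigned_regions(table)
        urs = pd.DataFrame(
            [{"Name": r.name, "Starts": r.start, "Stops": r.stop,
              "Length": r.length} for r in regs]
        )
        urs.to_csv(OUT / f"unassigned_{tag}.tsv", sep="\t", index=False)

        overlaps = pd.DataFrame(
            [{"A": o.feature_a, "B": o.feature_b, "bp": o.overlap_len}
             for o in detect_overlaps(table)]
        )
        overlaps.to_csv(OUT / f"overlaps_{tag}.tsv", sep="\t", index=False)

        clusters, unclustered = trna_clusters(table)
        starts, stops = tabulate_start_stop(table)
        summary = summarize_genome(table)
        payload = {
            "genome_length": summary.genome_length,
            "feature_counts": summary.counts,
            "total_unassigned": summary.total_unassigned,
            "lur_length": max(r.length for r in regs),
            "n_unassigned_regions": sum(1 for r in regs if not r.is_lur),
            "trna_clusters": [list(c.members) for c in clusters],
            "unclustered_trnas": unclustered,
            "start_codons": starts,
            "stop_codons": stops,
        }
        (OUT / f"summary_{tag}.json").write_text(json.dumps(payload, indent=1))

        print(
            f"{tag}: {summary.genome_length:,} bp, "
            f"{payload['n_unassigned_regions']} URs + LUR "
            f"({payload['lur_length']:,} bp) totalling "
            f"{summary.total_unassigned:,} bp unassigned; "
            f"{sum(len(c.members) for c in clusters)} tRNAs in "
            f"{len(clusters)} clusters, unclustered: {', '.join(unclustered)}; "
            f"starts {starts}, stops {stops}"
        )


if __name__ == "__main__":
    main()
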