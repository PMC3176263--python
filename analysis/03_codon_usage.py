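#!/usr/bin/env python
"""Codon-usage bias of the two proteomes from the published 64-codon counts.

Computes third-position composition, the A/T-ending fraction, NNT:NNC ratios
over NNY-synonymous families, usage rankings and strict-anticodon matching.
Writes results/codon_usage/.
"""

import json
from pathlib import Path

import pandas as pd

from mitopair import fixtures
from mitopair.codon_usage import (
    anticodon_mismatches,
    at_ending_fraction,
    family_marginals,
    most_least_used,
    nnt_nnc_ratio,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "codon_usage"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    tables = {"F": fixtures.feature_table_f(), "M": fixtures.feature_table_m()}
    for tag in ("F", "M"):
        counts = fixtures.codon_counts(tag)
        m = family_marginals(counts)
        pd.DataFrame(
            [{"Codon": c, "Count": n, "Percent": round(100 * n / counts.total, 1)}
             for c, n in sorted(counts.counts.items())]
        ).to_csv(OUT / f"codon_usage_{tag}.tsv", sep="\t", index=False)

        nny = nnt_nnc_ratio(counts)
        rank = most_least_used(counts)
        anticodons = [f.anticodon for f in tables[tag].of_type("tRNA")]
        records, _ = anticodon_mismatches(counts, anticodons)
        mismatches = sorted({r.exact_codon[:2] for r in records if not r.matches})
        stats = {
            "total_codons": counts.total,
            "at_ending_percent": round(at_ending_fraction(counts), 1),
            "nnt_nnc_ratio": round(nny.ratio, 1),
            "third_pos_T_percent": round(nny.pct_t, 1),
            "third_pos_C_percent": round(nny.pct_c, 1),
            "second_pos_T_percent": round(100 * m.second_position["NUN"] / counts.total, 1),
            "most_used": rank.most_used,
            "bottom_three": rank.ranking[-3:],
            "families_with_anticodon_mismatch": mismatches,
        }
        (OUT / f"stats_{tag}.json").write_text(json.dumps(stats, indent=1))
        print(
            f"{tag}: {counts.total} codons, {stats['at_ending_percent']}% end A/T, "
            f"NNT:NNC {stats['nnt_nnc_ratio']}:1, most used "
            f"{rank.most_used[0]} ({rank.most_used[1]}), "
            f"{len(mismatches)} families prefer a non-anticodon codon"
        )


if __name__ == "__main__":
    main()
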