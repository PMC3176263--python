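#!/usr/bin/env python
"""Base composition, A+T content and strand skews per gene and region.

Recomputes GC skew = (G-C)/(G+C) and AT skew = (A-T)/(A+T) on the H strand
from the published per-region base compositions, confirming the strongly
positive GC skew / negative AT skew of both sex-linked genomes.  Writes
results/composition/skews.tsv.
"""

from pathlib import Path

import pandas as pd

from mitopair import fixtures
from mitopair.composition import profile_from_percentages

OUT = Path(__file__).resolve().parents[1] / "results" / "composition"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    rows = []
    for _, r in fixtures.composition_rows().iterrows():
        p = profile_from_percentages(r.pT, r.pC, r.pA, r.pG,
                                     f"{r.Region}/{r.Lineage}")
        rows.append(
            {
                "Region": r.Region,
                "Lineage": r.Lineage,
                "Length": r.Length,
                "A+T": round(p.at_content, 1),
                "GC_skew": round(p.gc_skew, 2),
                "AT_skew": round(p.at_skew, 2),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "skews.tsv", sep="\t", index=False)
    whole = df[df.Region == "complete"].set_index("Lineage")
    print(
        "whole-genome skews: "
        f"F GC {whole.loc['F','GC_skew']:+.2f} / AT {whole.loc['F','AT_skew']:+.2f} "
        f"(A+T {whole.loc['F','A+T']}%), "
        f"M GC {whole.loc['M','GC_skew']:+.2f} / AT {whole.loc['M','AT_skew']:+.2f} "
        f"(A+T {whole.loc['M','A+T']}%)"
    )


if __name__ == "__main__":
    main()
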