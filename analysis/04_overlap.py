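#!/usr/bin/env python
"""Step 4: cross-trait gene-set overlap enrichment.

Two analyses: (a) the literature-curated disorder gene sets compared by
their reported sizes and overlaps against a 20,000-gene background, and
(b) the recurrent UC/CD sets curated from the bundle in step 2.
"""

import argparse

import pandas as pd

from ibdgba import io as cio
from ibdgba.overlap import (
    DEFAULT_BACKGROUND_N,
    bh_adjust,
    contingency,
    enrichment_ratio,
    fisher_two_sided,
    odds_ratio_ci,
)
from ibdgba.pipeline import RunConfig, run_overlap

# literature-curated set sizes and pairwise overlaps
SET_SIZES = {"IBD": 1029, "SCZ": 3193, "ASD": 1062, "ADHD": 1714, "DEP": 2473}
OVERLAPS = {
    ("IBD", "ASD"): 106,
    ("IBD", "ADHD"): 143,
    ("IBD", "DEP"): 188,
    ("IBD", "SCZ"): 238,
    ("SCZ", "ASD"): 721,
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    rows = []
    for (a, b), ov in OVERLAPS.items():
        table = contingency(SET_SIZES[a], SET_SIZES[b], ov, DEFAULT_BACKGROUND_N)
        or_, lo, hi = odds_ratio_ci(table)
        expected, ratio = enrichment_ratio(SET_SIZES[a], SET_SIZES[b], ov, DEFAULT_BACKGROUND_N)
        rows.append({
            "set_a": a, "set_b": b, "n_a": SET_SIZES[a], "n_b": SET_SIZES[b],
            "overlap": ov, "expected": round(expected, 1),
            "odds_ratio": round(or_, 2), "ci_low": round(lo, 2), "ci_high": round(hi, 2),
            "enrichment_ratio": round(ratio, 2), "fisher_p": fisher_two_sided(table),
        })
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["fisher_p"])
    cio.write_table(df, f"{args.out}/literature_overlap.tsv")
    print(df.to_string(index=False))

    config = RunConfig(out_dir=args.out)
    sets = {
        "UC_recurrent": cio.read_gene_set(f"{args.out}/recurrent_uc.txt"),
        "CD_recurrent": cio.read_gene_set(f"{args.out}/recurrent_cd.txt"),
    }
    results = run_overlap(config, sets)
    r = results[0]
    print(f"\nbundle UC/CD recurrent sets: overlap {r.overlap}, "
          f"OR {r.odds_ratio:.2f}, Fisher p {r.fisher_p:.3g}")


if __name__ == "__main__":
    main()
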