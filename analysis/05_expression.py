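#!/usr/bin/env python
"""Step 5: gut-brain tissue expression profile of the shared panel genes.

Aggregates per-gene mean TPM in each tissue, ranks tissues within the
gastrointestinal and brain groups, and tests GIT-vs-brain expression,
set-vs-background enrichment, and within-group region heterogeneity.
"""

import argparse

from ibdgba import io as cio
from ibdgba.pipeline import RunConfig, run_expression


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", default="results/sim")
    parser.add_argument("--out", default="results")
    parser.add_argument("--genes", default="results/shared_panel.txt",
                        help="one-symbol-per-line gene set (default: step-2 panel)")
    args = parser.parse_args()

    config = RunConfig(
        gct=f"{args.bundle}/expression.gct",
        tissue_groups=f"{args.bundle}/tissue_groups.tsv",
        out_dir=args.out,
    )
    genes = cio.read_gene_set(args.genes)
    out = run_expression(config, genes)
    for name, t in out["tests"].items():
        print(f"{name:24s} {t.test:14s} stat {t.statistic:10.3f}  p {t.p_value:.3g}")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
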