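#!/usr/bin/env python
"""Step 2: curate the catalog files into publication-based gene evidence.

Counts each gene once per publication, keeps the best p-value per
(publication, gene), extracts the recurrent (>= 3 studies) gene set per
trait, and intersects them into the shared panel.
"""

import argparse

from ibdgba.pipeline import RunConfig, run_curation


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", default="results/sim")
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    config = RunConfig(
        uc_catalog=f"{args.bundle}/catalog_uc.tsv",
        cd_catalog=f"{args.bundle}/catalog_cd.tsv",
        hgnc_table=f"{args.bundle}/hgnc.tsv",
        out_dir=args.out,
    )
    out = run_curation(config)
    uc, cd = out["recurrent"]["UC"], out["recurrent"]["CD"]
    print(f"recurrent genes: UC {len(uc)}, CD {len(cd)}")
    print(f"shared panel: {len(out['panel'])} genes")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
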