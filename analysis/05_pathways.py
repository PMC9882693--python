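#!/usr/bin/env python
"""Score gene sets per sample and test subtype contrasts.

Scores every sample against the signature and decoy gene sets with the
rank-based enrichment statistic ([-1, 1] per set and sample), then runs
moderated-t contrasts between subtypes and intersects the significant sets
across contrasts.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from brainscape.pipeline import default_config, run_score_pathways, \
    run_test_pathways


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = default_config()
    cfg["seed"] = args.seed
    run_score_pathways(cfg, args.outdir)
    run_test_pathways(cfg, args.outdir)

    scores = pd.read_csv(f"{args.outdir}/pathway_scores.tsv", sep="\t",
                         index_col=0)
    print(f"scored {scores.shape[0]} sets x {scores.shape[1]} samples; "
          f"range [{scores.min().min():.2f}, {scores.max().max():.2f}]")
    for ref, other in cfg["pathways"]["contrasts"]:
        t = pd.read_csv(
            f"{args.outdir}/differential_{ref}_vs_{other}.tsv", sep="\t")
        sig = t[t["adj_p_value"] <= cfg["pathways"]["adj_p_threshold"]]
        print(f"  {ref} vs {other}: {len(sig)} sets at BH "
              f"{cfg['pathways']['adj_p_threshold']}")
    shared = json.loads(Path(f"{args.outdir}/shared_pathways.json").read_text())
    for direction, info in shared.items():
        print(f"  shared {direction} across contrasts: "
              f"{info['counts']['intersection']} sets")


if __name__ == "__main__":
    main()
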