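#!/usr/bin/env python
"""Score the cohort: CHEI diet score, 0-5 lifestyle score, GRS tertiles.

Reads results/cohort.csv, appends the lifestyle profile and the in-sample
genetic risk score, writes results/scored.csv, and prints the score and
group distributions.
"""

import argparse
from pathlib import Path

from genelife.cohort import read_cohort
from genelife.config import AnalysisConfig
from genelife.scoring import score_cohort

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.results / "cohort.csv")
    scored, model = score_cohort(cohort, AnalysisConfig(seed=args.seed))
    scored.to_csv(args.results / "scored.csv", index=False, float_format="%.10g")

    print("lifestyle score distribution (%):")
    print((scored["lifestyle_score"].value_counts(normalize=True).sort_index() * 100).round(2))
    print("lifestyle groups:", scored["lifestyle_group"].value_counts().to_dict())
    print("GRS groups:", scored["grs_group"].value_counts().to_dict())
    print(f"GRS mean {scored['grs'].mean():.3f}, sd {scored['grs'].std():.3f}")
    n_warn = len(model.meta.get("warnings", []))
    print(f"genotype-effect model: outcome={model.meta['outcome']}, {n_warn} warning(s)")
    print(f"wrote {args.results/'scored.csv'}")
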