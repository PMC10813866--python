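#!/usr/bin/env python
"""Cross-modal association: z-score, |rho| > 0.9 filter, Spearman, FDR, KS.

Consumes the simulated cohort's pathomics features (recomputed from the
seed if 02 has not been run) and radiomics table.  Reports per-scale
retained feature counts, cross-modal sign percentages, top correlated
pairs, per-endpoint correlation counts, and the KS comparison of the two
modalities' endpoint-correlation distributions.  Outputs under
results/association/.
"""

import argparse
import json
import warnings
from pathlib import Path

from radiopathomics.pipeline import RunConfig, run
from radiopathomics.synthetic import SyntheticCohortSpec


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-patients", type=int, default=36)
    ap.add_argument("--out", type=Path, default=Path("results/association"))
    args = ap.parse_args()

    spec = SyntheticCohortSpec(n_patients=args.n_patients, seed=args.seed)
    cfg = RunConfig(synthetic=spec, seed=args.seed, out_dir=str(args.out))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = run(cfg)

    print(f"association outputs -> {args.out}")
    print("  retained features after |rho| > 0.9 filter:",
          results["retained_counts"])
    signs = results["cross_correlation"].sign_counts
    for _, row in signs.iterrows():
        print(f"  scale {row['scale']}: {row['positive_pct']:.0f}% positive / "
              f"{row['negative_pct']:.0f}% negative cross-modal correlations "
              f"(rho range {row['rho_min']:.2f} to {row['rho_max']:.2f})")
    top = results["cross_correlation"].top_pairs
    print(f"  {len(top)} pairs with |rho| > 0.5"
          + (f"; strongest: {top.iloc[0].pathomics_feature} ~ "
             f"{top.iloc[0].radiomics_feature} (rho {top.iloc[0].correlation:.2f}, "
             f"scale {top.iloc[0].scale})" if len(top) else ""))
    print("  KS comparison of endpoint-correlation distributions "
          "(pathomics vs radiomics):")
    for ep, k in results["ks"].items():
        print(f"    {ep}: D = {k['statistic']:.3f}, p = {k['pvalue']:.3f}")


if __name__ == "__main__":
    main()
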