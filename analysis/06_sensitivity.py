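"""Input-perturbation sensitivity of the trained yield model.

Each scenario multiplies the targeted held-out features by (1 + u),
u ~ Uniform over the stated relative-error range, re-predicts with the
fixed model and averages the metrics over replicates; the model is never
retrained.
"""

import argparse
from pathlib import Path

import pandas as pd

from cropcwp.evaluate import Scenario, sensitivity
from cropcwp.synthgrid import read_world
from cropcwp.yield_model import (FilterRules, filter_yield_records,
                                 split_train_test, train_rf)

FEATS = ("cumET", "cumGPP", "cumTs", "meanLAI")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--world", type=Path, default=Path("results/world"))
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/sensitivity.csv"))
    ap.add_argument("--reps", type=int, default=30)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    world = read_world(args.world)
    table, _ = filter_yield_records(pd.read_csv(args.features),
                                    FilterRules.for_crop(world.config.crop))
    train, test = split_train_test(table, 0.8, seed=args.seed)
    bundle = train_rf(train, ("ET", "GPP", "Ts", "LAI"), seed=args.seed)

    scenarios = []
    for lo, hi, tag in ((0.0, 0.4, "+40%"), (-0.4, 0.0, "-40%"), (-0.4, 0.4, "±40%")):
        scenarios.append(Scenario(f"all4 {tag}", FEATS, lo, hi))
        scenarios.extend(Scenario(f"{f} {tag}", (f,), lo, hi) for f in FEATS)

    rep = sensitivity(bundle, test, test["yield_kg_ha"], scenarios,
                      reps=args.reps, seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    rep.table.to_csv(args.out, index=False)
    print(f"baseline held-out R2 {rep.baseline.r2_conventional:.3f}, "
          f"rRMSE {rep.baseline.rrmse_pct:.2f}% (n={rep.baseline.n})")
    print(rep.table[["scenario", "r2", "rrmse_pct", "delta_r2", "delta_rrmse_pct"]]
          .round(3).to_string(index=False))
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
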