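"""Build the county-year modelling table from the world's rasters.

Phenology-window aggregates of the four indicators (cumulative ET, GPP,
Ts; mean LAI), zonal soil texture means and the recorded county yields
are joined on (county, year) and written as ``results/features.csv``.
"""

import argparse
from pathlib import Path

from cropcwp.preprocess import (FEATURE_NAME, WINDOW_STATISTIC,
                                build_feature_table,
                                build_feature_table_multiyear, window_cumulate)
from cropcwp.synthgrid import read_world


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--world", type=Path, default=Path("results/world"))
    ap.add_argument("--out", type=Path, default=Path("results/features.csv"))
    args = ap.parse_args()

    world = read_world(args.world)
    tables = []
    for year in world.years:
        annual = {FEATURE_NAME[ind]: window_cumulate(
            world.stacks[ind][year], world.phenology[year],
            WINDOW_STATISTIC[ind], crop_mask=world.crop_mask[year])
            for ind in ("ET", "GPP", "Ts", "LAI")}
        tables.append(build_feature_table(annual, world.soil, world.county_map,
                                          world.crop_mask[year],
                                          world.county_yields, year))
    table = build_feature_table_multiyear(tables)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"feature table: {len(table)} county-year rows -> {args.out}")
    print(table[["cumET", "cumGPP", "cumTs", "meanLAI", "yield_kg_ha"]]
          .describe().loc[["mean", "std", "min", "max"]].round(1).to_string())


if __name__ == "__main__":
    main()
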