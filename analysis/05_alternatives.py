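"""Project the seven remedial alternatives and compare year-10 fish means.

Reproduces the screening pattern that drove remedy selection: No Action
leaves fish concentrations highest, natural recovery alone (status quo)
helps, sediment removal + seep capture (Alternative 3) gives the large drop,
and storm storage/treatment beyond that adds little.  Writes
results/alternatives.csv.
"""

from pathlib import Path

import pandas as pd

from streampcb.scenario_engine import ALTERNATIVES, run_projection
from streampcb.synthetic_data import SynthConfig, gen_site_fixture

SEED = 20240101


def main():
    site = gen_site_fixture(SynthConfig(seed=SEED))
    rows = []
    for alt_id, alt in ALTERNATIVES.items():
        proj = run_projection(site, alternative=alt_id, calibration="base",
                              years=10.0)
        row = {"alternative": alt_id, "name": alt.name}
        for (st, sp), v in proj.year10_fish.items():
            row[f"{st}:{sp}"] = v
        row["CBVP_water_ngL"] = proj.year10_water["CBVP"]
        rows.append(row)
        print(f"Alt {alt_id} ({alt.name}): CBVP creek chub year-10 "
              f"{row['CBVP:creek_chub']:.2f} mg/kg")
    df = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/alternatives.csv", index=False, float_format="%.4f")
    d23 = df.loc[1, "CBVP:creek_chub"] - df.loc[2, "CBVP:creek_chub"]
    d37 = df.loc[2, "CBVP:creek_chub"] - df.loc[6, "CBVP:creek_chub"]
    print(f"\nAlt2->Alt3 reduction: {d23:.2f} mg/kg; Alt3->Alt7: {d37:.2f} mg/kg"
          "\n=> additional storm treatment provides little incremental benefit.")


if __name__ == "__main__":
    main()
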