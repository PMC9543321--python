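"""Diagnostic source apportionment by superposition.

Runs each PCB source alone (untreated bypass at the weir, treated effluent,
NSB seeps, and the initial sediment-bed inventory) and reports each source's
share of the time-averaged water column and active-bed exposure at the three
stations.  Because every process is first-order, the single-source runs sum
to the combined run to machine precision.  Writes results/apportionment.csv.
"""

from pathlib import Path

import pandas as pd

from streampcb import fate_transport
from streampcb.scenario_engine import build_run
from streampcb.synthetic_data import SynthConfig, gen_site_fixture

SEED = 20240101


def main():
    site = gen_site_fixture(SynthConfig(seed=SEED))
    run = build_run(site)
    app = fate_transport.apportion_sources(
        run["network"], run["hydro"], run["loads"], run["params"],
        run["bed0"], flows_df=run["flows"], tss_df=run["tss"], n_days=365)
    net = run["network"]
    rows = []
    for st in site.stations:
        cell = net.cell_of_mile(st.mile)
        for sid in app["fraction_water"]:
            rows.append({
                "station": st.name,
                "source": sid,
                "water_fraction": float(app["fraction_water"][sid][cell]),
                "bed_fraction": float(app["fraction_bed"][sid][cell]),
            })
    df = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/apportionment.csv", index=False, float_format="%.4f")
    print(df.pivot(index="source", columns="station", values="water_fraction")
          .round(3).to_string())
    print("\nStorm-dominated upstream loads flow largely through the system;"
          "\nthe bed and the steady seep loads matter most where fish feed.")


if __name__ == "__main__":
    main()
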