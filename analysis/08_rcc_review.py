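"""Five-year-review emulation: Remedy Confirmation Clause decisions.

Samples synthetic fish composites (lognormal individuals, composites of
three) around the year-10 projected means for the selected remedy and runs
the three-outcome compliance test against each station's risk-based target
(2.3 mg/kg whole body at CBVP, 0.9 at RCVP, 0.2 fillet at RC43), plus the
decline test against pre-remedy samples.  Writes results/rcc_decisions.json.
"""

import json
from pathlib import Path

import numpy as np

from streampcb.rcc_stats import decline_test, rcc_test
from streampcb.scenario_engine import run_projection
from streampcb.synthetic_data import SynthConfig, gen_fish_samples, gen_site_fixture

SEED = 20240101
N_FISH = {"CBVP": 60, "RCVP": 60, "RC43": 54}


def main():
    cfg = SynthConfig(seed=SEED)
    site = gen_site_fixture(cfg)
    pre = run_projection(site, 2, "base", years=1.0)
    post = run_projection(site, 3, "base", years=10.0)
    out = {}
    for i, ((station, species), mean) in enumerate(sorted(post.year10_fish.items())):
        if station not in site.rcc.targets:
            continue
        basis = site.rcc.targets[station][1]
        comp = gen_fish_samples(mean, cfg.fish_cv, N_FISH[station], 3,
                                seed=SEED + i, station=station,
                                species=species, basis=basis)
        vals = np.array([c.concentration for c in comp])
        d = rcc_test(vals, site.rcc, station)
        pre_mean = pre.year10_fish[(station, species)]
        pre_comp = gen_fish_samples(pre_mean, cfg.fish_cv, 30, 3,
                                    seed=SEED + 50 + i, station=station,
                                    species=species, basis=basis)
        dec = decline_test([c.concentration for c in pre_comp], vals)
        out[f"{station}:{species}"] = {
            "outcome": d.outcome, "mean": d.mean, "sem": d.sem,
            "target": d.target, "t": d.t_statistic, "p_below": d.p_below,
            "n_composites": d.n, "n_fish": N_FISH[station],
            "decline_p": dec["p"], "decline_significant": dec["significant"],
        }
    Path("results").mkdir(exist_ok=True)
    Path("results/rcc_decisions.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
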