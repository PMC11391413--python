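#!/usr/bin/env python
"""Bootstrap confidence intervals and model comparison on the S4 and EGFR data.

Two questions, mirroring the study workflow:

1. Do the two-site independent and cooperative models differ on S4-design
   data?  (They should not: the data are generated with independent sites,
   and even on real data the residuals were indistinguishable.)
2. Can conformational selection / induced fit be distinguished from plain
   single-site binding on the EGFR-like titration?  (The apparent-K_D
   identities make all three fit identically; only K_D,app is identified.)

Writes results/model_comparison_{S4,EGFR}.csv and results/bootstrap_S4.json.
"""

import json
from pathlib import Path

from cspfit import FitSpec, bootstrap, build_csp_profile, compare_models, fit, select_residues
from cspfit.io import read_titration

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def load(name):
    series = read_titration(
        ROOT / "datasets" / f"{name}_shifts.csv",
        ROOT / "datasets" / f"{name}_schedule.csv",
    )
    return series, select_residues(build_csp_profile(series))


def main() -> None:
    # --- S4: independent vs cooperative, with a full 1000-replicate bootstrap
    series, profile = load("S4")
    indep = fit(profile, series.schedule, FitSpec(model="two_site_independent"))
    bs = bootstrap(indep, n=1000, coverage=0.95, seed=SEED)
    payload = {
        "params": indep.params,
        "intervals": {k: list(v) for k, v in bs.intervals.items()},
        "ranks": list(bs.ranks),
        "n_replicates": bs.n_replicates,
    }
    (ROOT / "bootstrap_S4.json").write_text(json.dumps(payload, indent=2))
    print("S4 two-site independent fit with 95% bootstrap CIs "
          f"(ranks {bs.ranks[0]}/{bs.ranks[1]} of {bs.n_replicates}):")
    for k, v in indep.params.items():
        lo, hi = bs.intervals[k]
        print(f"  {k} = {v:.1f} uM  [{lo:.1f}, {hi:.1f}]")

    coop = fit(profile, series.schedule, FitSpec(model="two_site_cooperative"))
    bc = bootstrap(coop, n=200, seed=SEED + 1)
    comp = compare_models([(indep, bs), (coop, bc)])
    comp.table.to_csv(ROOT / "model_comparison_S4.csv", index=False)
    print("\nS4 model comparison (residual-SD bootstrap overlap):")
    print(comp.table[["model", "rss", "residual_sd", "n_params", "verdict"]]
          .to_string(index=False))

    # --- EGFR: single site vs conformational selection vs induced fit
    series, profile = load("EGFR")
    fits = []
    for model in ("single_site", "conformational_selection", "induced_fit"):
        fr = fit(profile, series.schedule, FitSpec(model=model))
        fits.append((fr, bootstrap(fr, n=200, seed=SEED + 2)))
    comp = compare_models(fits)
    comp.table.to_csv(ROOT / "model_comparison_EGFR.csv", index=False)
    print("\nEGFR-like model comparison:")
    print(comp.table[["model", "rss", "residual_sd", "n_params", "verdict"]]
          .to_string(index=False))
    print("\nThe two-state models match the single-site fit through their "
          "apparent-K_D identities; parsimony selects the single-site model, "
          "as in the original workflow.")


if __name__ == "__main__":
    main()
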