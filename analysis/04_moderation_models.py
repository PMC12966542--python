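"""Moderated mixed models: does hearing loss amplify the within-person
effect of auditory demand on effort, affect and fatigue?

Fits the person-level PTA -> mean-demand regressions and the full
outcome x demand family of REML mixed models (demand decomposed into
within/between components, PTA z-scored, demand(within) x PTA
interaction, covariates in original units, participant random
intercept).
"""

import argparse
from pathlib import Path

import pandas as pd

from audema import ModelSpec, fit_between_regression, fit_moderation_model

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "models")
    args = ap.parse_args()

    scored = pd.read_csv(args.study / "ema_scored.csv")
    participants = pd.read_csv(args.study / "participants.csv")
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for demand in ("environmental", "social", "subjective"):
        reg = fit_between_regression(participants, scored, demand)
        rows.append({"demand": demand, "slope_per_db": reg.slope,
                     "se": reg.se, "t": reg.t, "p": reg.p,
                     "r2": reg.r_squared})
        print(f"PTA -> mean {demand} demand: beta = {reg.slope:.4f}/dB "
              f"(SE {reg.se:.4f}), R^2 = {reg.r_squared:.3f}, p = {reg.p:.3g}")
    pd.DataFrame(rows).to_csv(args.out / "pta_demand_regressions.csv",
                              index=False)

    tables = []
    for outcome in ("effort", "affect", "fatigue"):
        for demand in ("environmental", "social", "subjective"):
            res = fit_moderation_model(scored, ModelSpec(outcome, demand))
            tab = res.coefficients.reset_index(names="term")
            tab.insert(0, "outcome", outcome)
            tab.insert(1, "demand", demand)
            tables.append(tab)
            wp = tab[tab["term"].str.endswith("_wp")].iloc[0]
            inter = tab[tab["term"].str.contains(":pta_z")].iloc[0]
            print(f"{outcome} ~ {demand}: within beta {wp['beta']:.2f} "
                  f"(p={wp['p']:.2g}), x PTA {inter['beta']:.2f} "
                  f"(p={inter['p']:.2g}), n={res.n_obs}")
    pd.concat(tables, ignore_index=True).to_csv(
        args.out / "moderation_models.csv", index=False)
    print(f"coefficient tables -> {args.out}")


if __name__ == "__main__":
    main()
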