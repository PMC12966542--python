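"""Score the raw EMA items into the derived demand and affect variables.

Reduces the listening-situation and who-with multi-selects to
environmental (0-3) and social (0-2) demand ranks, forms the difficulty
x importance product and its tertile-based subjective rank (0-2), and
averages the mood sliders.  Writes the scored table plus the per-person
summary that mirrors a descriptive overview of the study measures.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from audema import add_decomposition, score_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    args = ap.parse_args()

    ema = pd.read_csv(args.study / "ema_long.csv")
    participants = pd.read_csv(args.study / "participants.csv")
    scored, cuts = score_table(ema)
    scored = add_decomposition(scored.merge(participants,
                                            on="participant_id"))
    scored.to_csv(args.study / "ema_scored.csv", index=False)
    (args.study / "tertile_cutpoints.json").write_text(json.dumps(
        {"lower": cuts.lower, "upper": cuts.upper,
         "source_n": cuts.source_n}, indent=2))

    answered = scored[scored["answered"]]
    person_means = answered.groupby("participant_id")[
        ["fatigue", "effort", "importance", "difficulty", "affect",
         "positive_affect", "negative_affect", "environmental_demand",
         "social_demand", "subjective_demand"]].mean()
    summary = person_means.agg(["mean", "std", "median", "min", "max"]).T
    summary.round(2).to_csv(args.study / "ema_summary.csv")
    print(f"tertile cutpoints: lower {cuts.lower:g}, upper {cuts.upper:g} "
          f"(n={cuts.source_n})")
    print("per-participant averages of the derived measures:")
    print(summary.round(2).to_string())


if __name__ == "__main__":
    main()
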