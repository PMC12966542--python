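"""Simulate the emulated EMA study and write its raw tables.

Generates the default study conditions — 130 participants, 5.5 days x 7
daytime prompts with +/-15-min jitter, day-specific compliance declining
from 83% to 67%, hearing loss (PTA) centred at 27.4 dB HL (SD 20.1) —
and writes the participant roster and the EMA long table under
results/study/.
"""

import argparse
from pathlib import Path

from audema import TruthConfig, simulate_study
from audema.pipeline import EMA_COLUMNS, PARTICIPANT_COLUMNS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20260925)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "study")
    args = ap.parse_args()

    cfg = TruthConfig(seed=args.seed)
    study = simulate_study(cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    study.participants[PARTICIPANT_COLUMNS].to_csv(
        args.out / "participants.csv", index=False)
    study.ema[EMA_COLUMNS].to_csv(args.out / "ema_long.csv", index=False)
    cfg.to_yaml(args.out / "config.yaml")

    answered = study.ema["answered"]
    print(f"simulated {len(study.participants)} participants, "
          f"{len(study.ema)} prompts, {answered.mean():.1%} answered")
    print(f"PTA: mean {study.participants['pta'].mean():.1f} dB HL, "
          f"SD {study.participants['pta'].std(ddof=1):.1f}")
    print("clip rates:", {k: f"{v:.1%}" for k, v in study.clip_rates.items()})
    print(f"wrote tables to {args.out}")


if __name__ == "__main__":
    main()
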