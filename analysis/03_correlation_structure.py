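"""Between- vs within-subject correlation structure of the EMA measures.

Computes (a) Pearson correlations of per-participant medians across
participants, (b) the elementwise median of per-participant correlation
matrices, (c) the variance-weighted Fisher-z pooled within-subject
matrix, and (d) cell-by-cell Fisher z-contrasts between the between- and
pooled-within matrices at alpha = .007.
"""

import argparse
from pathlib import Path

import pandas as pd

from audema import (between_subject_matrix, contrast_table,
                    within_subject_matrices)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "correlations")
    args = ap.parse_args()

    scored = pd.read_csv(args.study / "ema_scored.csv")
    args.out.mkdir(parents=True, exist_ok=True)

    between = between_subject_matrix(scored)
    within = within_subject_matrices(scored)
    contrasts = contrast_table(scored)

    between.to_csv(args.out / "between_subject.csv")
    within.median.to_csv(args.out / "within_subject_median.csv")
    within.pooled.to_csv(args.out / "within_subject_pooled.csv")
    contrasts.to_csv(args.out / "contrasts.csv", index=False)

    sig = contrasts[contrasts["significant"]]
    print(f"{len(contrasts)} variable pairs contrasted at alpha=.007; "
          f"{len(sig)} differ significantly between levels:")
    if len(sig):
        print(sig[["var1", "var2", "r_between", "r_within_pooled",
                   "z_stat"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
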