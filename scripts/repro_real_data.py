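"""Optional recipe: rebuild the threshold and metric tables from the public data.

The yeast-display peptide libraries for the 2B4, 226 and 5cc7 TCRs and the
trained pairwise energy matrices / structure-derived contact maps are public:

    https://github.com/XingchengLin/RACER/tree/main/raw_data
    https://github.com/TAMUGeorgeGroup/Feature_Selection_TCR-Specific_Interaction.git

This script does not download anything. Convert each TCR's inputs into the
package's plain-text formats and lay them out as

    <data_dir>/<tcr_name>/library.csv        # id,sequence,reads
    <data_dir>/<tcr_name>/energy_matrix.tsv  # 21x21 grid, canonical order
    <data_dir>/<tcr_name>/contact_map.tsv    # tcr_index  tcr_residue  peptide_position

then run

    python scripts/repro_real_data.py --data-dir <data_dir> --out <out_dir>

to emit `table_thresholds.csv` (read thresholds and balanced class sizes per
TCR) and `table_metrics.csv` (the per-category evaluation panel). Output
values depend entirely on the supplied data; only the table layout is fixed.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

THRESHOLD_COLUMNS = ["TCR", "Threshold", "Peptides (0/1)"]
METRIC_COLUMNS = ["TCR Data", "Feature Category", "Accuracy", "Recall", "F1 Score", "MCC", "AUC"]


def build_threshold_table(outcomes: dict[str, "object"]) -> pd.DataFrame:
    """Per-TCR read thresholds and balanced class sizes (one row per TCR)."""
    rows = []
    for tcr, outcome in outcomes.items():
        n1 = sum(1 for r in outcome.balanced if r.label == 1)
        n0 = sum(1 for r in outcome.balanced if r.label == 0)
        rows.append(
            {
                "TCR": tcr,
                "Threshold": outcome.threshold.read_threshold,
                "Peptides (0/1)": f"{n0}/{n1}",
            }
        )
    return pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)


def build_metrics_table(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean metric panel per (TCR, feature category), Table-2-style layout."""
    rows = []
    for tcr, report in reports.items():
        means = report[report["repeat"] == "mean"]
        for _, row in means.iterrows():
            rows.append(
                {
                    "TCR Data": tcr,
                    "Feature Category": row["category"],
                    "Accuracy": round(float(row["accuracy"]), 2),
                    "Recall": round(float(row["recall"]), 2),
                    "F1 Score": round(float(row["f1"]), 2),
                    "MCC": round(float(row["mcc"]), 2),
                    "AUC": round(float(row["auc"]), 2),
                }
            )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def main() -> None:
    from tcrmotif import evaluate as ev
    from tcrmotif import io as tio
    from tcrmotif import pipeline as pl

    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, required=True)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-top", type=int, default=500)
    ap.add_argument("--n-strong-train", type=int, default=140)
    ap.add_argument("--categories", default="descriptor,tripeptide,ngram")
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    outcomes: dict[str, pl.LabelingOutcome] = {}
    reports: dict[str, pd.DataFrame] = {}
    for tcr_dir in sorted(p for p in args.data_dir.iterdir() if p.is_dir()):
        records = tio.read_peptides(tcr_dir / "library.csv", "csv")
        J = tio.read_energy_matrix(tcr_dir / "energy_matrix.tsv")
        cmap = tio.read_contact_map(tcr_dir / "contact_map.tsv")
        outcome = pl.label_library(
            records, cmap, J,
            n_top=args.n_top, n_strong_train=args.n_strong_train, seed=args.seed,
        )
        outcomes[tcr_dir.name] = outcome
        reports[tcr_dir.name] = ev.run_evaluation(
            outcome.balanced,
            categories=tuple(args.categories.split(",")),
            split_spec=ev.SplitSpec(n_repeats=10, seed=args.seed),
        )
    build_threshold_table(outcomes).to_csv(args.out / "table_thresholds.csv", index=False)
    build_metrics_table(reports).to_csv(args.out / "table_metrics.csv", index=False)
    print(f"wrote table_thresholds.csv and table_metrics.csv to {args.out}")


if __name__ == "__main__":
    main()
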