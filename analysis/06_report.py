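"""Aggregate the analysis outputs into one summary report.

Collects the tables written by the numbered analysis steps (run them
first) into results/summary.json, mirroring the subject flow from
simulation through modeling.
"""

import json
from pathlib import Path

import pandas as pd

from nmrmet import __version__

RESULTS = Path("results")


def main() -> None:
    summary: dict = {"version": __version__}

    cohort_path = RESULTS / "simulation" / "cohort.tsv"
    if cohort_path.exists():
        cohort = pd.read_csv(cohort_path, sep="\t")
        summary["cohort"] = {
            "n_subjects": len(cohort),
            "lifetime_cases": int(cohort.lifetime.sum()),
            "active_cases": int(cohort.active.sum()),
            "families": int(cohort.family_id.nunique()),
        }
    qc_path = RESULTS / "preprocess" / "qc_flags.tsv"
    if qc_path.exists():
        qc = pd.read_csv(qc_path, sep="\t")
        summary["spectral_batch"] = {
            "n_spectra": len(qc),
            "qc_failed": int((~qc.passed).sum()),
        }
    acc_path = RESULTS / "quantify" / "accuracy_per_signal.tsv"
    if acc_path.exists():
        acc = pd.read_csv(acc_path, sep="\t", index_col=0)
        summary["quantification"] = {
            "n_signals": len(acc),
            "median_corr_with_truth": float(acc.iloc[:, 0].median()),
        }
    reports_path = RESULTS / "model" / "profile_reports.json"
    if reports_path.exists():
        summary["profiles"] = json.loads(reports_path.read_text())

    out = RESULTS / "summary.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2)[:2000])


if __name__ == "__main__":
    main()
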