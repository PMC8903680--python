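"""Peak quantification of the preprocessed batch.

Pseudo-Voigt deconvolution of every JRES projection, median +- 3*IQR
discard, PLS rescue of failed cells, and metabolite assignment against
the shipped chemical-shift reference.  Scores fitted areas against the
generator's ground truth.  Writes under results/quantify/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nmrmet.config import RunConfig
from nmrmet.io import write_signal_table
from nmrmet.pipeline import preprocess_stage, quantify_stage, simulate_stage

SEED = 7
OUT = Path("results/quantify")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=SEED)
    cfg.cohort.n_subjects = 40
    cfg.spectra.n_corrupted = 2
    _, truth, _, spectra, projections = simulate_stage(cfg)
    _, warped, nonwarped, _, _ = preprocess_stage(cfg, spectra, projections)

    table = quantify_stage(cfg, warped, nonwarped, truth.catalog)
    write_signal_table(table, OUT / "signals")

    true_areas = truth.true_signal_areas().loc[table.values.index]
    cors = pd.Series(
        {s: table.values[s].corr(true_areas[s]) for s in table.signal_ids}
    )
    cors.rename("corr_with_truth").to_csv(OUT / "accuracy_per_signal.tsv", sep="\t")
    prov = table.provenance.stack().value_counts()
    print(f"quantified {len(table.signal_ids)} signals in "
          f"{len(table.sample_ids)} samples; provenance: {prov.to_dict()}")
    print(f"per-signal correlation with ground truth: median "
          f"{cors.median():.3f}, 10th pct {cors.quantile(0.1):.3f}")
    assigned = (table.signals.assignment != "unknown").sum()
    print(f"{assigned} signals assigned to reference metabolites "
          f"({(table.signals.assignment == 'Unknown').sum()} placeholder rows)")


if __name__ == "__main__":
    main()
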