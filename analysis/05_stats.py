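#!/usr/bin/env python
"""Phase-resolved group statistics over the combined feature table.

Concatenates the trajectory and IMF feature tables and runs the full battery
(ANOVA + Tukey-Kramer for trajectory sources; MANOVA gates + Holm-corrected
ANOVAs + post hoc for IMF sources).
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, RESULTS, ensure

from emgtf import io as eio
from emgtf import stats as estats


def main() -> None:
    ensure(RESULTS)
    tables = [eio.read_feature_table(RESULTS / "features_trajectories.csv")]
    imf_path = RESULTS / "features_imf.csv"
    if imf_path.exists():
        tables.append(eio.read_feature_table(imf_path))
    table = pd.concat(tables, ignore_index=True)
    summary, pairwise = estats.run_stat_battery(
        table, alpha=CONFIG.alpha, correction=CONFIG.correction, unit=CONFIG.unit
    )
    summary.to_csv(RESULTS / "stats_summary.csv", index=False, float_format=eio.FLOAT_FMT)
    pairwise.to_csv(RESULTS / "stats_pairwise.csv", index=False, float_format=eio.FLOAT_FMT)
    gates = summary[summary.test == "manova"]
    print(f"{len(summary)} tests ({int(gates.gate.sum())}/{len(gates)} MANOVA gates open), "
          f"{len(pairwise)} pairwise rows")


if __name__ == "__main__":
    main()
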