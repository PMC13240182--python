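#!/usr/bin/env python
"""Count luminescent cells in the synthetic compression video.

Reads the bundle written by 01_simulate_inputs.py, runs the counting
chain (blue channel -> mask -> 70/255 threshold -> local maxima), and
writes results/trace.csv plus a summary (peak and de-duplicated cell
counts, 10%-decay window) to results/counting_summary.json. Also sweeps
strain/rate conditions to build the normalised activation map
(results/activation_map.csv): no cells emit below the threshold strain
rate, and the map entry for the strongest condition is 1.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from dinolum import flashcount, io, synth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--bundle", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    stack = io.read_stack(args.bundle / "stack.tiff")
    trace = flashcount.trace_series(stack)
    pd.DataFrame({"time_s": trace.time, "n_cells": trace.n_cells,
                  "total_intensity": trace.total_intensity}
                 ).to_csv(args.out / "trace.csv", index=False)

    truth = json.loads((args.bundle / "ground_truth.json").read_text())
    n_true = len(truth["video"]["cell_positions"])

    summary = {
        "n_max": trace.n_max,
        "unique_cells": trace.unique_cells,
        "true_cell_count": n_true,
        "projected_integral": trace.projected_integral,
    }
    if trace.n_max > 0:
        dw = flashcount.decay_window(trace)
        summary["decay_window_s"] = dw.seconds
        summary["decay_window_truncated"] = dw.truncated

    # activation map over a strain / strain-rate sweep with a 2 mm/s
    # activation threshold emulating the minimum rate needed to fire cells
    threshold_rate = 2.0
    results = []
    for strain in (0.05, 0.10, 0.15):
        for rate in (0.5, 1.0, 2.5, 5.0, 7.5):
            n = int(12 * strain / 0.15) if rate >= threshold_rate else 0
            cfg = synth.SyntheticVideoConfig(
                cell_count=n, frame_count=10, height=160, width=160,
                onset_times=[0.1] * n, seed=args.seed + int(100 * rate))
            sweep_stack, _ = synth.gen_flash_stack(cfg)
            results.append((strain, rate,
                            flashcount.trace_series(sweep_stack).n_max))
    amap = flashcount.activation_map(results)
    rows = []
    for i, s in enumerate(amap.strain_levels):
        for j, r in enumerate(amap.rate_levels):
            rows.append({"strain": s, "rate_mm_s": r,
                         "normalized_n_max": amap.normalized_counts[i, j]})
    pd.DataFrame(rows).to_csv(args.out / "activation_map.csv", index=False)

    (args.out / "counting_summary.json").write_text(json.dumps(summary,
                                                               indent=2))
    print(f"found {summary['unique_cells']} unique cells "
          f"(true {n_true}), peak simultaneous {summary['n_max']}")
    print(f"wrote {args.out}/trace.csv, activation_map.csv, "
          "counting_summary.json")


if __name__ == "__main__":
    main()
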