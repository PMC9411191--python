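"""Quantitative context comparison: paired t-tests across networks.

Aggregates the per-trial metrics (posterior response and prior sigma of the
sensory areas, per 100-step context phase) to one value per (network,
context), then runs two-tailed paired t-tests with the network as the
pairing unit. Also summarizes the free-energy state shift around the
context switch via the 20-step moving average.

    python analysis/04_context_statistics.py --trials results/trials \
        --out results/stats.json
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pvrnn_attenuation import context_comparison, moving_average
from pvrnn_attenuation.datagen import SELF_PRODUCED, EXTERNALLY_PRODUCED


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", default="results/trials")
    ap.add_argument("--out", default="results/stats.json")
    args = ap.parse_args()

    trials = Path(args.trials)
    metrics = pd.read_csv(trials / "trial_metrics.csv")
    tests = context_comparison(metrics)

    report = {}
    for name, res in tests.items():
        report[name] = {
            "t": res.t_statistic, "df": res.degrees_of_freedom,
            "p": res.p_value, "mean_difference_self_minus_external":
                res.mean_difference,
        }
        print(f"{name}: t({res.degrees_of_freedom}) = {res.t_statistic:.3f},"
              f" p = {res.p_value:.4f} (self - external = "
              f"{res.mean_difference:+.4f})")

    log = pd.read_csv(trials / "trial_log.csv")
    fe = (log.groupby("step")["free_energy_window"].mean())
    ma = moving_average(fe.to_numpy(), window=20)
    switch = int((log.context == SELF_PRODUCED).sum() / log.network.nunique()
                 / log.trial.nunique())
    report["free_energy_moving_average"] = {
        "pre_switch_mean": float(ma[:switch].mean()),
        "post_switch_mean": float(ma[switch:].mean()),
        "post_switch_burst": float(ma[switch:switch + 20].mean()),
    }
    print("free-energy state shift (20-step moving average): "
          f"pre {report['free_energy_moving_average']['pre_switch_mean']:.4f}"
          f" -> post {report['free_energy_moving_average']['post_switch_mean']:.4f}")

    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    Path(args.out).write_text(json.dumps(report, indent=2))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
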