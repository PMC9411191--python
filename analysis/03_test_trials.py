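"""Test phase: closed-loop trials with a mid-trial context switch.

Loads a trained checkpoint, runs J held-out test trials per network (steps
1..switch self-produced, then externally produced from the test
exteroception), with online sliding-window posterior inference and PID
action generation. Writes the per-step trial log and the per-trial metric
table.

    python analysis/03_test_trials.py --data results/data \
        --ckpt results/train/checkpoint.npz --out results/trials
"""

import argparse
import time
from pathlib import Path

import numpy as np
import pandas as pd

from pvrnn_attenuation import TrialConfig, load_dataset, run_trial
from pvrnn_attenuation.analysis import trial_metrics_table
from pvrnn_attenuation.checkpoint import load_checkpoint
from pvrnn_attenuation.datagen import SELF_PRODUCED


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--ckpt", default="results/train/checkpoint.npz")
    ap.add_argument("--out", default="results/trials")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--trials", type=int, default=8)
    ap.add_argument("--steps", type=int, default=200)
    ap.add_argument("--switch", type=int, default=100)
    ap.add_argument("--window", type=int, default=10)
    ap.add_argument("--updates", type=int, default=50)
    ap.add_argument("--alpha", type=float, default=0.09)
    args = ap.parse_args()

    self_ds, ext_ds, test_extero = load_dataset(args.data)
    params, adaptive, net_cfg, meta = load_checkpoint(args.ckpt)
    dtype = params["w_dd_A"].dtype
    test = np.stack(test_extero[:args.trials]).astype(dtype)
    cfg = TrialConfig(total_steps=args.steps, switch_step=args.switch,
                      window=args.window, updates_per_step=args.updates,
                      learning_rate=args.alpha, seed=args.seed)
    contexts = np.array([s.context for s in self_ds.sequences + ext_ds.sequences])
    self_mask = contexts == SELF_PRODUCED

    t0 = time.time()
    log = run_trial(params, adaptive, self_mask, test, net_cfg, cfg)
    print(f"ran {params['w_dd_A'].shape[0]} networks x {test.shape[0]} "
          f"trials in {time.time() - t0:.0f} s")

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    metrics = trial_metrics_table(log, cfg)
    metrics.to_csv(out / "trial_metrics.csv", index=False)
    _step_table(log).to_csv(out / "trial_log.csv", index=False)
    print(metrics.groupby("context")[
        ["posterior_response", "prior_sigma", "free_energy"]].mean())


def _step_table(log) -> pd.DataFrame:
    """Long-format per-step trace of the quantities the figures use."""
    T, N, J = log.f_t.shape
    rows = []
    for n in range(N):
        for j in range(J):
            df = pd.DataFrame({
                "step": np.arange(1, T + 1), "network": n, "trial": j,
                "context": log.contexts,
                "free_energy": log.f_t[:, n, j],
                "free_energy_window": log.f_window[:, n, j],
                "mu_q_exec": log.exec_mu_online[:, n, j, 0],
                "sigma_p_extero": log.sg_p["E"][:, n, j, 0],
                "sigma_p_proprio": log.sg_p["P"][:, n, j, 0],
                "obj_x": log.x["E"][:, n, j, 0],
                "obj_y": log.x["E"][:, n, j, 1],
                "hand_error_extero": np.linalg.norm(
                    log.x["E"][:, n, j] - log.xhat["E"][:, n, j], axis=-1),
            })
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


if __name__ == "__main__":
    main()
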