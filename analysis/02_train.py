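"""Learning phase: train an ensemble of networks on the two-context dataset.

Jointly optimizes synaptic weights and per-sequence adaptive posterior
variables by free-energy minimization (full-batch Adam), tracking the
developmental metrics: sensory-level posterior response and prior sigma per
context. Writes a checkpoint and the learning curves.

    python analysis/02_train.py --data results/data --out results/train \
        --seed 0 --networks 10 --epochs 20000

The headline simulation uses 200000 epochs; reduced budgets already show
the attenuation direction (see docs/methods.md).
"""

import argparse
import time
from pathlib import Path

import numpy as np

from pvrnn_attenuation import (NetworkConfig, TrainingConfig, load_dataset,
                               SELF_PRODUCED, EXTERNALLY_PRODUCED)
from pvrnn_attenuation.checkpoint import save_checkpoint
from pvrnn_attenuation.training import (init_adaptive, init_parameters,
                                        learning_metrics, make_training_data,
                                        train)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/train")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--networks", type=int, default=10)
    ap.add_argument("--epochs", type=int, default=20_000)
    ap.add_argument("--log-every", type=int, default=200)
    ap.add_argument("--float64", action="store_true",
                    help="train in float64 (default float32)")
    ap.add_argument("--meta-priors", type=float, nargs=3,
                    default=(0.005, 0.005, 0.005), metavar=("W1", "W2", "W3"))
    args = ap.parse_args()
    dtype = np.float64 if args.float64 else np.float32

    self_ds, ext_ds, _ = load_dataset(args.data)
    data = make_training_data(self_ds, ext_ds, dtype)
    net_cfg = NetworkConfig(meta_priors=tuple(args.meta_priors))
    params = init_parameters(net_cfg, args.networks, args.seed, dtype=dtype)
    adaptive = init_adaptive(net_cfg, args.networks, data.n_sequences,
                             data.T, dtype=dtype)
    t_cfg = TrainingConfig(epochs=args.epochs, seed=args.seed,
                           metric_logging_interval=args.log_every)

    t0 = time.time()
    curves = train(data, params, adaptive, t_cfg, net_cfg)
    elapsed = time.time() - t0

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    curves.to_csv(out / "learning_curves.csv", index=False)
    ckpt = save_checkpoint(out / "checkpoint.npz", params, adaptive, net_cfg,
                           meta={"seed": args.seed, "epochs": args.epochs})

    lm = learning_metrics(params, adaptive, data, net_cfg)
    lm.to_csv(out / "final_metrics.csv", index=False)
    print(f"trained {args.networks} networks x {args.epochs} epochs "
          f"in {elapsed / 60:.1f} min -> {ckpt}")
    for metric in ("posterior_response", "prior_sigma", "free_energy"):
        s = lm[lm.context == SELF_PRODUCED][metric].mean()
        e = lm[lm.context == EXTERNALLY_PRODUCED][metric].mean()
        print(f"  {metric}: self={s:.4f}  external={e:.4f}  "
              f"(attenuation direction: {'yes' if s < e else 'no'})")


if __name__ == "__main__":
    main()
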