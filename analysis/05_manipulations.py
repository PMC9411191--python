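"""Architecture lesions and meta-prior manipulations.

Re-runs the learning phase under configurable manipulations and compares
the developmental attenuation effect (external minus self, for the
sensory-level posterior response and prior sigma) against the baseline:

* lesions: reduced association-latent dimension, or no executive latent;
* meta-prior sweeps: per-level overrides of W = (W1, W2, W3).

    python analysis/05_manipulations.py --data results/data --seed 0 \
        --epochs 5000 --networks 5 --out results/manipulations.csv
"""

import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from pvrnn_attenuation import (NetworkConfig, TrainingConfig, load_dataset,
                               lesion_config, meta_prior_config,
                               SELF_PRODUCED, EXTERNALLY_PRODUCED)
from pvrnn_attenuation.training import (init_adaptive, init_parameters,
                                        learning_metrics, make_training_data,
                                        train)


def variants(grid):
    base = NetworkConfig()
    yield "baseline", base
    yield "lesion_no_executive", lesion_config(base, executive_latents=0)
    yield "lesion_association_1", lesion_config(base, association_latents=1)
    for level in range(3):
        for w in grid:
            if w == base.meta_priors[level]:
                continue
            W = list(base.meta_priors)
            W[level] = w
            yield f"meta_prior_W{level + 1}_{w:g}", meta_prior_config(base, tuple(W))


def attenuation_effect(lm: pd.DataFrame) -> pd.DataFrame:
    wide = lm.pivot(index="network", columns="context")
    out = {}
    for metric in ("posterior_response", "prior_sigma"):
        out[metric + "_effect"] = (wide[(metric, EXTERNALLY_PRODUCED)]
                                   - wide[(metric, SELF_PRODUCED)])
    return pd.DataFrame(out)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/manipulations.csv")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--epochs", type=int, default=5000)
    ap.add_argument("--networks", type=int, default=5)
    ap.add_argument("--grid", type=float, nargs="+",
                    default=[0.0005, 0.005, 0.05])
    args = ap.parse_args()

    self_ds, ext_ds, _ = load_dataset(args.data)
    rows = []
    for name, net_cfg in variants(args.grid):
        data = make_training_data(self_ds, ext_ds, np.float32)
        params = init_parameters(net_cfg, args.networks, args.seed,
                                 dtype=np.float32)
        adaptive = init_adaptive(net_cfg, args.networks, data.n_sequences,
                                 data.T, dtype=np.float32)
        t_cfg = TrainingConfig(epochs=args.epochs, seed=args.seed,
                               metric_logging_interval=args.epochs)
        train(data, params, adaptive, t_cfg, net_cfg)
        eff = attenuation_effect(learning_metrics(params, adaptive, data,
                                                  net_cfg))
        for n, r in eff.iterrows():
            rows.append({"variant": name, "network": n, **r.to_dict()})
        print(f"{name}: posterior-response effect "
              f"{eff.posterior_response_effect.mean():+.5f}, prior-sigma "
              f"effect {eff.prior_sigma_effect.mean():+.5f}")

    df = pd.DataFrame(rows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
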