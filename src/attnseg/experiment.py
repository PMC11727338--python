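"""End-to-end experiment driver: generate -> split -> train -> evaluate,
optionally repeated over seeds with mean/SD/CI aggregation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as M
from .config import RunConfig, config_to_dict
from .nn.model import AttentionUNet, NetworkCfg
from .phantom import generate_dataset
from .training import LoggedDataset, TrainCfg, evaluate_run, patient_split, train

import dataclasses


def run_single(cfg: RunConfig, seed: int) -> dict:
    """One full train/evaluate cycle with every RNG source re-seeded to ``seed``.

    Returns the evaluation report plus the training history and the split.
    """
    data_cfg = dataclasses.replace(cfg.data, seed=seed)
    spec = data_cfg.to_spec()
    pairs, _ = generate_dataset(spec, data_cfg.n_patients, data_cfg.slices_per_patient)
    dataset = LoggedDataset(pairs)
    train_ids, test_ids = patient_split(
        dataset.patient_ids(), cfg.train.train_fraction, seed=seed
    )
    net_cfg = dataclasses.replace(cfg.network, seed=seed)
    model = AttentionUNet(net_cfg)
    train_cfg = dataclasses.replace(cfg.train, seed=seed)
    history, best_state = train(
        model, dataset, train_patients=train_ids, cfg=train_cfg, val_patients=test_ids
    )
    model.load_state_dict(best_state)
    report = evaluate_run(model, dataset, patients=test_ids, post_cfg=cfg.postprocess)
    report["history"] = history
    report["model"] = model
    report["train_patients"] = train_ids
    report["test_patients"] = test_ids
    report["seed"] = seed
    return report


def run_experiment(cfg: RunConfig, n_seeds: int, base_seed: int = 0, out_dir=None) -> dict:
    """Repeat the experiment over ``n_seeds`` seeds and aggregate per metric.

    Writes (when out_dir is given): per-seed metric table CSV, aggregate
    JSON report, and the resolved config.
    """
    if n_seeds < 2:
        raise ValueError("run_experiment requires n_seeds >= 2 for aggregation")
    per_seed = []
    for k in range(n_seeds):
        report = run_single(cfg, seed=base_seed + k)
        row = dict(report["summary"])
        row["seed"] = report["seed"]
        per_seed.append(row)
    table = pd.DataFrame(per_seed).set_index("seed")
    agg = M.aggregate_runs(table)
    result = {
        "n_seeds": n_seeds,
        "per_seed": table.reset_index().to_dict(orient="records"),
        "aggregate": {
            metric: {
                "mean": float(agg.loc[metric, "mean"]),
                "sd": float(agg.loc[metric, "sd"]),
                "ci95_half_width": float(agg.loc[metric, "ci95_half_width"]),
            }
            for metric in agg.index
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "per_seed_metrics.csv")
        (out / "report.json").write_text(json.dumps(result, indent=2))
        (out / "resolved_config.json").write_text(
            json.dumps(config_to_dict(cfg), indent=2)
        )
    return result
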