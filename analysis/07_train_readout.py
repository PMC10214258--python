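#!/usr/bin/env python
"""Train the 60 x 4 softmax readout and evaluate it on the held-out half.

Uses the state matrix from 06, a stratified 500/500 split, and reports the
confusion matrix and test accuracy; the trained model is persisted as
JSON.  A label-permutation null confirms the accuracy reflects signal.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from egtrc.pipeline import states_from_csv
from egtrc.readout import (
    evaluate,
    model_to_json,
    permutation_null,
    stratified_split_indices,
    train_readout,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--states", type=Path, default=ROOT / "scratch" / "states.csv")
    parser.add_argument("--split-seed", type=int, default=42)
    parser.add_argument("--mode", choices=("softmax", "ridge"), default="softmax")
    args = parser.parse_args()

    states, labels, _ = states_from_csv(args.states)
    tr, te = stratified_split_indices(labels, 0.5, seed=args.split_seed)
    model = train_readout(states[tr], labels[tr], seed=args.split_seed,
                          mode=args.mode)
    report = evaluate(model, states[te], labels[te])

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    model_to_json(model, results / "readout_model.json")
    report.to_frame().to_csv(results / "confusion.csv")
    null = permutation_null(states, labels, n_shuffles=20, seed=args.split_seed)
    summary = {
        "mode": args.mode,
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
        "test_accuracy": report.accuracy,
        "per_class_accuracy": dict(
            zip(report.classes.tolist(), np.round(report.per_class_accuracy, 4))
        ),
        "permutation_null_mean": float(null.mean()),
    }
    (results / "readout_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"test accuracy ({args.mode}): {report.accuracy:.1%} "
          f"on {len(te)} held-out samples")
    print(report.to_frame().to_string())
    print(f"label-shuffled baseline: {null.mean():.1%} (chance = 25%)")


if __name__ == "__main__":
    main()
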