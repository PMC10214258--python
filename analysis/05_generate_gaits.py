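#!/usr/bin/env python
"""Generate the labelled four-class gait dataset (250 samples per class).

Writes the full dataset (JSON Lines, one sample per line with its contact
events and derived gate-voltage trains) plus a manifest of the stratified
500/500 split.  The full JSONL is bulky and goes under scratch/; a small
preview and per-class summary land in results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from egtrc.gait import (
    GaitGenParams,
    dataset_manifest,
    dataset_to_jsonl,
    generate_dataset,
    split_dataset,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-per-class", type=int, default=250)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "gaits.jsonl")
    args = parser.parse_args()

    params = GaitGenParams()
    samples = generate_dataset(args.n_per_class, params, master_seed=args.seed)
    split = split_dataset(samples, train_fraction=0.5, seed=args.seed)

    args.out.parent.mkdir(exist_ok=True)
    dataset_to_jsonl(samples, args.out)
    manifest = dataset_manifest(samples, split)
    manifest.to_csv(args.out.with_suffix(".manifest.csv"), index=False)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    dataset_to_jsonl(samples[:2], results / "gaits_preview.jsonl")
    rows = []
    for cls, group in manifest.groupby("class"):
        members = [s for s in samples if s.gait_class.value == cls]
        n_events = [len(s.contacts.left) + len(s.contacts.right) for s in members]
        rows.append({
            "class": cls,
            "n_samples": len(members),
            "n_train": int((group["split"] == "train").sum()),
            "mean_contacts_per_sample": float(np.mean(n_events)),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(results / "gait_dataset_summary.csv", index=False)
    print(f"wrote {len(samples)} samples to {args.out}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
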