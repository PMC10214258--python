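"""End-to-end runs: generate gaits -> simulate reservoir -> train -> score.

These are the fixed protocols behind the headline numbers: 250 samples per
class (1000 total), a stratified 500/500 split, 60 reservoir states at
100 ms sampling, and a softmax readout; the reported accuracy is the mean
over several master seeds so the stochastic quantity is stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .device import EGTParams, default_params
from .gait import GaitGenParams, generate_dataset
from .pipeline import batch_states
from .readout import single_run, uniform_downsample_indices

__all__ = ["GaitRunResult", "run_gait_classification", "headline_accuracy",
           "derive_master_seeds"]


@dataclass(frozen=True)
class GaitRunResult:
    master_seed: int
    accuracy: dict[int, float]  # readout size -> test accuracy
    n_samples: int


def derive_master_seeds(seed: int, n_seeds: int = 10) -> list[int]:
    """Deterministic master seeds (< 2**31) for the repeated protocol."""
    state = np.random.SeedSequence(seed).generate_state(n_seeds, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def run_gait_classification(
    master_seed: int,
    n_per_class: int = 250,
    gait_params: GaitGenParams | None = None,
    device: EGTParams | None = None,
    sizes: Sequence[int] = (60,),
    mode: str = "softmax",
) -> GaitRunResult:
    """One full pipeline run under a single master seed.

    The same master seed drives both the dataset generation and the
    stratified split, so the run is reproducible bit-for-bit.
    """
    gait_params = gait_params if gait_params is not None else GaitGenParams()
    device = device if device is not None else default_params()
    dataset = generate_dataset(n_per_class, gait_params, master_seed)
    states, labels = batch_states(dataset, device)
    n_states = states.shape[1]
    accuracy = {}
    for size in sizes:
        idx = None if size == n_states else uniform_downsample_indices(n_states, size)
        acc, _ = single_run(
            states, labels, split_seed=master_seed, mode=mode, feature_indices=idx
        )
        accuracy[int(size)] = acc
    return GaitRunResult(
        master_seed=master_seed, accuracy=accuracy, n_samples=len(dataset)
    )


def headline_accuracy(
    master_seeds: Sequence[int],
    n_per_class: int = 250,
    sizes: Sequence[int] = (60, 30),
    gait_params: GaitGenParams | None = None,
    device: EGTParams | None = None,
    mode: str = "softmax",
) -> pd.DataFrame:
    """Mean/sd test accuracy per readout size over repeated full runs."""
    results = [
        run_gait_classification(
            s, n_per_class=n_per_class, gait_params=gait_params,
            device=device, sizes=sizes, mode=mode,
        )
        for s in master_seeds
    ]
    rows = []
    for size in sizes:
        accs = np.array([r.accuracy[int(size)] for r in results])
        rows.append(
            {
                "size": int(size),
                "mean_accuracy": float(accs.mean()),
                "sd": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
                "n_seeds": len(accs),
                "per_seed": accs.tolist(),
            }
        )
    return pd.DataFrame(rows)
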