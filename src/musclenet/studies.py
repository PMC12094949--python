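"""Desk-scale simulation studies used for validation and reporting.

These compose the public pipeline stages into the experiments a reader
would run to check the method: synergy-count recovery under the study
design (6 subjects x 5 trials per condition) and the VAF floor on the
default synthetic dataset.
"""

from __future__ import annotations

import numpy as np

from .config import SynthEmgConfig, derive_seed
from .preprocess import preprocess_trials
from .synergy import select_synergy_count, vaf_curve
from .synthetic import generate_dataset


def selection_study(
    k_true: int,
    n_replicates: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    snr_db: float = 20.0,
    dominant_share: float = 0.8,
    k_range=range(1, 8),
    vaf_restarts: int = 3,
) -> list[int]:
    """Selected synergy count per replicate of the full study design.

    Each replicate simulates 6 subjects x 5 trials of one condition with
    ``k_true`` planted synergies, preprocesses them, builds the per-trial
    VAF table over ``k_range`` and applies the significant-difference
    criterion.
    """
    picks = []
    for r in range(n_replicates):
        cfg = SynthEmgConfig(
            seed=derive_seed(seed, "selection", k_true, r),
            k_true=k_true,
            snr_db=snr_db,
            dominant_share=dominant_share,
        )
        trials, _ = generate_dataset(cfg, conditions=("self",))
        table = vaf_curve(
            preprocess_trials(trials),
            k_range=k_range,
            seed=derive_seed(seed, "vaf", k_true, r),
            n_restarts=vaf_restarts,
        )
        picks.append(select_synergy_count(table, alpha=alpha)[0])
    return picks


def vaf_floor_study(
    seed: int = 0,
    k_true_by_condition: dict[str, int] | None = None,
    k_range=range(1, 8),
    vaf_restarts: int = 3,
) -> float:
    """Minimum VAF cell over both conditions of the default dataset."""
    if k_true_by_condition is None:
        k_true_by_condition = {"self": 2, "robot": 3}
    worst = np.inf
    for cond, k_true in k_true_by_condition.items():
        cfg = SynthEmgConfig(
            seed=derive_seed(seed, "floor", cond), k_true=k_true
        )
        trials, _ = generate_dataset(cfg, conditions=(cond,))
        table = vaf_curve(
            preprocess_trials(trials),
            k_range=k_range,
            seed=derive_seed(seed, "floor-vaf", cond),
            n_restarts=vaf_restarts,
        )
        worst = min(worst, float(table.min().min()))
    return worst
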