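"""Shared fixtures: a small, fast synthetic world reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from climenv.occurrence import (
    assemble_training_set,
    sample_pseudo_absences,
    transect_absence_midpoints,
)
from climenv.synthetic import (
    SyntheticWorldConfig,
    generate_climate_grid,
    sample_presences,
    simulate_transects,
    true_occupancy,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticWorldConfig:
    # coarse resolution keeps every fit in the suite fast
    return SyntheticWorldConfig(resolution=0.2, n_presence=250, n_transects=60, seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    """Grid, truth surface and occurrence data for a compact study region."""
    grid = generate_climate_grid(small_config)
    surface = true_occupancy(grid, small_config)
    presences = sample_presences(surface, small_config.n_presence, seed=21)
    transects = simulate_transects(
        surface, small_config.n_transects, small_config.transect_length_km,
        small_config.detection_prob, seed=31,
    )
    return {
        "config": small_config,
        "grid": grid,
        "surface": surface,
        "presences": presences,
        "transects": transects,
    }


@pytest.fixture(scope="session")
def small_table(small_world):
    """Feature table: presences + transect absences + 750 pseudo-absences."""
    absences = transect_absence_midpoints(small_world["transects"])
    pseudo = sample_pseudo_absences(
        small_world["config"].extent, small_world["presences"],
        n=750, min_dist_km=10.0, seed=41,
    )
    return assemble_training_set(
        small_world["presences"], absences, pseudo, small_world["grid"]
    )


# -- independent oracles -------------------------------------------------------


def auc_brute_force(observed, predicted) -> float:
    """All-pairs concordance: P(score_1 > score_0) + 0.5 P(tie)."""
    obs = np.asarray(observed)
    pred = np.asarray(predicted, dtype=float)
    pos = pred[obs == 1]
    neg = pred[obs == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def kappa_at(observed, predicted, threshold: float) -> float:
    """Cohen's kappa of the binarisation pred >= threshold, from first principles."""
    obs = np.asarray(observed)
    hat = (np.asarray(predicted, dtype=float) >= threshold).astype(int)
    n = len(obs)
    po = float((hat == obs).mean())
    pe = float(
        (hat == 1).mean() * (obs == 1).mean() + (hat == 0).mean() * (obs == 0).mean()
    )
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def max_kappa_brute_force(observed, predicted) -> tuple[float, float]:
    """Exhaustive search over all candidate thresholds; ties to the smallest."""
    cands = sorted(set(np.asarray(predicted, dtype=float)) | {0.0, 1.0})
    best_t, best_k = None, -np.inf
    for t in cands:
        k = kappa_at(observed, predicted, t)
        if k > best_k:
            best_t, best_k = t, k
    return best_t, best_k
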