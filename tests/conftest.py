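"""Shared fixtures: a 7-class synthetic beat dataset and a desk-scale trained
feature bank, built once per session and reused by the heavier tests."""

from __future__ import annotations

import numpy as np
import pytest

from evombn import generate_beat_dataset
from evombn.branch_network import (DESK_WIDTH_PLAN, TrainSchedule, build_feature_bank,
                                   train_all_branches)
from evombn.leads import CLASS_ORDER

DESK_SEED = 11


@pytest.fixture(scope="session")
def beat_dataset7():
    """~200 z-scored beats over all 7 classes, 21 patients (3 per class)."""
    return generate_beat_dataset(29, CLASS_ORDER, n_patients=21, noise_sd=0.05,
                                 seed=DESK_SEED)


@pytest.fixture(scope="session")
def trained_nets(beat_dataset7):
    sched = TrainSchedule(lr0=0.05, batch=32, epochs=5, seed=DESK_SEED)
    nets, _ = train_all_branches(beat_dataset7, DESK_WIDTH_PLAN, sched,
                                 seed=DESK_SEED)
    return nets


@pytest.fixture(scope="session")
def feature_bank7(trained_nets, beat_dataset7):
    return build_feature_bank(trained_nets, beat_dataset7)


@pytest.fixture(scope="session")
def planted_optimum_results():
    """GA vs 1000-sample random search on planted-optimum landscapes.

    For each seed 0..79: plant a target genome (independent stream, so the
    optimum never coincides with the GA's seeded initial population), evolve
    with the default protocol, and compare the best evolved fitness against
    the best of 1000 uniformly drawn genomes.  Returns (wins, margins).
    """
    from evombn.ga_search import GAConfig, evolve, fitness, random_genome

    wins, margins = [], []
    for seed in range(80):
        rng = np.random.default_rng(10_000 + seed)
        target = random_genome(rng)

        def landscape(genome, t=target):
            closeness = 1.0 - sum(abs(a - b) for a, b in zip(genome, t)) / 180.0
            return closeness, 0.0, True

        best, _ = evolve(landscape, GAConfig(seed=seed))
        baseline = max(fitness(landscape(g)[0], 0.0, g)
                       for g in (random_genome(rng) for _ in range(1000)))
        wins.append(bool(best.fitness >= baseline))
        margins.append(best.fitness - baseline)
    return wins, margins


@pytest.fixture(scope="session")
def attention_recovery_wins():
    """Run the 5-seed lead-attention recovery experiment once per session.

    For each seed: generate an IMI-vs-HC dataset, train desk branches, train a
    binary LSE head on top-level features and record whether the mean
    excitation of the inferior leads (II, III, aVF) exceeds the mean of the
    other nine leads.
    """
    from evombn import LSEConfig, mean_excitations, train_lse
    from evombn.branch_network import build_feature_bank as bfb
    from evombn.leads import LEAD_INDEX

    inferior = [LEAD_INDEX[n] for n in ("II", "III", "aVF")]
    others = [i for i in range(12) if i not in inferior]
    genome = (17,) * 12
    wins = []
    for seed in range(5):
        ds = generate_beat_dataset(40, ("HC", "IMI"), n_patients=10,
                                   noise_sd=0.05, seed=seed)
        sched = TrainSchedule(lr0=0.05, batch=32, epochs=3, seed=seed)
        nets, _ = train_all_branches(ds, DESK_WIDTH_PLAN, sched, seed=1000 * seed)
        bank = bfb(nets, ds)
        model, _ = train_lse(bank, genome, LSEConfig(epochs=30, seed=seed),
                             classes=("HC", "IMI"), class_mode="binary",
                             positive_class="IMI")
        e = mean_excitations(model, bank, genome)
        assert np.all((e > 0) & (e < 1))
        wins.append(bool(e[inferior].mean() > e[others].mean()))
    return wins
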