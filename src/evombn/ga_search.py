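"""Genetic-algorithm search over multi-branch architectures.

An architecture is a 12-integer genome ``L = [l_1, ..., l_12]`` assigning a
feature level to each lead (leads in conventional order I, II, III, aVR, aVL,
aVF, V1..V6).  The search space restricts each element to the even levels
2..16 or the top level 17.  Evolution proceeds by

* uniform initialization over the 9 allowed levels (population 100);
* fitness  ``alpha * F1 + beta * Accuracy - eta * sum(l_i)``  with
  alpha = 1, beta = 0.1, eta = 1e-5 — performance first, then a depth-sum
  complexity penalty that prefers the most lightweight of equally good models;
* truncation selection of the 10 fittest individuals as parents;
* one-point crossover split at the central point, i.e. between the limb-lead
  half (positions 1-6) and the precordial half (positions 7-12);
* mutation that picks k = 3 elements without replacement and resets each to
  2 with probability p1 = 0.8 or to 17 with probability p2 = 0.2, applied to
  each offspring independently with probability pm = 0.25;
* early stop when the maximum fitness is unchanged for 2 consecutive
  generations, with a 10-generation cap.

Parents are carried into the next generation unchanged, so the population's
best fitness is non-decreasing (elitism).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .branch_network import FeatureBank
from .lse_summarizer import LSEConfig, predict_proba, train_lse

logger = logging.getLogger(__name__)

GENOME_LENGTH = 12
ALLOWED_LEVELS = (2, 4, 6, 8, 10, 12, 14, 16, 17)
CROSSOVER_POINT = 6  # limb leads | precordial leads


def validate_genome(L) -> list[str]:
    """Return the list of violated search-space constraints (empty = pass)."""
    violations = []
    L = list(L)
    if len(L) != GENOME_LENGTH:
        violations.append(f"length {len(L)} != {GENOME_LENGTH}")
    for i, l in enumerate(L):
        if not isinstance(l, (int, np.integer)):
            violations.append(f"element {i + 1} = {l!r} is not an integer")
            continue
        if l > 17:
            violations.append(f"element {i + 1} = {l} exceeds 17")
        if l < 2:
            violations.append(f"element {i + 1} = {l} is below the minimum level 2")
        if l % 2 != 0 and l != 17:
            violations.append(f"element {i + 1} = {l} is odd and != 17")
    return violations


def is_valid_genome(L) -> bool:
    return not validate_genome(L)


@dataclass
class Individual:
    genome: tuple
    fitness: float | None = None
    metrics: dict | None = None  # {"F1": ..., "Accuracy": ...}


@dataclass
class GAConfig:
    """Default settings of the evolutionary search."""

    pop_size: int = 100
    n_parents: int = 10
    p1: float = 0.8     # reset-to-2 probability
    p2: float = 0.2     # reset-to-17 probability
    pm: float = 0.25    # per-offspring mutation probability
    k: int = 3          # elements reset per mutation
    max_generations: int = 10
    patience: int = 2
    alpha: float = 1.0
    beta: float = 0.1
    eta: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if abs(self.p1 + self.p2 - 1.0) > 1e-12:
            raise ValueError("p1 + p2 must equal 1")
        if not 0 < self.pm < 1:
            raise ValueError("pm must lie in (0, 1)")
        if not 0 < self.n_parents < self.pop_size:
            raise ValueError("need 0 < n_parents < pop_size")
        if not 1 <= self.k <= GENOME_LENGTH:
            raise ValueError("k must be in 1..12")
        if min(self.alpha, self.beta, self.eta) <= 0:
            raise ValueError("fitness weights must be positive")


def fitness(f1: float, accuracy: float, L, alpha: float = 1.0, beta: float = 0.1,
            eta: float = 1e-5) -> float:
    """alpha * F1 + beta * Accuracy - eta * sum(l_i), both scores on [0, 1]."""
    return float(alpha * f1 + beta * accuracy - eta * sum(L))


def random_genome(rng: np.random.Generator) -> tuple:
    return tuple(int(v) for v in rng.choice(ALLOWED_LEVELS, size=GENOME_LENGTH))


def init_population(config: GAConfig, rng: np.random.Generator | None = None):
    """Uniformly sampled population of ``pop_size`` valid genomes."""
    rng = rng or np.random.default_rng(config.seed)
    return [Individual(random_genome(rng)) for _ in range(config.pop_size)]


def select(population, n_parents: int):
    """Top-``n_parents`` by fitness, descending; ties break by smaller depth
    sum, then by insertion order."""
    for ind in population:
        if ind.fitness is None:
            raise ValueError("cannot select from unevaluated individuals")
    order = sorted(range(len(population)),
                   key=lambda i: (-population[i].fitness,
                                  sum(population[i].genome), i))
    return [population[i] for i in order[:n_parents]]


def crossover(parent_a, parent_b):
    """One-point splice at the central point: limb-lead half from one parent,
    precordial half from the other."""
    a, b = tuple(parent_a), tuple(parent_b)
    child_a = a[:CROSSOVER_POINT] + b[CROSSOVER_POINT:]
    child_b = b[:CROSSOVER_POINT] + a[CROSSOVER_POINT:]
    return child_a, child_b


def mutate(L, rng: np.random.Generator, k: int = 3, p1: float = 0.8,
           p2: float = 0.2) -> tuple:
    """Reset ``k`` distinct elements to 2 (prob. p1) or 17 (prob. p2).

    A reset that lands on the element's current value still counts as one of
    the k mutated elements.
    """
    if abs(p1 + p2 - 1.0) > 1e-12:
        raise ValueError("p1 + p2 must equal 1")
    if not 1 <= k <= GENOME_LENGTH:
        raise ValueError("k must be in 1..12")
    L = list(L)
    positions = rng.choice(GENOME_LENGTH, size=k, replace=False)
    for pos in positions:
        L[pos] = 2 if rng.random() < p1 else 17
    return tuple(L)


def mutation_step(genomes, rng: np.random.Generator, config: GAConfig):
    """Apply the mutation operator to each offspring independently with
    probability ``pm``.  Returns ``(new_genomes, mutated_mask)``."""
    out, mask = [], []
    for g in genomes:
        hit = rng.random() < config.pm
        out.append(mutate(g, rng, config.k, config.p1, config.p2) if hit else tuple(g))
        mask.append(hit)
    return out, np.array(mask)


class CachingEvaluator:
    """Wraps a genome -> (F1, Accuracy, is_valid) callable with memoization."""

    def __init__(self, fn):
        self.fn = fn
        self.cache: dict[tuple, tuple] = {}
        self.calls = 0
        self.cache_hits = 0

    def __call__(self, genome):
        key = tuple(genome)
        if key in self.cache:
            self.cache_hits += 1
            return self.cache[key]
        self.calls += 1
        result = self.fn(key)
        self.cache[key] = result
        return result


def _evaluate(population, evaluator, config: GAConfig):
    for ind in population:
        if ind.fitness is not None:
            continue
        try:
            f1, acc, ok = evaluator(ind.genome)
        except Exception as exc:  # evaluator failure -> floor fitness
            logger.warning("fitness evaluation failed for %s: %s", ind.genome, exc)
            ind.fitness, ind.metrics = float("-inf"), {"F1": np.nan, "Accuracy": np.nan}
            continue
        if not ok:
            ind.fitness, ind.metrics = float("-inf"), {"F1": np.nan, "Accuracy": np.nan}
            continue
        ind.metrics = {"F1": float(f1), "Accuracy": float(acc)}
        ind.fitness = fitness(f1, acc, ind.genome, config.alpha, config.beta, config.eta)


def evolve(evaluator, config: GAConfig):
    """Run the evolutionary loop; returns ``(best Individual, history)``.

    ``history`` holds one record per generation: generation index, max and
    mean fitness, and the best genome.  The initial population counts as
    generation 1.
    """
    rng = np.random.default_rng(config.seed)
    if not isinstance(evaluator, CachingEvaluator):
        evaluator = CachingEvaluator(evaluator)

    population = init_population(config, rng)
    _evaluate(population, evaluator, config)
    history = [_snapshot(1, population)]
    unchanged = 0
    prev_max = history[-1]["max_fitness"]

    for gen in range(2, config.max_generations + 1):
        parents = select(population, config.n_parents)
        n_offspring = config.pop_size - config.n_parents
        children = []
        while len(children) < n_offspring:
            i, j = rng.choice(len(parents), size=2, replace=False)
            ca, cb = crossover(parents[i].genome, parents[j].genome)
            children.extend([ca, cb])
        children = children[:n_offspring]
        mutated, _ = mutation_step(children, rng, config)
        population = parents + [Individual(g) for g in mutated]
        for ind in population:
            assert is_valid_genome(ind.genome)
        _evaluate(population, evaluator, config)
        history.append(_snapshot(gen, population))
        cur_max = history[-1]["max_fitness"]
        assert cur_max >= prev_max - 1e-12, "elitism violated"
        unchanged = unchanged + 1 if abs(cur_max - prev_max) <= 1e-12 else 0
        prev_max = cur_max
        if unchanged >= config.patience:
            break

    best = select(population, 1)[0]
    return best, history


def _snapshot(gen: int, population) -> dict:
    finite = [i.fitness for i in population if np.isfinite(i.fitness)]
    best = select(population, 1)[0]
    return {
        "generation": gen,
        "max_fitness": float(best.fitness),
        "mean_fitness": float(np.mean(finite)) if finite else float("-inf"),
        "best_genome": list(best.genome),
    }


# --------------------------------------------------------------------------
# fitness evaluators
# --------------------------------------------------------------------------

def _genome_seed(genome, base_seed: int) -> int:
    """Stable per-genome substream seed below 2**31."""
    h = zlib.crc32(bytes(int(g) for g in genome))
    return (h ^ (base_seed * 2654435761)) % (2 ** 31)


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray, classes) -> float:
    f1s = []
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        if tp == 0 and (fp + fn) == 0:
            continue
        f1s.append(2 * tp / (2 * tp + fp + fn))
    return float(np.mean(f1s)) if f1s else 0.0


@dataclass
class LSEFitnessEvaluator:
    """Genome fitness backed by training an LSE head on cached features.

    An 80/20 *patient-wise* fit/validation split is carved once from the given
    (training-fold) bank; every genome trains a fresh LSE head on the fit part
    and is scored on the validation part.  Deterministic given genome + seed.
    """

    bank: FeatureBank
    task: str = "multiclass"            # "multiclass" | "binary"
    positive_class: str | None = None   # binary mode target class
    classes: tuple = ()
    lse: LSEConfig = field(default_factory=LSEConfig)
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self):
        if not self.classes:
            self.classes = tuple(self.bank.class_set)
        rng = np.random.default_rng(self.seed)
        pids = self.bank.patient_ids
        val_patients = set()
        for c in self.classes:
            cp = np.array(sorted(set(pids[self.bank.labels == c])))
            if cp.size == 0:
                continue
            n_val = max(1, int(round(self.val_fraction * cp.size)))
            val_patients.update(rng.permutation(cp)[:n_val])
        self._val_mask = np.isin(pids, sorted(val_patients))
        self._fit_bank = self.bank.subset(~self._val_mask)
        self._val_bank = self.bank.subset(self._val_mask)

    def __call__(self, genome):
        cfg = LSEConfig(epochs=self.lse.epochs, batch=self.lse.batch, lr=self.lse.lr,
                        r=self.lse.r, seed=_genome_seed(genome, self.seed),
                        force_excitation=self.lse.force_excitation)
        mode = "binary" if self.task == "binary" else "multiclass"
        model, _ = train_lse(self._fit_bank, genome, cfg, classes=self.classes,
                             class_mode=mode, positive_class=self.positive_class)
        proba = predict_proba(model, self._val_bank, genome,
                              force_excitation=self.lse.force_excitation)
        y_true = self._val_bank.labels
        if mode == "binary":
            y_pred_bin = proba >= 0.5
            y_bin = y_true == self.positive_class
            tp = int(np.sum(y_bin & y_pred_bin))
            fp = int(np.sum(~y_bin & y_pred_bin))
            fn = int(np.sum(y_bin & ~y_pred_bin))
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            acc = float(np.mean(y_bin == y_pred_bin))
        else:
            pred_idx = np.argmax(proba, axis=1)
            y_pred = np.array([self.classes[i] for i in pred_idx])
            f1 = _macro_f1(y_true, y_pred, self.classes)
            acc = float(np.mean(y_true == y_pred))
        return f1, acc, True
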