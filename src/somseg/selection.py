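"""Genetic-algorithm wrapper selection of discriminative feature subsets.

Candidate subsets are fixed-length bit masks over the feature names.  The
fitness of a mask is the negated sum of the mean per-tissue Jaccard scores
obtained by running the full segmentation pipeline restricted to that
subset on a set of training volumes with references — lower is better, and
-3 is the perfect-recovery bound.  The GA itself (tournament selection,
uniform crossover, bit-flip mutation, elitism 1) is generic over any
fitness function, which the tests exploit with cheap synthetic problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .evaluation import score_segmentation
from .features import FEATURE_NAMES
from .io_volume import LabelMap, Volume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters (conventional defaults, all configurable)."""

    population: int = 50
    generations: int = 60
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1 / n_bits
    tournament: int = 3
    seed: int = 0
    min_features: int = 1

    def __post_init__(self) -> None:
        if self.population < 2 or self.population % 2:
            raise ValueError("population must be even and >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for r in (self.crossover_rate, self.mutation_rate):
            if r is not None and not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")


@dataclass
class FeatureMask:
    """Boolean selection over the canonical feature names."""

    bits: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        self.names = tuple(self.names)
        if self.bits.shape != (len(self.names),):
            raise ValueError("bits length must match names length")
        if not self.bits.any():
            raise ValueError("a feature mask must select at least one feature")

    @property
    def selected_names(self) -> list[str]:
        return [n for n, b in zip(self.names, self.bits) if b]


def _repair(bits: np.ndarray, min_features: int, rng: np.random.Generator) -> None:
    """Switch on random bits in place until at least min_features are set."""
    deficit = min_features - int(bits.sum())
    if deficit > 0:
        off = np.flatnonzero(~bits)
        bits[rng.choice(off, size=deficit, replace=False)] = True


def ga_optimize(
    fitness_fn: Callable[[np.ndarray], float],
    n_bits: int,
    cfg: GAConfig = GAConfig(),
) -> tuple[np.ndarray, list[float]]:
    """Minimize a fitness function over bit strings with an elitist GA.

    Returns the best bit string found and the per-generation best-fitness
    trace, which elitism makes non-increasing.  Fitness evaluations are
    memoized, so a deterministic ``fitness_fn`` is only called once per
    distinct mask.
    """
    rng = np.random.default_rng(cfg.seed)
    p_mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n_bits
    cache: dict[bytes, float] = {}

    def evaluate(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = float(fitness_fn(bits))
        return cache[key]

    pop = rng.random((cfg.population, n_bits)) < 0.5
    for bits in pop:
        _repair(bits, cfg.min_features, rng)
    fits = np.array([evaluate(b) for b in pop])

    trace: list[float] = []
    best_bits = pop[int(fits.argmin())].copy()
    best_fit = float(fits.min())

    for _ in range(cfg.generations):
        children = []
        while len(children) < cfg.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population, size=cfg.tournament)
                parents.append(pop[contenders[fits[contenders].argmin()]].copy())
            a, b = parents
            if rng.random() < cfg.crossover_rate:
                swap = rng.random(n_bits) < 0.5
                a[swap], b[swap] = b[swap].copy(), a[swap].copy()
            for child in (a, b):
                flip = rng.random(n_bits) < p_mut
                child[flip] = ~child[flip]
                _repair(child, cfg.min_features, rng)
                children.append(child)
        pop = np.array(children[: cfg.population])
        fits = np.array([evaluate(b) for b in pop])
        # elitism: worst child replaced by the best-so-far individual
        worst = int(fits.argmax())
        if best_fit < fits[worst]:
            pop[worst] = best_bits
            fits[worst] = best_fit
        gen_best = int(fits.argmin())
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_bits = pop[gen_best].copy()
        trace.append(best_fit)

    return best_bits, trace


def fitness(
    mask: FeatureMask | np.ndarray,
    volumes: Sequence[tuple[Volume, LabelMap]],
    pipeline_config=None,
) -> float:
    """-(mean J_CSF + mean J_GM + mean J_WM) of the pipeline under ``mask``.

    Each training volume is segmented using only the selected features and
    scored against its reference; per-tissue Jaccard values are averaged
    across volumes.  A volume on which the pipeline fails is skipped with
    a warning; if all fail, an error is raised.
    """
    from .pipeline import PipelineConfig, segment  # deferred: avoid cycle

    if isinstance(mask, FeatureMask):
        names = mask.selected_names
    else:
        bits = np.asarray(mask, dtype=bool)
        names = [n for n, b in zip(FEATURE_NAMES, bits) if b]
    if not names:
        raise ValueError("mask selects no features")
    if len(volumes) == 0:
        raise ValueError("volumes must be nonempty")

    cfg = pipeline_config if pipeline_config is not None else PipelineConfig()
    cfg = replace(cfg, selected_features=tuple(names))

    sums = np.zeros(3)
    n_ok = 0
    for vol, ref in volumes:
        try:
            seg, _, _ = segment(vol, cfg)
            score = score_segmentation(seg, ref)
            sums += [score.per_tissue[t] for t in sorted(score.per_tissue)]
            n_ok += 1
        except Exception as exc:  # noqa: BLE001 - skip-and-warn contract
            logger.warning("pipeline failed on a training volume: %s", exc)
    if n_ok == 0:
        raise RuntimeError("pipeline failed on every training volume")
    return float(-(sums / n_ok).sum())


def ga_select(
    volumes: Sequence[tuple[Volume, LabelMap]],
    cfg: GAConfig = GAConfig(),
    pipeline_config=None,
) -> tuple[FeatureMask, list[float]]:
    """Evolve the feature subset minimizing pipeline fitness on ``volumes``."""
    n_bits = len(FEATURE_NAMES)
    best_bits, trace = ga_optimize(
        lambda bits: fitness(bits, volumes, pipeline_config), n_bits, cfg
    )
    return FeatureMask(bits=best_bits), trace
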