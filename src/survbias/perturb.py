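"""Subjective response-error simulator.

Models unreliable survey answers by probabilistic uniform replacement: for each
bias-susceptible categorical feature with answer set A, every cell is independently
selected with probability p; a selected response r becomes a uniform draw from A
(or from A \\ {r} when exclude_original is set — the stricter reading under which
every selected answer is forced to change). With the inclusive default the
probability a selected cell actually changes value is 1 - 1/|A|.

A single seed deterministically derives one substream per feature, so extending
the target set does not alter the draws of features already targeted.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable
from .exceptions import ConfigurationError

__all__ = [
    "PerturbationConfig",
    "PerturbationLog",
    "perturb_dataset",
    "perturb_single_feature",
    "expected_change_rate",
]


@dataclass(frozen=True)
class PerturbationConfig:
    """Replacement probability, target features (None = all perturbable), semantics, seed."""

    p: float = 0.2
    target_features: tuple | None = None
    exclude_original: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ConfigurationError(f"replacement probability p={self.p} outside [0,1]")


@dataclass
class PerturbationLog:
    """Per-feature selected row indices and counts of cells whose value changed."""

    selected: dict = field(default_factory=dict)   # feature -> np.ndarray of row indices
    changed: dict = field(default_factory=dict)    # feature -> int

    def selected_count(self, feature: str) -> int:
        return len(self.selected[feature])


def _feature_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(("perturb:" + name).encode())])
    )


def _resolve_targets(table: CohortTable, config: PerturbationConfig) -> list:
    targets = (list(config.target_features) if config.target_features is not None
               else table.schema.perturbable_features())
    for name in targets:
        try:
            spec = table.schema.feature(name)
        except KeyError:
            raise ConfigurationError(f"target feature {name!r} not present in schema") from None
        if spec.kind != "categorical":
            raise ConfigurationError(f"target feature {name!r} is not categorical")
        if not spec.perturbable:
            raise ConfigurationError(f"target feature {name!r} is not flagged perturbable")
    return targets


def perturb_dataset(table: CohortTable, config: PerturbationConfig):
    """Return (perturbed copy of table, PerturbationLog); the input is untouched.

    Non-target columns and outcomes are bit-identical to the input. Missing cells
    behave like any other: if selected they receive a uniform draw from the full
    answer set (a missing original is never a member of A, so exclusion is moot).
    """
    targets = _resolve_targets(table, config)
    out = table.copy()
    log = PerturbationLog()
    n = table.n
    for name in targets:
        spec = table.schema.feature(name)
        answers = np.asarray(spec.answer_set, dtype=object)
        k = len(answers)
        rng = _feature_rng(config.seed, name)
        selected = np.flatnonzero(rng.random(n) < config.p)
        log.selected[name] = selected
        if len(selected) == 0:
            log.changed[name] = 0
            continue
        col = out.df[name].to_numpy(dtype=object, copy=True)
        original = col[selected]
        if config.exclude_original:
            # uniform over the k-1 answers other than the original; missing originals
            # (not in A) fall back to a draw over all k answers
            lookup = {a: i for i, a in enumerate(answers)}
            orig_idx = np.array([lookup.get(v, -1) for v in original])
            draws = rng.integers(0, k - 1, size=len(selected))
            new_idx = np.where((orig_idx >= 0) & (draws >= orig_idx), draws + 1, draws)
            # rows whose original is missing: uniform over all k
            miss = orig_idx < 0
            if miss.any():
                new_idx[miss] = rng.integers(0, k, size=int(miss.sum()))
            replacements = answers[new_idx]
        else:
            replacements = answers[rng.integers(0, k, size=len(selected))]
        changed = sum(1 for a, b in zip(original, replacements)
                      if (a != b) and not (a != a and b != b))  # NaN-safe inequality
        col[selected] = replacements
        out.df[name] = col
        log.changed[name] = int(changed)
    return out, log


def perturb_single_feature(table: CohortTable, feature: str, p: float, seed: int,
                           exclude_original: bool = False) -> CohortTable:
    """Perturb exactly one feature; equivalent to perturb_dataset with a singleton target set."""
    config = PerturbationConfig(p=p, target_features=(feature,),
                                exclude_original=exclude_original, seed=seed)
    perturbed, _ = perturb_dataset(table, config)
    return perturbed


def expected_change_rate(p: float, cardinality: int, exclude_original: bool) -> float:
    """Closed-form probability that a cell's value changes under the replacement rule."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0,1]")
    if cardinality < 2:
        raise ValueError("answer-set cardinality must be >= 2")
    if exclude_original:
        return p
    return p * (1.0 - 1.0 / cardinality)
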