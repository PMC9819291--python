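"""Monte-Carlo empirical power for the Wilcoxon-Mann-Whitney comparison.

Replicates the post hoc power step of the fatigue analyses: for each
replicate, two groups are drawn (from parametric samplers or by
resampling supplied group data, the pipeline default -- matching the
"empirical power" wording), compared with the two-sided Mann-Whitney U
test, and the rejection proportion at level alpha is reported together
with its Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .rank_stats import mann_whitney_u

__all__ = [
    "Sampler",
    "PowerSpec",
    "PowerEstimate",
    "wmw_power",
    "normal_sampler",
    "resampler",
]

#: A group sampler: (generator, size) -> 1-d sample.
Sampler = Callable[[np.random.Generator, int], np.ndarray]


def normal_sampler(mean: float, sd: float) -> Sampler:
    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(mean, sd, size)
    return draw


def resampler(data) -> Sampler:
    """Sampler resampling an observed group with replacement."""
    values = np.asarray(data, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("cannot resample an empty group")

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return values[rng.integers(0, values.size, size)]
    return draw


@dataclass
class PowerSpec:
    generator_a: Sampler
    generator_b: Sampler
    n_a: int
    n_b: int
    alpha: float = 0.05
    n_reps: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("group sizes must be >= 2")


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    mc_se: float
    n_reps: int
    alpha: float
    n_a: int
    n_b: int
    degenerate_fraction: float = 0.0

    @property
    def degenerate(self) -> bool:
        """True when a material share of replicates had constant equal data."""
        return self.degenerate_fraction > 0.01


def wmw_power(spec: PowerSpec) -> PowerEstimate:
    """Empirical power of the two-sided Mann-Whitney U test.

    Deterministic given ``spec.seed``.  Replicates where the pooled sample
    is one constant value cannot reject and are counted in
    ``degenerate_fraction``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rejections = 0
    degenerate = 0
    for _ in range(spec.n_reps):
        a = spec.generator_a(rng, spec.n_a)
        b = spec.generator_b(rng, spec.n_b)
        res = mann_whitney_u(a, b, method="asymptotic"
                             if np.ptp(np.concatenate([a, b])) > 0 else "auto")
        if res.method == "mwu-degenerate":
            degenerate += 1
            continue
        if res.p_value < spec.alpha:
            rejections += 1
    power = rejections / spec.n_reps
    mc_se = float(np.sqrt(power * (1.0 - power) / spec.n_reps))
    return PowerEstimate(power, mc_se, spec.n_reps, spec.alpha,
                         spec.n_a, spec.n_b,
                         degenerate_fraction=degenerate / spec.n_reps)
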