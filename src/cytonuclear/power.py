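"""Monte-Carlo power of the exact test for a two-proportion difference.

Mirrors the study-design question: with n1 annotated genes in one set and
n2 in another, how often does the exact test detect an absolute difference
delta between the two sets' in-category proportions? Each replicate draws
the two in-category counts as independent binomials, forms the 2x2 table,
and applies the package's own Freeman–Halton test (which on 2x2 tables is
Fisher's exact test). Power is the rejection fraction at level alpha, with
its binomial Monte-Carlo standard error.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .contingency import ContingencyTable2xK, fisher_exact_2xk
from .errors import ValidationError

__all__ = ["PowerEstimate", "simulate_power", "minimum_detectable_difference"]


@dataclasses.dataclass(frozen=True)
class PowerEstimate:
    """Rejection proportion of a simulated test with its Monte-Carlo error."""

    power: float
    n_reps: int
    mc_se: float
    settings: dict

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValidationError(f"power {self.power} outside [0, 1]")


def _validate_two_group(n1: int, n2: int, p0: float, delta: float) -> None:
    if n1 < 1 or n2 < 1:
        raise ValidationError("group sizes must be >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"baseline proportion {p0} outside (0, 1)")
    if not 0.0 < p0 + delta < 1.0:
        raise ValidationError(
            f"shifted proportion {p0 + delta} outside (0, 1)"
        )


def simulate_power(
    n1: int,
    n2: int,
    p0: float,
    delta: float,
    *,
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PowerEstimate:
    """Simulated power to detect an absolute proportion difference *delta*.

    Group 1 counts are Binomial(n1, p0), group 2 Binomial(n2, p0 + delta);
    each replicate's 2x2 table is tested two-sided at level *alpha* with the
    exact test. Identical count pairs share one p-value evaluation, so large
    replicate numbers stay cheap.
    """
    _validate_two_group(n1, n2, p0, delta)
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha {alpha} outside (0, 1)")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x1 = rng.binomial(n1, p0, size=n_reps)
    x2 = rng.binomial(n2, p0 + delta, size=n_reps)
    pairs = x1.astype(np.int64) * (n2 + 1) + x2
    unique_pairs, counts = np.unique(pairs, return_counts=True)
    rejected = 0
    for code, weight in zip(unique_pairs, counts):
        a, b = divmod(int(code), n2 + 1)
        table = ContingencyTable2xK.from_rows((a, b), (n1 - a, n2 - b))
        if fisher_exact_2xk(table).p_value <= alpha:
            rejected += int(weight)
    power = rejected / n_reps
    return PowerEstimate(
        power=power,
        n_reps=n_reps,
        mc_se=float(np.sqrt(power * (1.0 - power) / n_reps)),
        settings={
            "n1": n1,
            "n2": n2,
            "p0": p0,
            "delta": delta,
            "alpha": alpha,
            "seed": None if isinstance(seed, np.random.Generator) else seed,
        },
    )


def minimum_detectable_difference(
    n1: int,
    n2: int,
    p0: float,
    *,
    alpha: float = 0.05,
    target_power: float = 0.8,
    n_reps: int = 10_000,
    seed: int = 0,
    grid: Sequence[float],
) -> float | None:
    """Smallest grid delta whose simulated power reaches *target_power*.

    The *grid* must be sorted ascending. Each candidate delta gets an
    independent random substream derived from *seed*. Returns ``None`` when
    no grid delta reaches the target.
    """
    if len(grid) == 0:
        raise ValidationError("delta grid must be non-empty")
    if list(grid) != sorted(grid):
        raise ValidationError("delta grid must be sorted ascending")
    streams = np.random.SeedSequence(seed).spawn(len(grid))
    for delta, stream in zip(grid, streams):
        estimate = simulate_power(
            n1,
            n2,
            p0,
            delta,
            alpha=alpha,
            n_reps=n_reps,
            seed=np.random.default_rng(stream),
        )
        if estimate.power >= target_power:
            return float(delta)
    return None
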