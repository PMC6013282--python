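"""Stochastic simulation of synchronously dividing coenocytes.

The model is a *timer*: within each cell, nuclear divisions fire at the ends
of i.i.d. intervals drawn from a Normal distribution with a fixed mean period
(11 h by default) and a cell-to-cell coefficient of variation (CV).  Every
division doubles the cell's DNA content, so a cell's ploidy trajectory is a
non-decreasing step function over powers of two.  A population of such cells,
released synchronously from starvation at t = 0, gradually desynchronizes at
a rate governed by the CV; the spread of log2 DNA content across the
population (the geometric standard deviation, GSD) is the asynchrony metric
used throughout the package.

Simulating many replicate populations over a grid of CV values yields
*asynchrony envelopes* (mean ± SD of the baseline-subtracted log2 GSD across
replicates), against which an observed asynchrony series can be compared to
bound the cell-to-cell variability of the timer
(:func:`coenocycle.flowstats.cv_upper_bound`).

Reproducibility: one root seed governs a run.  Replicate streams are derived
with counter-based spawn keys, so the stream of replicate *r* does not depend
on how many replicates or cells are requested.  Within a population the
interval matrix is filled row-wise (one row per cell), so enlarging the
population extends it without reshuffling existing cells' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "DivisionModel",
    "InitialPloidyDistribution",
    "PloidyTrajectorySet",
    "AsynchronyEnvelope",
    "simulate_cell",
    "simulate_population",
    "asynchrony_envelope",
]


def _is_power_of_two(x: float) -> bool:
    if x <= 0:
        return False
    k = math.log2(x)
    return abs(k - round(k)) < 1e-9


@dataclass(frozen=True)
class DivisionModel:
    """Timer parameters: mean nuclear doubling time (hours) and its
    cell-to-cell coefficient of variation.

    The standard deviation of division intervals is ``cv * mean_doubling_time``.
    """

    mean_doubling_time: float = 11.0
    cv: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean_doubling_time > 0:
            raise InvalidInputError(
                f"mean_doubling_time must be > 0, got {self.mean_doubling_time}"
            )
        if self.cv < 0:
            raise InvalidInputError(f"cv must be >= 0, got {self.cv}")

    @property
    def interval_sd(self) -> float:
        """Standard deviation of a single division interval, in hours."""
        return self.cv * self.mean_doubling_time


@dataclass(frozen=True)
class InitialPloidyDistribution:
    """Population mixture over starting DNA contents (C units).

    Ploidies must be exact powers of two (1C, 2C, 4C, ...) and fractions must
    sum to 1.  The default matches a starvation-synchronized culture at
    release: a mixture of 1C, 2C and 4C cells.
    """

    fractions: Mapping[float, float] = field(
        default_factory=lambda: {1.0: 0.25, 2.0: 0.50, 4.0: 0.25}
    )

    def __post_init__(self) -> None:
        if not self.fractions:
            raise InvalidInputError("initial distribution is empty")
        for p, f in self.fractions.items():
            if not _is_power_of_two(p) or p < 1:
                raise InvalidInputError(f"ploidy {p} is not a power of two >= 1")
            if f < 0:
                raise InvalidInputError(f"negative fraction {f} for ploidy {p}")
        total = float(sum(self.fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(f"fractions sum to {total}, expected 1")

    @property
    def ploidies(self) -> np.ndarray:
        return np.array(sorted(self.fractions), dtype=float)

    def apportion(self, n_cells: int) -> np.ndarray:
        """Deterministic largest-remainder apportionment of ``n_cells``
        over the mixture; removes multinomial sampling noise from the
        population's initial state."""
        ploidies = self.ploidies
        fracs = np.array([self.fractions[p] for p in ploidies])
        ideal = fracs * n_cells
        counts = np.floor(ideal).astype(int)
        remainder = n_cells - counts.sum()
        if remainder > 0:
            order = np.argsort(-(ideal - counts), kind="stable")
            counts[order[:remainder]] += 1
        return np.repeat(ploidies, counts)

    def sample(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        """Multinomial draw of initial ploidies (the stochastic alternative
        to :meth:`apportion`)."""
        ploidies = self.ploidies
        fracs = np.array([self.fractions[p] for p in ploidies])
        counts = rng.multinomial(n_cells, fracs / fracs.sum())
        return np.repeat(ploidies, counts)

    def log2_geommean(self) -> float:
        return float(
            sum(f * math.log2(p) for p, f in self.fractions.items())
        )


@dataclass(frozen=True)
class PloidyTrajectorySet:
    """Realized population: per-cell ploidy (C units) over a shared time grid.

    ``ploidies`` has shape (n_cells, n_times); every value is a power of two
    and each row is non-decreasing.
    """

    time_grid: np.ndarray
    ploidies: np.ndarray
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.ploidies.shape[0]

    def log2(self) -> np.ndarray:
        return np.log2(self.ploidies)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns cell_id, time_h, ploidy_c."""
        n, t = self.ploidies.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n), t),
                "time_h": np.tile(self.time_grid, n),
                "ploidy_c": self.ploidies.ravel(),
            }
        )


@dataclass(frozen=True)
class AsynchronyEnvelope:
    """Replicate summary of simulated asynchrony growth for one CV.

    ``mean_delta_log2gsd`` / ``sd_delta_log2gsd`` are the across-replicate
    mean and SD of log2(GSD) after per-replicate subtraction of the t = 0
    baseline, so the mean is exactly 0 at t = 0.
    """

    time_grid: np.ndarray
    mean_delta_log2gsd: np.ndarray
    sd_delta_log2gsd: np.ndarray
    n_replicates: int
    cv: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_grid,
                "mean_delta_log2gsd": self.mean_delta_log2gsd,
                "sd_delta_log2gsd": self.sd_delta_log2gsd,
                "cv": self.cv,
                "n_replicates": self.n_replicates,
            }
        )


def _draw_intervals(
    rng: np.random.Generator, mean: float, sd: float, shape: tuple[int, ...]
) -> np.ndarray:
    """Normal division intervals; non-positive draws are redrawn (they are
    astronomically rare at CV <= 0.15 but would break the renewal process)."""
    iv = rng.normal(mean, sd, size=shape)
    if sd > 0:
        while True:
            bad = iv <= 0
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            iv[bad] = rng.normal(mean, sd, size=n_bad)
    return iv


def simulate_cell(
    model: DivisionModel,
    initial_ploidy: float,
    t_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Division times of a single cell on (0, t_max].

    The cell starts a fresh interval at t = 0 (starvation-synchronized
    release); interval k is an independent Normal(mean, cv*mean) draw.  The
    cell's ploidy at time t is ``initial_ploidy * 2**(divisions <= t)``.
    """
    if not _is_power_of_two(initial_ploidy) or initial_ploidy < 1:
        raise InvalidInputError(
            f"initial ploidy {initial_ploidy} is not a power of two >= 1"
        )
    if not t_max > 0:
        raise InvalidInputError(f"t_max must be > 0, got {t_max}")
    mean, sd = model.mean_doubling_time, model.interval_sd
    times: list[float] = []
    t = 0.0
    while True:
        t += float(_draw_intervals(rng, mean, sd, (1,))[0])
        if t > t_max:
            break
        times.append(t)
    return np.asarray(times)


def _interval_matrix(
    model: DivisionModel, n_cells: int, t_max: float, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative division times, one row per cell, guaranteed to extend
    beyond t_max for every cell."""
    mean, sd = model.mean_doubling_time, model.interval_sd
    m = int(np.ceil(t_max / mean)) + 6
    iv = _draw_intervals(rng, mean, sd, (n_cells, m))
    ct = np.cumsum(iv, axis=1)
    while ct[:, -1].min() <= t_max:  # pragma: no cover - needs extreme cv
        extra = _draw_intervals(rng, mean, sd, (n_cells, 4))
        ct = np.hstack([ct, ct[:, -1:] + np.cumsum(extra, axis=1)])
    return ct


def simulate_population(
    model: DivisionModel,
    init: InitialPloidyDistribution,
    n_cells: int,
    time_grid: np.ndarray,
    seed: int | np.random.SeedSequence = 0,
    multinomial_init: bool = False,
) -> PloidyTrajectorySet:
    """Evolve ``n_cells`` independent timer-driven cells over ``time_grid``.

    Initial ploidies are apportioned deterministically from ``init``
    (largest-remainder rounding) unless ``multinomial_init`` is set.  A
    division falling exactly on a grid time counts (ploidy(t) includes
    divisions with time <= t).
    """
    if n_cells < 1:
        raise InvalidInputError(f"n_cells must be >= 1, got {n_cells}")
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0:
        raise InvalidInputError("time grid is empty")
    if np.any(np.diff(time_grid) <= 0) or time_grid[0] != 0:
        raise InvalidInputError("time grid must be sorted, start at 0")
    seed_seq = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(seed_seq)
    initial = (
        init.sample(n_cells, rng) if multinomial_init else init.apportion(n_cells)
    )
    ct = _interval_matrix(model, n_cells, float(time_grid[-1]), rng)
    # divisions completed by each grid time, closed on the right
    n_div = (ct[:, :, None] <= time_grid[None, None, :]).sum(axis=1)
    ploidies = initial[:, None] * np.exp2(n_div)
    root = seed if isinstance(seed, int) else None
    return PloidyTrajectorySet(time_grid=time_grid, ploidies=ploidies, seed=root)


def asynchrony_envelope(
    model: DivisionModel,
    init: InitialPloidyDistribution,
    n_cells: int = 5000,
    n_replicates: int = 100,
    time_grid: np.ndarray | None = None,
    seed: int = 0,
    multinomial_init: bool = False,
) -> AsynchronyEnvelope:
    """Replicate-averaged growth of population asynchrony for one CV.

    For each replicate population, log2(GSD) of the exact ploidy histogram is
    computed at every grid time and the t = 0 value is subtracted; the mean
    and SD across replicates form the envelope.  The default grid mirrors a
    3-hourly sampling of the growth phase (0-48 h).
    """
    from . import flowstats  # local import to avoid a cycle at import time

    if n_replicates < 2:
        raise InvalidInputError(f"n_replicates must be >= 2, got {n_replicates}")
    if time_grid is None:
        time_grid = np.arange(0.0, 48.0 + 1e-9, 3.0)
    time_grid = np.asarray(time_grid, dtype=float)
    deltas = np.empty((n_replicates, time_grid.size))
    for rep in range(n_replicates):
        rep_seq = np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
        pop = simulate_population(
            model, init, n_cells, time_grid, seed=rep_seq,
            multinomial_init=multinomial_init,
        )
        gsd = np.array(
            [
                flowstats.log2_gsd(flowstats.histogram_from_ploidies(col))
                for col in pop.ploidies.T
            ]
        )
        deltas[rep] = gsd - gsd[0]
    return AsynchronyEnvelope(
        time_grid=time_grid,
        mean_delta_log2gsd=deltas.mean(axis=0),
        sd_delta_log2gsd=deltas.std(axis=0, ddof=0),
        n_replicates=n_replicates,
        cv=model.cv,
    )
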