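"""Generative model of a coenocytic growth experiment with known ground
truth.

The generator emulates every measurement the analysis modules consume, so
the whole pipeline runs and is testable without external data:

* **Nuclear timing** — each starting cell runs the division timer of
  :mod:`coenocycle.simulator` (Normal i.i.d. intervals, default mean 11 h,
  CV 0.10) from a starvation-synchronized 1C/2C/4C mixture.  The realized
  division times are *shared across media levels*: nutrient concentration
  affects volume growth only.  This decoupling of the nuclear timer from
  growth is the structural claim the synthetic experiment encodes.
* **Burst** — each coenocyte carries a cellularization threshold of 64C or
  128C (equal odds).  A cell that reaches its threshold is capped there
  (cellularized); it bursts inside the 48-72 h window, releasing newborn
  cells of 2C (or 4C) that share the mother's volume equally and resume
  dividing on a fresh timer.
* **Volume** — exponential growth at a media-dependent specific rate,
  strictly increasing with nutrient concentration.
* **Instrument noise** — DAPI intensity = reference x ploidy x log-normal
  noise; side scatter is a power law of volume (exponent 2/3,
  surface-like scattering) with log-normal noise; a small fraction of
  debris events with sub-1C intensity exercises the debris-flagging path.

Outputs are the exact table dialects consumed by
:mod:`coenocycle.flowstats` and :mod:`coenocycle.sizestats`, plus a
:class:`GroundTruth` record (division times, burst times, thresholds,
growth rates) that tests use as the oracle and analysis code never reads.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, InvalidInputError
from .simulator import (
    DivisionModel,
    InitialPloidyDistribution,
    _interval_matrix,
)

__all__ = [
    "ExperimentConfig",
    "GroundTruth",
    "SyntheticExperiment",
    "media_label",
    "generate_experiment",
    "generate_mixed_calibration_sample",
    "write_experiment",
]


def media_label(level: float) -> str:
    """Human-readable media concentration label (1 -> '1x', 0.25 -> '1/4x')."""
    if level <= 0:
        raise InvalidInputError("media level must be > 0")
    if level >= 1:
        return f"{level:g}x"
    inv = 1.0 / level
    return f"1/{inv:g}x"


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of a synthetic coenocytic growth experiment.

    Defaults reproduce the study conditions: ~5,000 events per flow
    measurement, sampling every 12 h out to 72 h, an 11 h timer with 10%
    cell-to-cell CV, burst between 48 and 72 h at 64-128 nuclei, newborn
    cells mostly binucleate, and four media concentrations (1x to 1/16x)
    whose volume growth rates rise strictly with nutrient concentration.
    The 1x rate (0.043 / h on volume) lets a newborn roughly double its
    projected area within ~24 h; lower levels are ordinal stand-ins, not
    fitted estimates.
    """

    division_model: DivisionModel = field(
        default_factory=lambda: DivisionModel(11.0, 0.10)
    )
    initial_distribution: InitialPloidyDistribution = field(
        default_factory=InitialPloidyDistribution
    )
    media_levels: tuple[float, ...] = (1.0, 0.5, 0.25, 0.0625)
    volume_growth_rates: Mapping[float, float] = field(
        default_factory=lambda: {1.0: 0.043, 0.5: 0.033, 0.25: 0.025, 0.0625: 0.012}
    )
    newborn_volume_um3: float = 525.0  # ~5 um radius newborn
    initial_volume_cv: float = 0.15
    burst_ploidies: tuple[float, ...] = (64.0, 128.0)
    burst_window_h: tuple[float, float] = (48.0, 72.0)
    newborn_ploidy_weights: Mapping[float, float] = field(
        default_factory=lambda: {2.0: 0.8, 4.0: 0.2}
    )
    intensity_reference: float = 100.0
    intensity_cv: float = 0.07
    ssc_scale: float = 10.0
    ssc_exponent: float = 2.0 / 3.0
    ssc_cv: float = 0.10
    debris_fraction: float = 0.02
    events_per_timepoint: int = 5000
    microscopy_cells_per_timepoint: int = 200
    radius_measurement_cv: float = 0.02
    timelapse_cells_per_condition: int = 40
    timelapse_duration_h: float = 36.0
    timelapse_step_h: float = 0.25
    area_noise_cv: float = 0.02
    sample_times_h: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0)
    n_cells: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        levels = sorted(self.media_levels)
        rates = [self.volume_growth_rates.get(lv) for lv in levels]
        if any(r is None for r in rates):
            raise InvalidConfigError("every media level needs a growth rate")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise InvalidConfigError(
                "volume growth rates must increase strictly with media level"
            )
        for p in self.burst_ploidies:
            k = math.log2(p)
            if abs(k - round(k)) > 1e-9:
                raise InvalidConfigError(f"burst ploidy {p} is not a power of two")
        if not self.burst_window_h[0] < self.burst_window_h[1]:
            raise InvalidConfigError("burst window must be an increasing interval")
        if self.burst_window_h[1] > max(self.sample_times_h):
            raise InvalidConfigError("burst window extends past the horizon")
        for name in ("intensity_cv", "ssc_cv", "initial_volume_cv",
                     "radius_measurement_cv", "area_noise_cv"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not 0 <= self.debris_fraction < 1:
            raise InvalidConfigError("debris_fraction must be in [0, 1)")
        wsum = sum(self.newborn_ploidy_weights.values())
        if abs(wsum - 1.0) > 1e-9:
            raise InvalidConfigError("newborn ploidy weights must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["division_model"] = {
            "mean_doubling_time": self.division_model.mean_doubling_time,
            "cv": self.division_model.cv,
        }
        d["initial_distribution"] = {
            str(k): v for k, v in self.initial_distribution.fractions.items()
        }
        d["volume_growth_rates"] = {
            str(k): v for k, v in self.volume_growth_rates.items()
        }
        d["newborn_ploidy_weights"] = {
            str(k): v for k, v in self.newborn_ploidy_weights.items()
        }
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Per-cell generative record: the oracle for pipeline tests.

    ``division_times[i]`` are the mother's realized division times (shared
    across media); ``burst_time_h`` is NaN for cells that never burst.
    Newborn counts obey nuclei conservation:
    ``newborn_count = burst threshold / newborn ploidy``.
    """

    initial_ploidy: np.ndarray
    division_times: list[np.ndarray]
    burst_threshold: np.ndarray
    burst_time_h: np.ndarray
    newborn_ploidy: np.ndarray
    newborn_count: np.ndarray
    newborn_division_times: list[np.ndarray]
    volume_growth_rates: Mapping[float, float]
    initial_volume_um3: Mapping[float, np.ndarray]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        n = self.initial_ploidy.size
        return pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "initial_ploidy_c": self.initial_ploidy,
                "burst_threshold_c": self.burst_threshold,
                "burst_time_h": self.burst_time_h,
                "newborn_ploidy_c": self.newborn_ploidy,
                "newborn_count": self.newborn_count,
                "division_times_h": [
                    ";".join(f"{t:.4f}" for t in dt) for dt in self.division_times
                ],
            }
        )


@dataclass(frozen=True)
class SyntheticExperiment:
    """Bundle of every synthetic measurement table plus its ground truth."""

    events: pd.DataFrame
    cells: pd.DataFrame
    areas: pd.DataFrame
    truth: GroundTruth
    config: ExperimentConfig


def _timing_backbone(config: ExperimentConfig):
    """Division schedule shared by all media levels.

    Returns per-mother cumulative division times (uncapped), burst
    thresholds, the time each mother reaches its threshold, burst times,
    newborn cohort ploidies/counts and newborn division times.
    """
    model = config.division_model
    n = config.n_cells
    horizon = max(config.sample_times_h)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(0,)))
    initial = config.initial_distribution.apportion(n)
    ct = _interval_matrix(model, n, horizon + model.mean_doubling_time, rng)
    thresholds = rng.choice(np.asarray(config.burst_ploidies, dtype=float), size=n)
    max_divs = np.round(np.log2(thresholds / initial)).astype(int)
    reach = ct[np.arange(n), max_divs - 1]
    w0, w1 = config.burst_window_h
    burst = np.where(reach <= w1, np.maximum(reach, w0), np.nan)
    nb_ploidies = np.asarray(sorted(config.newborn_ploidy_weights), dtype=float)
    nb_w = np.array([config.newborn_ploidy_weights[p] for p in nb_ploidies])
    newborn_ploidy = rng.choice(nb_ploidies, size=n, p=nb_w / nb_w.sum())
    newborn_ploidy = np.where(np.isnan(burst), np.nan, newborn_ploidy)
    newborn_count = np.where(
        np.isnan(burst), 0, thresholds / np.where(np.isnan(newborn_ploidy), 1,
                                                  newborn_ploidy)
    ).astype(int)
    # newborn cohorts restart the timer at burst; a short interval matrix
    # suffices (they cannot reach their own threshold before the horizon)
    nb_ct = _interval_matrix(model, n, horizon + model.mean_doubling_time, rng)
    division_times = [ct[i, : max_divs[i]] for i in range(n)]
    nb_division = [
        burst[i] + nb_ct[i][nb_ct[i] + burst[i] <= horizon]
        if not np.isnan(burst[i])
        else np.array([])
        for i in range(n)
    ]
    return initial, ct, thresholds, max_divs, burst, newborn_ploidy, \
        newborn_count, nb_division, division_times


def _population_at(
    t: float,
    initial: np.ndarray,
    ct: np.ndarray,
    max_divs: np.ndarray,
    burst: np.ndarray,
    newborn_ploidy: np.ndarray,
    newborn_count: np.ndarray,
    nb_division: list[np.ndarray],
    v0: np.ndarray,
    rate: float,
):
    """Alive units at time t: (ploidy, volume, multiplicity) arrays.

    Mothers that have burst by t are replaced by their newborn cohort
    (multiplicity = cohort size); newborn volume is the mother's burst
    volume split equally, growing at the media rate afterwards.
    """
    n = initial.size
    n_div = (ct <= t).sum(axis=1)
    mother_ploidy = initial * np.exp2(np.minimum(n_div, max_divs))
    mother_vol = v0 * np.exp(rate * t)
    is_burst = ~np.isnan(burst) & (burst <= t)
    ploidy = mother_ploidy.copy()
    vol = mother_vol.copy()
    mult = np.ones(n)
    if is_burst.any():
        idx = np.nonzero(is_burst)[0]
        nb_divs = np.array([(nb_division[i] <= t).sum() for i in idx])
        ploidy[idx] = newborn_ploidy[idx] * np.exp2(nb_divs)
        vol_at_burst = v0[idx] * np.exp(rate * burst[idx])
        vol[idx] = (vol_at_burst / newborn_count[idx]) * np.exp(
            rate * (t - burst[idx])
        )
        mult[idx] = newborn_count[idx]
    return ploidy, vol, mult


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with median 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def generate_experiment(config: ExperimentConfig | None = None) -> SyntheticExperiment:
    """Generate the full synthetic experiment for every media level.

    Returns event tables for each (time, media) sample, a microscopy table
    (nuclei counts and radii), time-lapse area series, and the generative
    ground truth.  All outputs are reproducible from ``config.seed``.
    """
    config = config or ExperimentConfig()
    (initial, ct, thresholds, max_divs, burst, newborn_ploidy,
     newborn_count, nb_division, division_times) = _timing_backbone(config)
    n = config.n_cells
    event_frames = []
    cell_frames = []
    area_frames = []
    init_volumes: dict[float, np.ndarray] = {}
    for m_idx, level in enumerate(config.media_levels):
        rate = config.volume_growth_rates[level]
        label = media_label(level)
        rng_vol = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1, m_idx))
        )
        # starved starting cells: newborn-like volume scaled by ploidy
        v0 = (
            config.newborn_volume_um3
            * (initial / 2.0)
            * _lognormal_factor(rng_vol, config.initial_volume_cv, n)
        )
        init_volumes[level] = v0
        for t_idx, t in enumerate(config.sample_times_h):
            ploidy, vol, mult = _population_at(
                t, initial, ct, max_divs, burst, newborn_ploidy,
                newborn_count, nb_division, v0, rate,
            )
            rng_ev = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed,
                                       spawn_key=(2, m_idx, t_idx))
            )
            k = config.events_per_timepoint
            pick = rng_ev.choice(n, size=k, p=mult / mult.sum())
            ev_ploidy = ploidy[pick]
            ev_vol = vol[pick]
            dapi = (
                config.intensity_reference
                * ev_ploidy
                * _lognormal_factor(rng_ev, config.intensity_cv, k)
            )
            ssc = (
                config.ssc_scale
                * ev_vol ** config.ssc_exponent
                * _lognormal_factor(rng_ev, config.ssc_cv, k)
            )
            n_debris = rng_ev.binomial(k, config.debris_fraction)
            if n_debris:
                dj = rng_ev.choice(k, size=n_debris, replace=False)
                lo = 0.05 * config.intensity_reference
                hi = 0.7 * config.intensity_reference
                dapi[dj] = np.exp(
                    rng_ev.uniform(math.log(lo), math.log(hi), n_debris)
                )
                ssc[dj] = ssc.min() * rng_ev.uniform(0.2, 1.0, n_debris)
            event_frames.append(
                pd.DataFrame(
                    {
                        "event_id": [f"{label}_t{t:g}_{i}" for i in range(k)],
                        "dapi_intensity": dapi,
                        "ssc": ssc,
                        "time_h": t,
                        "condition": label,
                    }
                )
            )
            # microscopy sample at the same time point
            rng_mic = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed,
                                       spawn_key=(3, m_idx, t_idx))
            )
            km = config.microscopy_cells_per_timepoint
            pick_m = rng_mic.choice(n, size=km, p=mult / mult.sum())
            radius = (3.0 * vol[pick_m] / (4.0 * np.pi)) ** (1.0 / 3.0)
            radius = radius * _lognormal_factor(
                rng_mic, config.radius_measurement_cv, km
            )
            cell_frames.append(
                pd.DataFrame(
                    {
                        "cell_id": [f"{label}_t{t:g}_c{i}" for i in range(km)],
                        "n_nuclei": ploidy[pick_m].astype(int),
                        "radius_um": radius,
                        "time_h": t,
                        "condition": label,
                    }
                )
            )
        # time-lapse of the first cells; the horizon precedes any burst
        rng_tl = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(4, m_idx))
        )
        tl_times = np.arange(
            0.0, config.timelapse_duration_h + 1e-9, config.timelapse_step_h
        )
        n_tl = min(config.timelapse_cells_per_condition, n)
        for i in range(n_tl):
            vol_t = v0[i] * np.exp(rate * tl_times)
            area = np.pi * (3.0 * vol_t / (4.0 * np.pi)) ** (2.0 / 3.0)
            area = area * _lognormal_factor(
                rng_tl, config.area_noise_cv, tl_times.size
            )
            area_frames.append(
                pd.DataFrame(
                    {
                        "cell_id": f"{label}_tl{i}",
                        "time_h": tl_times,
                        "area_um2": area,
                        "condition": label,
                    }
                )
            )
    truth = GroundTruth(
        initial_ploidy=initial,
        division_times=division_times,
        burst_threshold=thresholds,
        burst_time_h=burst,
        newborn_ploidy=newborn_ploidy,
        newborn_count=newborn_count,
        newborn_division_times=nb_division,
        volume_growth_rates=dict(config.volume_growth_rates),
        initial_volume_um3=init_volumes,
        seed=config.seed,
    )
    events = pd.concat(event_frames, ignore_index=True)
    cells = pd.concat(cell_frames, ignore_index=True)
    cells["volume_um3"] = (4.0 / 3.0) * np.pi * cells["radius_um"] ** 3
    areas = pd.concat(area_frames, ignore_index=True)
    return SyntheticExperiment(
        events=events, cells=cells, areas=areas, truth=truth, config=config
    )


def generate_mixed_calibration_sample(
    config: ExperimentConfig | None = None,
    n_events: int = 5000,
) -> tuple[pd.DataFrame, float]:
    """Pooled sample spanning every DNA-content stage, for peak calibration.

    Events are spread uniformly over all power-of-two bins from 1C to the
    maximum burst ploidy (as if samples from every stage of the coenocytic
    cycle were co-stained), with the configured intensity noise.  Returns
    the event table and the ground-truth reference intensity.
    """
    config = config or ExperimentConfig()
    if n_events < 100:
        raise InvalidInputError("need at least 100 events to calibrate")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(5,))
    )
    max_p = max(config.burst_ploidies)
    bins = 2.0 ** np.arange(0, int(round(math.log2(max_p))) + 1)
    ploidy = np.repeat(bins, math.ceil(n_events / bins.size))[:n_events]
    dapi = (
        config.intensity_reference
        * ploidy
        * _lognormal_factor(rng, config.intensity_cv, n_events)
    )
    ssc = config.ssc_scale * (100.0 * ploidy) ** config.ssc_exponent
    df = pd.DataFrame(
        {
            "event_id": [f"mix_{i}" for i in range(n_events)],
            "dapi_intensity": dapi,
            "ssc": ssc,
            "time_h": 0.0,
            "condition": "mixed",
        }
    )
    return df, config.intensity_reference


def write_experiment(exp: SyntheticExperiment, outdir) -> dict:
    """Serialize an experiment bundle to ``outdir``.

    Writes events.tsv, cells.csv, areas.csv, truth.tsv (ground truth,
    never read by analysis code) and manifest.json (config + seed).
    Returns the manifest dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    exp.events.to_csv(out / "events.tsv", sep="\t", index=False)
    exp.cells.to_csv(out / "cells.csv", index=False)
    exp.areas.to_csv(out / "areas.csv", index=False)
    exp.truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest = {
        "config": exp.config.to_dict(),
        "seed": exp.config.seed,
        "files": ["events.tsv", "cells.csv", "areas.csv", "truth.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
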