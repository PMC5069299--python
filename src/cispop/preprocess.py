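"""Spike-train preprocessing: smoothing, trial averaging, screening,
soft normalization, and assembly of the labeled analysis matrix.

The conventions follow common practice for motor-cortex population
analyses: spike trains are smoothed with a 28 ms SD Gaussian, averaged over
trials of the same condition in two alignments (target onset and movement
onset), screened so that each retained unit's firing-rate range exceeds its
maximal SEM, and soft-normalized (rate divided by range + 5 spikes/s)
before any dimensionality reduction.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d

from .containers import SEG_MOVE, SEG_TARGET, LabeledDataMatrix, PopulationResponse, SingleTrialDataset

__all__ = [
    "smooth_spikes",
    "smooth_counts",
    "trial_average",
    "snr_screen",
    "soft_normalize",
    "invert_soft_normalize",
    "build_data_matrix",
]

LONG_DELAY_CONTINUOUS = 450.0  # ms; ">450 ms" rule for continuous-delay data


def _kernel(sd_ms: float, dt_ms: float) -> np.ndarray:
    """Unit-area Gaussian kernel truncated at +/- 4 SD."""
    if sd_ms <= 0:
        raise ValueError("smoothing SD must be positive")
    half = max(1, int(np.ceil(4.0 * sd_ms / dt_ms)))
    t = np.arange(-half, half + 1) * dt_ms
    k = np.exp(-0.5 * (t / sd_ms) ** 2)
    return k / k.sum()


def smooth_counts(counts: np.ndarray, sd_ms: float, dt_ms: float,
                  renormalize_edges: bool = True) -> np.ndarray:
    """Gaussian-smooth binned spike counts along the last axis -> spikes/s.

    The kernel is truncated at +/-4 SD; when ``renormalize_edges`` is set
    the output is divided, per bin, by the kernel mass falling inside the
    window so rates near the epoch edges are unbiased (no reflection).
    """
    k = _kernel(sd_ms, dt_ms)
    sm = convolve1d(counts, k, axis=-1, mode="constant", cval=0.0)
    if renormalize_edges:
        mass = convolve1d(np.ones(counts.shape[-1]), k, mode="constant", cval=0.0)
        sm = sm / mass
    return sm / (dt_ms / 1000.0)


def smooth_spikes(spike_times: np.ndarray, grid: np.ndarray, sd_ms: float = 28.0,
                  renormalize_edges: bool = True) -> np.ndarray:
    """Smooth a single spike train onto ``grid`` (bin centers, ms).

    Returns a rate trace in spikes/s.  An empty spike train yields zeros.
    """
    grid = np.asarray(grid, float)
    dt = float(grid[1] - grid[0])
    edges = np.concatenate([grid - dt / 2.0, [grid[-1] + dt / 2.0]])
    counts, _ = np.histogram(np.asarray(spike_times, float), bins=edges)
    return smooth_counts(counts.astype(float), sd_ms, dt, renormalize_edges)


def _aligned_psth(trials: SingleTrialDataset, grid: np.ndarray, align: np.ndarray,
                  sd_ms: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-condition mean and SEM of smoothed rates on ``grid``."""
    dt = float(grid[1] - grid[0])
    edges = np.concatenate([grid - dt / 2.0, [grid[-1] + dt / 2.0]])
    conds = np.unique(trials.condition)
    n_c = conds.size
    mean = np.zeros((trials.n_units, n_c, grid.size))
    sem = np.zeros_like(mean)
    counts_per_cond = np.zeros(n_c, int)
    for j, c in enumerate(conds):
        sub = trials.select(trials.condition == c)
        counts_per_cond[j] = sub.n_trials
        if sub.n_trials == 0:
            continue
        binned = sub.bin_counts(edges, align=align[trials.condition == c])
        rates = smooth_counts(binned, sd_ms, dt)
        mean[:, j, :] = rates.mean(axis=0)
        if sub.n_trials >= 2:
            sem[:, j, :] = rates.std(axis=0, ddof=1) / np.sqrt(sub.n_trials)
    return mean, sem, counts_per_cond


def trial_average(trials: SingleTrialDataset,
                  target_grid: np.ndarray,
                  move_grid: np.ndarray,
                  sd_ms: float = 28.0,
                  delays: object = "long") -> PopulationResponse:
    """Average single trials into a dual-alignment :class:`PopulationResponse`.

    ``delays`` selects trials before averaging: ``"long"`` keeps trials with
    delay > 450 ms or exactly 500 ms (the long-delay fitting set), ``"all"``
    keeps everything, a number keeps that exact delay, and a sequence keeps
    the listed delays.  Conditions with zero retained trials are flagged in
    ``meta['empty_conditions']``.
    """
    if delays == "long":
        mask = (trials.delay > LONG_DELAY_CONTINUOUS) | (trials.delay == 500.0)
    elif delays == "all":
        mask = np.ones(trials.n_trials, bool)
    elif np.isscalar(delays):
        mask = trials.delay == float(delays)
    else:
        mask = np.isin(trials.delay, np.asarray(delays, float))
    sub = trials.select(mask)
    if sub.n_trials == 0:
        raise ValueError("no trials match the requested delay filter")
    tgt_mean, tgt_sem, n_per = _aligned_psth(sub, np.asarray(target_grid, float),
                                             align=np.zeros(sub.n_trials), sd_ms=sd_ms)
    mov_mean, mov_sem, _ = _aligned_psth(sub, np.asarray(move_grid, float),
                                         align=sub.move_time, sd_ms=sd_ms)
    empty = np.flatnonzero(n_per == 0)
    if empty.size:
        import warnings

        warnings.warn(f"conditions with no trials excluded from averaging: {empty.tolist()}")
    pop = PopulationResponse(
        target_rates=tgt_mean, move_rates=mov_mean,
        target_time=np.asarray(target_grid, float),
        move_time=np.asarray(move_grid, float),
        target_sem=tgt_sem, move_sem=mov_sem,
        meta={"kind": "trial_average", "n_trials_per_condition": n_per,
              "empty_conditions": empty.tolist()},
    )
    pop.validate()
    return pop


def snr_screen(population: PopulationResponse) -> np.ndarray:
    """Boolean mask of units whose rate range exceeds their maximal SEM.

    The range is taken over all conditions and times in both alignments;
    the comparison is a strict inequality, so a flat unit (range 0) is
    dropped for any positive SEM, as is a unit whose range exactly ties its
    maximal SEM.
    """
    if population.target_sem is None or population.move_sem is None:
        raise ValueError("SNR screening requires SEMs (trial-resolved input)")
    flat = np.concatenate([population.target_rates.reshape(population.n_units, -1),
                           population.move_rates.reshape(population.n_units, -1)], axis=1)
    rng = flat.max(axis=1) - flat.min(axis=1)
    sem = np.concatenate([population.target_sem.reshape(population.n_units, -1),
                          population.move_sem.reshape(population.n_units, -1)], axis=1)
    return rng > sem.max(axis=1)


def apply_unit_mask(population: PopulationResponse, mask: np.ndarray) -> PopulationResponse:
    """Restrict a population to the units selected by ``mask``."""
    pop = PopulationResponse(
        target_rates=population.target_rates[mask],
        move_rates=population.move_rates[mask],
        target_time=population.target_time,
        move_time=population.move_time,
        target_sem=None if population.target_sem is None else population.target_sem[mask],
        move_sem=None if population.move_sem is None else population.move_sem[mask],
        meta=dict(population.meta),
        ground_truth=population.ground_truth,
    )
    pop.meta["unit_mask"] = np.asarray(mask)
    return pop


def soft_normalize(population: PopulationResponse, constant: float = 5.0):
    """Divide each unit by its firing-rate range plus ``constant``.

    Returns ``(normalized_population, record)`` where ``record`` holds the
    per-unit range, the per-unit raw mean, and the constant, sufficient to
    invert the normalization exactly.
    """
    if constant < 0:
        raise ValueError("soft-normalization constant must be >= 0")
    n = population.n_units
    flat = np.concatenate([population.target_rates.reshape(n, -1),
                           population.move_rates.reshape(n, -1)], axis=1)
    rng = flat.max(axis=1) - flat.min(axis=1)
    if constant == 0 and np.any(rng == 0):
        raise ZeroDivisionError("flat unit with constant=0; screen units first")
    denom = rng + constant
    record = {"range": rng, "constant": float(constant), "mean": flat.mean(axis=1)}
    pop = PopulationResponse(
        target_rates=population.target_rates / denom[:, None, None],
        move_rates=population.move_rates / denom[:, None, None],
        target_time=population.target_time,
        move_time=population.move_time,
        target_sem=None if population.target_sem is None
        else population.target_sem / denom[:, None, None],
        move_sem=None if population.move_sem is None
        else population.move_sem / denom[:, None, None],
        meta=dict(population.meta),
        ground_truth=population.ground_truth,
    )
    pop.meta["soft_norm"] = record
    return pop, record


def invert_soft_normalize(population: PopulationResponse, record: dict) -> PopulationResponse:
    denom = record["range"] + record["constant"]
    pop = population.copy()
    pop.target_rates = pop.target_rates * denom[:, None, None]
    pop.move_rates = pop.move_rates * denom[:, None, None]
    if pop.target_sem is not None:
        pop.target_sem = pop.target_sem * denom[:, None, None]
    if pop.move_sem is not None:
        pop.move_sem = pop.move_sem * denom[:, None, None]
    return pop


def _window_index(axis: np.ndarray, window: tuple[float, float], name: str) -> np.ndarray:
    lo, hi = window
    eps = 1e-9
    if lo < axis[0] - eps or hi > axis[-1] + eps:
        raise ValueError(
            f"{name} window [{lo}, {hi}] ms exceeds available data "
            f"[{axis[0]}, {axis[-1]}] ms"
        )
    return np.flatnonzero((axis >= lo - eps) & (axis <= hi + eps))


def build_data_matrix(population: PopulationResponse,
                      target_window: tuple[float, float] = (-200.0, 400.0),
                      move_window: tuple[float, float] = (-300.0, 600.0),
                      norm_constant: float = 5.0,
                      normalize: bool = True) -> LabeledDataMatrix:
    """Assemble the labeled analysis matrix from a population response.

    Rows are (condition, time) samples: for each condition, the samples of
    the target-aligned window (endpoints inclusive on the grid) followed by
    those of the movement-aligned window.  Units are soft-normalized unless
    ``normalize=False`` (in which case the normalization record holds the
    raw range with constant 0 applied as a no-op divisor of 1 — set by
    ``norm_range = 0``).
    """
    if normalize:
        pop, record = soft_normalize(population, norm_constant)
        norm_range, const = record["range"], record["constant"]
        unit_mean = record["mean"]
    else:
        pop = population
        n = population.n_units
        norm_range = np.zeros(n)
        const = 1.0
        flat = np.concatenate([population.target_rates.reshape(n, -1),
                               population.move_rates.reshape(n, -1)], axis=1)
        unit_mean = flat.mean(axis=1)
    it = _window_index(pop.target_time, target_window, "target")
    im = _window_index(pop.move_time, move_window, "move")
    tt, tm = pop.target_time[it], pop.move_time[im]
    n, C = pop.n_units, pop.n_conditions
    # (C, T_total, n) condition-major stacking
    block = np.concatenate([
        pop.target_rates[:, :, it].transpose(1, 2, 0),
        pop.move_rates[:, :, im].transpose(1, 2, 0),
    ], axis=1)
    T = block.shape[1]
    seg_seq = np.concatenate([np.full(it.size, SEG_TARGET, np.int8),
                              np.full(im.size, SEG_MOVE, np.int8)])
    time_seq = np.concatenate([tt, tm])
    dm = LabeledDataMatrix(
        R=block.reshape(C * T, n),
        condition=np.repeat(np.arange(C), T),
        time=np.tile(time_seq, C),
        segment=np.tile(seg_seq, C),
        norm_range=norm_range,
        norm_const=const,
        unit_mean=unit_mean,
        meta={"target_window": tuple(target_window), "move_window": tuple(move_window)},
    )
    dm.validate()
    return dm
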