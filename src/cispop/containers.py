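"""Core data containers shared across the analysis pipeline.

The pipeline operates on three in-memory objects:

``PopulationResponse``
    Trial-averaged firing rates (PSTHs) for a population of units across
    reach conditions, kept in two alignments: one time axis locked to target
    onset and one locked to movement onset.  Synthetic populations carry
    their generating ground truth alongside.

``SingleTrialDataset``
    Spike trains for individual trials together with the behavioral events
    (go cue, movement onset) and the reaction time of each trial.

``LabeledDataMatrix``
    The analysis matrix ``R`` used by the demixing machinery: one column per
    unit, one row per (condition, time) sample, with explicit row labels.
    Rows are ordered condition-major, and within each condition the
    target-aligned window precedes the movement-aligned window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationResponse",
    "SingleTrialDataset",
    "LabeledDataMatrix",
    "SEG_TARGET",
    "SEG_MOVE",
]

#: segment codes used in row labels
SEG_TARGET = 0
SEG_MOVE = 1


@dataclass
class PopulationResponse:
    """Per-unit trial-averaged firing rates in two alignments.

    Parameters
    ----------
    target_rates, move_rates
        Arrays of shape ``(n_units, n_conditions, n_time)`` in spikes/s.
    target_time, move_time
        Time axes in ms relative to target onset / movement onset.
    target_sem, move_sem
        Optional standard errors of the mean, same shapes as the rates.
    ground_truth
        For synthetic populations: the planted components, mixing weights
        and generator model (see :mod:`cispop.synthgen`).
    """

    target_rates: np.ndarray
    move_rates: np.ndarray
    target_time: np.ndarray
    move_time: np.ndarray
    target_sem: np.ndarray | None = None
    move_sem: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    @property
    def n_units(self) -> int:
        return self.target_rates.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.target_rates.shape[1]

    def validate(self) -> None:
        if self.target_rates.ndim != 3 or self.move_rates.ndim != 3:
            raise ValueError("rate arrays must be (units, conditions, time)")
        if self.target_rates.shape[:2] != self.move_rates.shape[:2]:
            raise ValueError("alignments disagree on units/conditions")
        if self.target_rates.shape[2] != self.target_time.size:
            raise ValueError("target time axis does not match rates")
        if self.move_rates.shape[2] != self.move_time.size:
            raise ValueError("move time axis does not match rates")
        for ax in (self.target_time, self.move_time):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("time axes must be strictly increasing")

    def copy(self) -> "PopulationResponse":
        return PopulationResponse(
            target_rates=self.target_rates.copy(),
            move_rates=self.move_rates.copy(),
            target_time=self.target_time.copy(),
            move_time=self.move_time.copy(),
            target_sem=None if self.target_sem is None else self.target_sem.copy(),
            move_sem=None if self.move_sem is None else self.move_sem.copy(),
            meta=dict(self.meta),
            ground_truth=self.ground_truth,
        )


@dataclass
class SingleTrialDataset:
    """Spike trains and behavioral events for individual trials.

    Spike times are stored per trial as a pair of parallel arrays: the unit
    index of each spike and its time in ms on the trial clock (target onset
    at 0 ms).  ``go_time`` equals the delay-period duration, ``move_time``
    is the movement onset, and ``rt = move_time - go_time``.
    """

    spike_units: list
    spike_times: list
    condition: np.ndarray
    delay: np.ndarray
    go_time: np.ndarray
    move_time: np.ndarray
    rt: np.ndarray
    n_units: int
    dt: float
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.condition.size

    def select(self, mask: np.ndarray) -> "SingleTrialDataset":
        """Subset of trials given a boolean mask or index array."""
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return SingleTrialDataset(
            spike_units=[self.spike_units[i] for i in idx],
            spike_times=[self.spike_times[i] for i in idx],
            condition=self.condition[idx],
            delay=self.delay[idx],
            go_time=self.go_time[idx],
            move_time=self.move_time[idx],
            rt=self.rt[idx],
            n_units=self.n_units,
            dt=self.dt,
            meta=dict(self.meta),
        )

    def bin_counts(self, edges: np.ndarray, align: np.ndarray) -> np.ndarray:
        """Spike counts of every trial on a common grid of bin ``edges``.

        ``align`` gives, per trial, the event time (on the trial clock) that
        maps to 0 ms of the grid.  Returns ``(n_trials, n_units, n_bins)``.
        """
        n_bins = edges.size - 1
        out = np.zeros((self.n_trials, self.n_units, n_bins))
        for i in range(self.n_trials):
            t = self.spike_times[i] - align[i]
            inside = (t >= edges[0]) & (t < edges[-1])
            if not np.any(inside):
                continue
            b = np.searchsorted(edges, t[inside], side="right") - 1
            np.add.at(out[i], (self.spike_units[i][inside], b), 1.0)
        return out


@dataclass
class LabeledDataMatrix:
    """The labeled analysis matrix ``R``.

    ``R`` has one column per unit and one row per (condition, time) sample;
    ``condition``, ``time`` and ``segment`` label the rows.  The soft
    normalization applied to each unit is recorded (``norm_range``,
    ``norm_const``) so it can be inverted, and the raw per-unit mean and
    range (in spikes/s) are kept for the affine restores used by the
    surrogate controls.
    """

    R: np.ndarray
    condition: np.ndarray
    time: np.ndarray
    segment: np.ndarray
    norm_range: np.ndarray
    norm_const: float
    unit_mean: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.R.shape[1]

    @property
    def n_conditions(self) -> int:
        return int(np.unique(self.condition).size)

    @property
    def samples_per_condition(self) -> int:
        return self.R.shape[0] // self.n_conditions

    def validate(self) -> None:
        rows = self.R.shape[0]
        if not (self.condition.size == self.time.size == self.segment.size == rows):
            raise ValueError("row labels must match matrix rows")
        if rows % self.n_conditions:
            raise ValueError("rows must form a full condition x time factorial")
        labels = np.stack([self.condition, self.segment, self.time.round(6)], axis=1)
        if np.unique(labels, axis=0).shape[0] != rows:
            raise ValueError("row labels are not unique")

    def as_tensor(self, M: np.ndarray | None = None) -> np.ndarray:
        """Reshape rows to ``(n_conditions, samples_per_condition, k)``."""
        A = self.R if M is None else M
        return A.reshape(self.n_conditions, self.samples_per_condition, A.shape[1])

    def segment_times(self) -> tuple[np.ndarray, np.ndarray]:
        """(segment, time) labels of the per-condition sample sequence."""
        s = self.samples_per_condition
        return self.segment[:s], self.time[:s]
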