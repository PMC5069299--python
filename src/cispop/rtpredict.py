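"""Single-trial reaction-time prediction from population projections.

The predictor follows a four-step recipe: (1) choose a dimension of
interest (CIS_1, PC_1, the mean over all units, a speed-decoding
dimension, or a supervised classifier axis); (2) bin and smooth each
trial's spikes (10 ms bins from -60 to +500 ms around the go cue, 30 ms SD
Gaussian); (3) project each trial onto the dimension; (4) take the first
post-go time the projection crosses a criterion — the midpoint of the
median long-delay trace — as the predicted movement-initiation time.
Trials that never cross, or that cross before the go cue, are excluded.
The criterion is always fitted on long-delay trials; applying it to
zero-delay trials tests pure generalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .containers import SEG_MOVE, LabeledDataMatrix, SingleTrialDataset
from .demix import Decomposition
from .preprocess import smooth_counts

__all__ = [
    "TrialProjection",
    "CriterionRule",
    "RTPredictionResult",
    "SpeedDecoder",
    "ClassifierModel",
    "prepare_trial_rates",
    "project_trials",
    "mean_over_units_weights",
    "compute_criterion",
    "predict_rt",
    "fit_speed_decoder",
    "fit_move_classifier",
    "classifier_influence",
    "cis_speed_correlation",
]

GO_WINDOW = (-60.0, 500.0)  # ms relative to go cue
BIN_MS = 10.0
TRIAL_SMOOTH_SD = 30.0


@dataclass
class TrialProjection:
    """Projected value per time bin per trial, plus trial bookkeeping."""

    z: np.ndarray  # (n_trials, n_bins)
    bins: np.ndarray  # bin centers, ms relative to go cue
    method: str
    weights: np.ndarray
    delay: np.ndarray
    rt: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]


@dataclass
class CriterionRule:
    """Criterion value derived from the median long-delay trace."""

    criterion: float
    median_trace: np.ndarray
    bins: np.ndarray
    sign: float = 1.0


@dataclass
class RTPredictionResult:
    """Per-trial crossing times and their correlation with behavioral RT."""

    crossing: np.ndarray  # ms after go cue; nan when excluded
    excluded: np.ndarray  # '', 'never', 'pre_go'
    r_by_delay: dict
    excluded_fraction: float
    slope: float
    intercept: float

    @property
    def usable(self) -> np.ndarray:
        return self.excluded == ""


@dataclass
class SpeedDecoder:
    weights: np.ndarray
    bias: float
    lead_ms: float
    fit_r: float


@dataclass
class ClassifierModel:
    weights: np.ndarray  # over decomposition components
    intercept: float
    accuracy: float
    premove_bin: tuple
    move_bin: tuple
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def prepare_trial_rates(trials: SingleTrialDataset,
                        window: tuple[float, float] = GO_WINDOW,
                        align: str = "go",
                        bin_ms: float = BIN_MS,
                        smooth_sd: float = TRIAL_SMOOTH_SD) -> tuple[np.ndarray, np.ndarray]:
    """Binned, smoothed single-trial rates around the go cue (or movement).

    Returns ``(rates, bin_centers)`` with rates of shape
    ``(n_trials, n_units, n_bins)`` in spikes/s.  The truncated Gaussian
    kernel is renormalized per bin at the window edges, so rates are
    unbiased there and a trial's total smoothed mass stays within a few
    percent of its in-window spike count.
    """
    event = trials.go_time if align == "go" else trials.move_time
    if np.any(~np.isfinite(event)):
        raise ValueError(f"trial missing {align} event time")
    edges = np.arange(window[0], window[1] + 0.5 * bin_ms, bin_ms)
    counts = trials.bin_counts(edges, align=event)
    rates = smooth_counts(counts, smooth_sd, bin_ms, renormalize_edges=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return rates, centers


def mean_over_units_weights(n_units: int) -> np.ndarray:
    """The mean-over-all-units dimension (all weights 1/n)."""
    return np.full(n_units, 1.0 / n_units)


def project_trials(rates: np.ndarray, bins: np.ndarray, weights: np.ndarray,
                   norm_range: np.ndarray, norm_const: float,
                   method: str, delay: np.ndarray, rt: np.ndarray) -> TrialProjection:
    """Weighted sum of soft-normalized single-trial rates.

    The same per-unit normalization used when fitting the dimension is
    applied to the trial rates before projection.
    """
    weights = np.asarray(weights, float)
    if rates.shape[1] != weights.size:
        raise ValueError("unit count mismatch between rates and weights")
    denom = norm_range + norm_const
    z = np.einsum("rut,u->rt", rates / denom[None, :, None], weights)
    return TrialProjection(z=z, bins=bins, method=method, weights=weights,
                           delay=np.asarray(delay), rt=np.asarray(rt))


def compute_criterion(long_delay: TrialProjection, min_trials: int = 10) -> CriterionRule:
    """Midpoint-of-median criterion from long-delay projections.

    The per-bin median across trials gives the template trace; the
    criterion is halfway between its extremes.  If the template *falls*
    rather than rises after the go cue, the dimension's sign is flipped
    before the criterion logic (recorded in ``sign``).
    """
    if long_delay.n_trials < min_trials:
        raise ValueError(f"need >= {min_trials} long-delay trials")
    med = np.median(long_delay.z, axis=0)
    post = long_delay.bins > 0
    start = med[post][0]
    sign = 1.0
    if (med[post].max() - start) < (start - med[post].min()):
        sign = -1.0
        med = -med
    lo, hi = float(med.min()), float(med.max())
    if hi - lo <= 0:
        raise ValueError("flat median trace: dimension is uninformative")
    return CriterionRule(criterion=(hi + lo) / 2.0, median_trace=med,
                         bins=long_delay.bins, sign=sign)


def _first_crossing(z: np.ndarray, bins: np.ndarray, criterion: float):
    """(crossing time, exclusion flag) for one trial trace."""
    pre = bins <= 0
    if np.any(z[pre] >= criterion):
        return np.nan, "pre_go"
    post_idx = np.flatnonzero(bins > 0)
    above = z[post_idx] >= criterion
    if not np.any(above):
        return np.nan, "never"
    k = post_idx[np.argmax(above)]
    if k == 0 or z[k - 1] >= criterion:
        return float(bins[k]), ""
    # linear interpolation between the bracketing bins
    frac = (criterion - z[k - 1]) / (z[k] - z[k - 1])
    return float(bins[k - 1] + frac * (bins[k] - bins[k - 1])), ""


def predict_rt(projection: TrialProjection, rule: CriterionRule,
               min_group: int = 3) -> RTPredictionResult:
    """Criterion-crossing RT prediction for every trial.

    Pearson correlations between crossing time and behavioral RT are
    computed per delay group; groups with fewer than ``min_group`` usable
    trials, or with zero crossing-time variance, are flagged with ``nan``.
    """
    z = projection.z * rule.sign
    n = projection.n_trials
    crossing = np.full(n, np.nan)
    excluded = np.empty(n, dtype=object)
    for i in range(n):
        crossing[i], excluded[i] = _first_crossing(z[i], projection.bins, rule.criterion)
    usable = excluded == ""
    r_by_delay = {}
    for d in np.unique(projection.delay):
        sel = usable & (projection.delay == d)
        if sel.sum() < min_group or np.std(crossing[sel]) == 0:
            r_by_delay[float(d)] = float("nan")
            continue
        r, _ = stats.pearsonr(crossing[sel], projection.rt[sel])
        r_by_delay[float(d)] = float(r)
    if usable.sum() >= 2 and np.std(crossing[usable]) > 0:
        slope, intercept = np.polyfit(crossing[usable], projection.rt[usable], 1)
    else:
        slope = intercept = float("nan")
    return RTPredictionResult(
        crossing=crossing, excluded=excluded, r_by_delay=r_by_delay,
        excluded_fraction=float(1.0 - usable.mean()),
        slope=float(slope), intercept=float(intercept),
    )


# ---------------------------------------------------------------------------
# speed decoding and the supervised classifier


def fit_speed_decoder(dm: LabeledDataMatrix, speed: np.ndarray,
                      move_time_axis: np.ndarray, lead_ms: float = 150.0,
                      ridge: float = 0.0) -> SpeedDecoder:
    """Least-squares regression of the (advanced) speed profile on ``R``.

    ``speed`` is (n_conditions, n_move_samples) on ``move_time_axis``; the
    profile is advanced by ``lead_ms`` (neural activity leads movement) and
    placed on the movement-aligned rows of the matrix; target-aligned rows
    regress against zero speed (the hand is at rest).  A rank-deficient
    system falls back to a small ridge with a warning.
    """
    s_rows = np.zeros(dm.R.shape[0])
    move_rows = dm.segment == SEG_MOVE
    t_move = dm.time[move_rows][dm.condition[move_rows] == 0]
    for c in range(dm.n_conditions):
        rows = move_rows & (dm.condition == c)
        adv = np.interp(dm.time[rows] + lead_ms, move_time_axis, speed[c],
                        left=speed[c][0], right=speed[c][-1])
        s_rows[rows] = adv
    A = np.column_stack([dm.R, np.ones(dm.R.shape[0])])
    if ridge > 0:
        AtA = A.T @ A + ridge * np.eye(A.shape[1])
        coef = np.linalg.solve(AtA, A.T @ s_rows)
    else:
        coef, _, rank, _ = np.linalg.lstsq(A, s_rows, rcond=None)
        if rank < A.shape[1]:
            import warnings

            warnings.warn("rank-deficient design; refitting with ridge 1e-6")
            return fit_speed_decoder(dm, speed, move_time_axis, lead_ms, ridge=1e-6)
    pred = A @ coef
    if np.std(pred) > 0 and np.std(s_rows) > 0:
        r = float(stats.pearsonr(pred, s_rows)[0])
    else:
        r = float("nan")
    return SpeedDecoder(weights=coef[:-1], bias=float(coef[-1]),
                        lead_ms=lead_ms, fit_r=r)


PREMOVE_BIN = (-360.0, -150.0)
MOVE_BIN = (-150.0, 60.0)


def fit_move_classifier(trials: SingleTrialDataset, dec: Decomposition,
                        norm_range: np.ndarray, norm_const: float,
                        C_reg: float = 1.0) -> ClassifierModel:
    """Logistic classifier separating premovement from movement activity.

    Each trial contributes two vectors of mean projections onto all
    decomposition components: one for the premovement bin (-360 to -150 ms
    relative to movement onset) and one for the movement bin (-150 to
    +60 ms).  The fitted axis lives in component space and can be mapped to
    unit space via ``dec.W @ weights`` for use as an RT-predicting
    dimension.  L2 regularization (strength ``C_reg``) keeps degenerate,
    perfectly separable inputs well posed.
    """
    rates, bins = prepare_trial_rates(trials, window=(PREMOVE_BIN[0], MOVE_BIN[1]),
                                      align="move")
    denom = norm_range + norm_const
    proj = np.einsum("rut,ud->rdt", rates / denom[None, :, None], dec.W)
    pre = (bins >= PREMOVE_BIN[0]) & (bins < PREMOVE_BIN[1])
    mov = (bins >= MOVE_BIN[0]) & (bins < MOVE_BIN[1])
    X = np.concatenate([proj[:, :, pre].mean(axis=2), proj[:, :, mov].mean(axis=2)])
    y = np.concatenate([np.zeros(trials.n_trials), np.ones(trials.n_trials)])
    clf = LogisticRegression(C=C_reg, max_iter=2000)
    clf.fit(X, y)
    acc = float(clf.score(X, y))
    return ClassifierModel(
        weights=clf.coef_[0], intercept=float(clf.intercept_[0]),
        accuracy=acc, premove_bin=PREMOVE_BIN, move_bin=MOVE_BIN,
        meta={"training_data": X, "labels": y},
    )


def classifier_influence(model: ClassifierModel, dec: Decomposition,
                         projected: np.ndarray | None = None):
    """Per-component influence ``|w_d| * var[(R W)_d]`` and the CIS share.

    ``projected`` defaults to the classifier's own training data; the CIS
    share is the summed influence of condition-invariant components over
    the total.
    """
    if projected is None:
        projected = model.meta["training_data"]
    var = projected.var(axis=0)
    influence = np.abs(model.weights) * var
    total = influence.sum()
    ci = dec.ci_indices
    share = float(influence[ci].sum() / total) if total > 0 else float("nan")
    return influence, share


def cis_speed_correlation(cis1_timecourse: np.ndarray,
                          speed: np.ndarray) -> tuple[float, float]:
    """Pearson correlation across conditions of peak |CIS_1| vs peak speed.

    ``cis1_timecourse`` is (n_conditions, T); ``speed`` likewise.  Needs at
    least 5 conditions; constant inputs are flagged with ``(nan, nan)``.
    """
    if cis1_timecourse.shape[0] < 5:
        raise ValueError("need >= 5 conditions for a meaningful correlation")
    peak_cis = np.abs(cis1_timecourse).max(axis=1)
    peak_speed = np.asarray(speed).max(axis=1)
    if np.std(peak_cis) == 0 or np.std(peak_speed) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(peak_speed, peak_cis)
    return float(r), float(p)
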