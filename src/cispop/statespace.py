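"""Rotational-plane identification and state-space geometry.

Within the condition-specific subspace found by the demixed decomposition,
population trajectories during the perimovement epoch rotate at roughly
2 Hz.  The dominant rotational plane is identified by fitting linear
dynamics ``dX/dt = X M`` with ``M`` constrained skew-symmetric (the
rotation-only analogue of jPCA, applied directly to the condition-specific
components with no extra PCA step or mean subtraction) and taking the real
2-D invariant subspace of the largest-frequency eigenvalue pair.  Combined
with the CIS_1 dimension this yields the canonical 3-D picture: delay-
period states at the narrow end of a cone, a condition-invariant
translation just before movement onset, and rotations at the wide end.
``neural_speed`` quantifies the rate of change of the state within a named
subspace, used to compare the timing of the CIS translation against the
rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SEG_MOVE, SEG_TARGET
from .demix import Decomposition

__all__ = [
    "RotationalPlane",
    "SpeedProfile",
    "fit_skew_symmetric",
    "fit_rotational_plane",
    "build_3d_projection",
    "neural_speed",
    "subspace_trajectories",
    "compare_peak_timing",
]

DEFAULT_EPOCH = (-200.0, 150.0)  # ms relative to movement onset


@dataclass
class RotationalPlane:
    """Two orthonormal dimensions spanning the strongest rotations."""

    plane_units: np.ndarray  # (n_units, 2), orthonormal, within CS subspace
    plane_components: np.ndarray  # (n_cs, 2) coordinates in CS-component space
    M: np.ndarray  # skew-symmetric dynamics matrix (CS-component space)
    eigenfrequency_hz: float
    epoch: tuple
    rotating: bool = True


@dataclass
class SpeedProfile:
    """Condition-averaged, max-normalized rate of change of the state."""

    speed: np.ndarray  # normalized trace in [0, 1]
    time: np.ndarray  # ms (move-aligned)
    peak_time: float
    raw_peak: float
    flagged: str = ""


def fit_skew_symmetric(X: np.ndarray, Xdot: np.ndarray) -> np.ndarray:
    """Least-squares skew-symmetric ``M`` minimizing ``||Xdot - X M||^2``.

    Solved exactly on the basis of elementary skew-symmetric matrices
    (k(k-1)/2 free parameters), which also serves as the brute-force
    parameterization the fit is validated against.
    """
    k = X.shape[1]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    n_par = len(pairs)
    # column b of the design: X @ (E_ij - E_ji) flattened over samples
    design = np.empty((X.shape[0] * k, n_par))
    for b, (i, j) in enumerate(pairs):
        D = np.zeros((X.shape[0], k))
        D[:, j] = X[:, i]
        D[:, i] = -X[:, j]
        design[:, b] = D.reshape(-1)
    coef, *_ = np.linalg.lstsq(design, Xdot.reshape(-1), rcond=None)
    M = np.zeros((k, k))
    for b, (i, j) in enumerate(pairs):
        M[i, j] = coef[b]
        M[j, i] = -coef[b]
    return M


def _cs_trajectories(dec: Decomposition, epoch: tuple) -> tuple[np.ndarray, np.ndarray]:
    """(n_cond, T_epoch, n_cs) trajectories and their time axis."""
    cs = dec.cs_indices
    C = int(np.unique(dec.condition).size)
    Xcs = dec.X[:, cs].reshape(C, -1, cs.size)
    seg = dec.segment.reshape(C, -1)[0]
    t = dec.time.reshape(C, -1)[0]
    sel = (seg == SEG_MOVE) & (t >= epoch[0]) & (t <= epoch[1])
    return Xcs[:, sel, :], t[sel]


def fit_rotational_plane(dec: Decomposition,
                         epoch: tuple = DEFAULT_EPOCH) -> RotationalPlane:
    """Dominant rotational plane of the condition-specific components.

    Central-difference derivatives of the per-condition CS-component
    trajectories over the perimovement epoch are regressed on the state
    with a skew-symmetric dynamics matrix; the plane is the real invariant
    subspace of the largest-modulus eigenvalue pair, orthonormalized, and
    the eigenfrequency is |Im eigenvalue| / 2 pi (in Hz).
    """
    cs = dec.cs_indices
    if cs.size < 4:
        raise ValueError("need >= 4 condition-specific components")
    traj, t = _cs_trajectories(dec, epoch)
    if t.size < 3:
        raise ValueError("epoch contains fewer than 3 time samples")
    dt_ms = float(t[1] - t[0])
    Xdot = np.gradient(traj, dt_ms, axis=1)  # per ms
    Xs = traj.reshape(-1, cs.size)
    M = fit_skew_symmetric(Xs, Xdot.reshape(-1, cs.size))
    scale = np.abs(M).max()
    if scale <= 1e-12 * max(1.0, np.abs(Xs).max()):
        return RotationalPlane(
            plane_units=dec.W[:, cs[:2]], plane_components=np.eye(cs.size)[:, :2],
            M=M, eigenfrequency_hz=0.0, epoch=tuple(epoch), rotating=False,
        )
    vals, vecs = np.linalg.eig(M)
    # among the conjugate eigenplanes, take the one carrying the most data
    # variance (the plane with the strongest rotations), not the fastest
    best, best_var = None, -1.0
    seen = set()
    for k in range(vals.size):
        if vals.imag[k] <= 0 or k in seen:
            continue
        seen.add(k)
        v = vecs[:, k]
        u1 = v.real / np.linalg.norm(v.real)
        u2 = v.imag - (v.imag @ u1) * u1
        n2 = np.linalg.norm(u2)
        if n2 < 1e-12:
            continue
        u2 = u2 / n2
        P = np.column_stack([u1, u2])
        var = float(np.sum((Xs @ P) ** 2))
        if var > best_var:
            best_var = var
            best = (abs(vals.imag[k]), P)
    if best is None:  # no oscillatory eigenvalues at all
        return RotationalPlane(
            plane_units=dec.W[:, cs[:2]], plane_components=np.eye(cs.size)[:, :2],
            M=M, eigenfrequency_hz=0.0, epoch=tuple(epoch), rotating=False,
        )
    omega_per_ms, plane_comp = best
    plane_units = dec.W[:, cs] @ plane_comp
    return RotationalPlane(
        plane_units=plane_units, plane_components=plane_comp, M=M,
        eigenfrequency_hz=float(omega_per_ms * 1000.0 / (2.0 * np.pi)),
        epoch=tuple(epoch),
    )


def build_3d_projection(dec: Decomposition, plane: RotationalPlane,
                        perimovement: tuple = DEFAULT_EPOCH):
    """Per-condition 3-D trajectories (CIS_1, rotation plane) + variance.

    Returns ``(table, variance_fraction)`` where the table has columns
    condition, segment, time_ms, period (baseline | delay | perimovement |
    other), cis, rot1, rot2, and ``variance_fraction`` is the share of the
    decomposition-captured variance carried by the three dimensions.
    """
    w_cis = dec.W[:, dec.cis1]
    basis = np.column_stack([w_cis, plane.plane_units])
    C = int(np.unique(dec.condition).size)
    # 3-D coordinates from the already-projected components: basis lies in
    # the span of W, so project X back through W
    coords = dec.X @ (dec.W.T @ basis)  # (rows, 3)
    var3 = coords.var(axis=0).sum()
    frac = float(var3 / dec.variance.sum())
    period = np.full(dec.time.size, "other", dtype=object)
    period[(dec.segment == SEG_TARGET) & (dec.time < 0)] = "baseline"
    period[(dec.segment == SEG_TARGET) & (dec.time >= 100.0)] = "delay"
    peri = (dec.segment == SEG_MOVE) & (dec.time >= perimovement[0]) & (dec.time <= perimovement[1])
    period[peri] = "perimovement"
    table = pd.DataFrame({
        "condition": dec.condition,
        "segment": dec.segment,
        "time_ms": dec.time,
        "period": period,
        "cis": coords[:, 0],
        "rot1": coords[:, 1],
        "rot2": coords[:, 2],
    })
    return table, frac


def neural_speed(trajectories: np.ndarray, time: np.ndarray) -> SpeedProfile:
    """Rate of change of the state in a subspace.

    ``trajectories`` is (n_conditions, T, k).  The Euclidean norm of the
    central-difference derivative is computed per condition, averaged
    across conditions, and normalized by its maximum.  A constant state is
    flagged (normalization undefined).
    """
    time = np.asarray(time, float)
    if time.size < 3:
        raise ValueError("need >= 3 samples for a derivative")
    dt = float(time[1] - time[0])
    vel = np.gradient(trajectories, dt, axis=1)
    speed = np.linalg.norm(vel, axis=2).mean(axis=0)
    peak = float(speed.max())
    if peak <= 0:
        return SpeedProfile(speed=np.zeros_like(speed), time=time,
                            peak_time=float("nan"), raw_peak=0.0,
                            flagged="constant state: normalization undefined")
    norm = speed / peak
    k = int(np.argmax(norm))  # earliest maximum
    flagged = ""
    if np.sum(norm >= norm[k] - 1e-12) > 1:
        flagged = "multiple equal maxima: earliest taken"
    return SpeedProfile(speed=norm, time=time, peak_time=float(time[k]),
                        raw_peak=peak, flagged=flagged)


def subspace_trajectories(dec: Decomposition, dims: np.ndarray,
                          epoch: tuple = (-300.0, 300.0)):
    """Move-aligned per-condition trajectories projected on ``dims``.

    ``dims`` is (n_units, k); returns ``(trajectories, time)`` shaped
    (n_conditions, T, k).
    """
    C = int(np.unique(dec.condition).size)
    coords = dec.X @ (dec.W.T @ dims)
    coords = coords.reshape(C, -1, dims.shape[1])
    seg = dec.segment.reshape(C, -1)[0]
    t = dec.time.reshape(C, -1)[0]
    sel = (seg == SEG_MOVE) & (t >= epoch[0]) & (t <= epoch[1])
    return coords[:, sel, :], t[sel]


def compare_peak_timing(speed_cis: SpeedProfile, speed_rot: SpeedProfile) -> float:
    """Lead of the CIS speed peak over the rotational speed peak (ms).

    Positive values mean the CIS dimensions reach their peak rate of
    change before the rotational plane does.
    """
    if speed_cis.time.size != speed_rot.time.size or \
            not np.allclose(speed_cis.time, speed_rot.time):
        raise ValueError("speed profiles must share a time grid")
    return float(speed_rot.peak_time - speed_cis.peak_time)
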