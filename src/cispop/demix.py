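"""Demixed decomposition of labeled population data.

Splits the labeled analysis matrix into orthonormal **condition-invariant**
and **condition-specific** components.  The decomposition works on the two
marginalizations of the centered data:

* the *time* marginalization ``R_time`` — each row replaced by the
  across-condition mean at that (segment, time) sample — captures
  structure varying with time alone;
* the *condition* marginalization ``R_cond = R_centered - R_time`` —
  the residual — captures everything that differs between conditions.

The fit is a greedy orthonormal scheme: at each step, within the orthogonal
complement of the dimensions already chosen, the leading eigenvector of the
covariance of each marginalization is computed, and whichever captures more
variance of its own marginalization is adopted (ties go to the time
marginalization).  Components are then characterized by the marginal
variance fractions of the *actual* projections ``X = R W``: a component is
classified condition-invariant when more than half of its variance is
carried by its across-condition mean time course.  The collection of
condition-invariant components is the CIS; the largest is CIS_1.

A feasibility analysis (:func:`demixing_feasibility`) answers, for a known
component set, whether *any* unit-norm linear combination of the components
is condition-invariant — solved exactly as a generalized eigenproblem
between the time-marginal and total covariances.  This makes precise why
condition-correlated components do not, in general, admit a
condition-invariant combination: equality of the combination across all
``C`` conditions at all ``T`` times imposes ``(C-1)*T`` linear constraints
on only ``D`` coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import SEG_MOVE, LabeledDataMatrix
from .synthgen import ComponentSet

__all__ = [
    "Decomposition",
    "FeasibilityResult",
    "marginalize",
    "marginal_variance",
    "fit_dpca",
    "fit_pca",
    "classify_components",
    "select_dimensionality",
    "compare_decompositions",
    "demixing_feasibility",
]


@dataclass
class Decomposition:
    """Orthonormal dimensions ``W`` and their projections ``X = R_c W``.

    Components (columns) are sorted by total variance, descending.  ``f_ci``
    and ``f_cs`` are the condition-invariant / condition-specific variance
    fractions of each projection; classification uses the strict rule
    ``f_ci > threshold`` (default 0.5).
    """

    W: np.ndarray
    X: np.ndarray
    f_ci: np.ndarray
    f_cs: np.ndarray
    variance: np.ndarray
    fit_labels: np.ndarray
    method: str
    condition: np.ndarray
    time: np.ndarray
    segment: np.ndarray
    threshold: float = 0.5
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def ci_indices(self) -> np.ndarray:
        """Condition-invariant components, by descending variance."""
        return np.flatnonzero(self.f_ci > self.threshold)

    @property
    def cs_indices(self) -> np.ndarray:
        return np.flatnonzero(~(self.f_ci > self.threshold))

    @property
    def cis1(self) -> int:
        """Index of the largest condition-invariant component."""
        ci = self.ci_indices
        if ci.size == 0:
            raise ValueError("decomposition has no condition-invariant component")
        return int(ci[0])

    def component_timecourse(self, k: int) -> np.ndarray:
        """Projection of component ``k`` as a (condition, time) array."""
        C = int(np.unique(self.condition).size)
        return self.X[:, k].reshape(C, -1)


@dataclass
class FeasibilityResult:
    """Best achievable condition-invariant purity of a component mixture."""

    p: np.ndarray
    best_purity: float
    solvable: bool
    counting_unsolvable: bool  # whether (C-1)*T > D
    C: int
    T: int
    D: int


# ---------------------------------------------------------------------------
# marginalization


def _center(dm: LabeledDataMatrix) -> np.ndarray:
    return dm.R - dm.R.mean(axis=0, keepdims=True)


def marginalize(dm: LabeledDataMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Split the column-centered matrix into its two marginalizations.

    Returns ``(R_time, R_cond)`` with ``R_time + R_cond`` equal to the
    centered matrix exactly; the two parts are orthogonal (their squared
    norms add up to the squared norm of the centered matrix).
    """
    Rc = _center(dm)
    tens = dm.as_tensor(Rc)  # (C, T, n)
    time_mean = tens.mean(axis=0, keepdims=True)
    R_time = np.broadcast_to(time_mean, tens.shape).reshape(Rc.shape)
    return np.ascontiguousarray(R_time), Rc - R_time


def marginal_variance(x: np.ndarray) -> tuple[float, float]:
    """Condition-invariant / condition-specific variance split of one
    component time course ``x`` of shape (conditions, time).

    ``f_ci = sum_t C * mean_c(x)^2 / sum_{c,t} x^2`` after removing the
    grand mean.  An all-zero component is flagged with ``(nan, nan)``.
    """
    x = np.asarray(x, float)
    xc = x - x.mean()
    total = float(np.sum(xc**2))
    if total <= 0:
        return (float("nan"), float("nan"))
    C = x.shape[0]
    f_ci = float(C * np.sum(xc.mean(axis=0) ** 2) / total)
    return f_ci, 1.0 - f_ci


# ---------------------------------------------------------------------------
# fitting


def _leading_eigvec(S: np.ndarray) -> tuple[float, np.ndarray]:
    n = S.shape[0]
    vals, vecs = scipy.linalg.eigh(S, subset_by_index=[n - 1, n - 1])
    return float(vals[0]), vecs[:, 0]


def _greedy_step(St: np.ndarray, Sc: np.ndarray, Q: np.ndarray | None):
    """One greedy dimension within the complement of the basis ``Q``."""
    n = St.shape[0]
    if Q is None or Q.shape[1] == 0:
        Pt, Pc = St, Sc
        proj = None
    else:
        P = np.eye(n) - Q @ Q.T
        Pt, Pc = P @ St @ P, P @ Sc @ P
        proj = P
    lam_t, v_t = _leading_eigvec(Pt)
    lam_c, v_c = _leading_eigvec(Pc)
    if max(lam_t, lam_c) <= 1e-12 * max(np.trace(St) + np.trace(Sc), 1e-300):
        raise np.linalg.LinAlgError("requested dimension exceeds data rank")
    # tie-break in favor of the time marginalization
    if lam_t >= lam_c:
        label, v = "time", v_t
    else:
        label, v = "condition", v_c
    if proj is not None:
        v = proj @ v
        # re-orthogonalize against accumulated numerical drift
        v = v - Q @ (Q.T @ v)
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise np.linalg.LinAlgError("requested dimension exceeds data rank")
    return label, v / nv


def _finalize(dm: LabeledDataMatrix, W: np.ndarray, labels: list, method: str,
              threshold: float = 0.5) -> Decomposition:
    Rc = _center(dm)
    X = Rc @ W
    C = dm.n_conditions
    # sign convention: time-averaged projection over the move-aligned window
    # is nonnegative
    move_rows = dm.segment == SEG_MOVE
    sign = np.where(X[move_rows].mean(axis=0) < 0, -1.0, 1.0)
    W = W * sign
    X = X * sign
    var = X.var(axis=0)
    order = np.argsort(var)[::-1]
    W, X, var = W[:, order], X[:, order], var[order]
    labels = np.asarray(labels)[order]
    f = np.array([marginal_variance(X[:, k].reshape(C, -1)) for k in range(W.shape[1])])
    return Decomposition(
        W=W, X=X, f_ci=f[:, 0], f_cs=f[:, 1], variance=var,
        fit_labels=labels, method=method,
        condition=dm.condition, time=dm.time, segment=dm.segment,
        threshold=threshold,
    )


def fit_dpca(dm: LabeledDataMatrix, D: int, threshold: float = 0.5) -> Decomposition:
    """Greedy demixed decomposition with ``D`` orthonormal dimensions."""
    if D < 1 or D > min(dm.R.shape):
        raise ValueError("D must be between 1 and min(rows, units)")
    R_time, R_cond = marginalize(dm)
    St, Sc = R_time.T @ R_time, R_cond.T @ R_cond
    Q = np.empty((dm.n_units, 0))
    labels: list = []
    for _ in range(D):
        label, v = _greedy_step(St, Sc, Q)
        Q = np.column_stack([Q, v])
        labels.append(label)
    return _finalize(dm, Q, labels, "dpca", threshold)


def fit_pca(dm: LabeledDataMatrix, D: int, threshold: float = 0.5) -> Decomposition:
    """Standard PCA of the column-centered matrix, with the same marginal
    variance reporting as the demixed fit."""
    if D < 1 or D > min(dm.R.shape):
        raise ValueError("D must be between 1 and min(rows, units)")
    Rc = _center(dm)
    S = Rc.T @ Rc
    n = S.shape[0]
    vals, vecs = scipy.linalg.eigh(S, subset_by_index=[n - D, n - 1])
    W = vecs[:, ::-1]
    if vals[0] <= 1e-12 * max(vals):
        raise ValueError("D exceeds the rank of the data")
    return _finalize(dm, W, ["pca"] * D, "pca", threshold)


def classify_components(dec: Decomposition, threshold: float = 0.5):
    """(CI list, CS list) of component indices under the strict >threshold
    rule; exactly 50% condition-invariant variance counts as CS."""
    ci = np.flatnonzero(dec.f_ci > threshold)
    cs = np.flatnonzero(~(dec.f_ci > threshold))
    return list(ci), list(cs)


def select_dimensionality(dm: LabeledDataMatrix, target_cs: int = 8,
                          max_extra: int = 30, threshold: float = 0.5):
    """Smallest total dimensionality yielding exactly ``target_cs``
    condition-specific components.

    The greedy fit is extended one dimension at a time; because earlier
    dimensions (and hence their classifications) never change as dimensions
    are appended, the condition-specific count is nondecreasing in the
    total dimensionality and the first crossing is the answer.  If the rank
    budget is exhausted first, the best-effort decomposition is returned
    with a diagnostic in ``meta``.
    """
    if target_cs < 1:
        raise ValueError("target_cs must be >= 1")
    R_time, R_cond = marginalize(dm)
    St, Sc = R_time.T @ R_time, R_cond.T @ R_cond
    Rc = R_time + R_cond
    C = dm.n_conditions
    D_max = min(dm.R.shape[0], dm.n_units, target_cs + max_extra)
    Q = np.empty((dm.n_units, 0))
    labels: list = []
    n_cs = 0
    exhausted = True
    while Q.shape[1] < D_max:
        try:
            label, v = _greedy_step(St, Sc, Q)
        except np.linalg.LinAlgError:
            break
        Q = np.column_stack([Q, v])
        labels.append(label)
        x = (Rc @ v).reshape(C, -1)
        f_ci, _ = marginal_variance(x)
        if not f_ci > threshold:
            n_cs += 1
        if n_cs == target_cs:
            exhausted = False
            break
    dec = _finalize(dm, Q, labels, "dpca", threshold)
    if exhausted:
        dec.meta["diagnostic"] = (
            f"no dimensionality <= {D_max} yields {target_cs} condition-specific "
            f"components (got {n_cs}); returning best effort"
        )
    return dec.n_components, dec


def compare_decompositions(dpca: Decomposition, pca: Decomposition):
    """(variance ratio, first-dimension angle in degrees) between two fits.

    The variance ratio is the total variance captured by the demixed
    dimensions divided by that captured by the same number of PCA
    dimensions; the angle is ``arccos |w1_dpca . w1_pca|``.
    """
    if dpca.n_components != pca.n_components:
        raise ValueError("decompositions must have equal dimensionality")
    ratio = float(dpca.variance.sum() / pca.variance.sum())
    cosang = abs(float(dpca.W[:, 0] @ pca.W[:, 0]))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return ratio, angle


# ---------------------------------------------------------------------------
# feasibility


def _components_array(obj) -> np.ndarray:
    """(n_comp, C, T) array from a ComponentSet or Decomposition."""
    if isinstance(obj, ComponentSet):
        return obj.x
    if isinstance(obj, Decomposition):
        C = int(np.unique(obj.condition).size)
        return obj.X.T.reshape(obj.n_components, C, -1)
    return np.asarray(obj, float)


def demixing_feasibility(components, tol: float = 1e-9) -> FeasibilityResult:
    """Maximal condition-invariant purity over unit-norm combinations.

    For ``y = sum_i p_i x_i`` the purity ``f_CI(y)`` is a generalized
    Rayleigh quotient ``p'A p / p'B p`` with ``A`` the time-marginal and
    ``B`` the total covariance of the (grand-centered) components; the
    optimum is the top generalized eigenpair.  ``solvable`` reports whether
    an exactly condition-invariant combination exists — decided by the rank
    of the ``(C-1)*T x D`` between-condition difference system, which also
    covers the degenerate case of a constant (zero-variance) invariant
    combination that the variance-based purity cannot see.
    ``counting_unsolvable`` reports whether the counting bound
    ``(C-1)*T > D`` — under which exact solvability is nongeneric — holds.
    """
    x = _components_array(components)
    if x.ndim != 3 or x.shape[0] < 1 or x.shape[1] < 2:
        raise ValueError("need (n_comp, C>=2, T) components")
    D, C, T = x.shape
    xc = x - x.reshape(D, -1).mean(axis=1)[:, None, None]
    if np.any(xc.reshape(D, -1).std(axis=1) <= 0):
        raise ValueError("degenerate (constant) component")
    mean_c = xc.mean(axis=1)  # (D, T)
    A = C * mean_c @ mean_c.T
    B = np.einsum("ict,jct->ij", xc, xc)
    # tiny ridge keeps B positive definite for near-collinear components
    ridge = 1e-12 * np.trace(B) / D
    vals, vecs = scipy.linalg.eigh(A, B + ridge * np.eye(D))
    best = float(np.clip(vals[-1], 0.0, 1.0))
    p = vecs[:, -1]
    p = p / np.linalg.norm(p)
    # exact solvability: null space of the between-condition differences
    diffs = (x[:, :-1, :] - x[:, 1:, :]).reshape(D, -1).T  # ((C-1)T, D)
    s = np.linalg.svd(diffs, compute_uv=False)
    solvable = bool(s.size < D or s[-1] <= np.sqrt(tol) * max(s[0], 1e-300)) \
        if s.size else True
    if solvable and 1.0 - best > tol:
        # invariant combination exists but is constant in time: report it
        null = scipy.linalg.null_space(diffs, rcond=np.sqrt(tol))
        if null.size:
            p = null[:, 0] / np.linalg.norm(null[:, 0])
        best = 1.0
    return FeasibilityResult(
        p=p,
        best_purity=best,
        solvable=solvable,
        counting_unsolvable=(C - 1) * T > D,
        C=C, T=T, D=D,
    )
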