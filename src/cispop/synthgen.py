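"""Synthetic delayed-reach population generator.

Emulates the structure of motor/premotor cortex population activity in a
delayed-reach task with many reach conditions, so every downstream stage of
the analysis can be exercised against known ground truth:

* a **condition-invariant** component (identical time course for every
  condition) that rises sigmoidally ~150 ms before movement onset, plus
  optional smaller condition-invariant transients;
* **condition-specific** components: delay-period preparatory plateaus with
  condition-dependent amplitude, ~2 Hz sine/cosine rotation pairs with
  condition-dependent amplitude and phase that switch on at the rise
  midpoint, and one condition-correlated "speed" component (positive,
  condition-varying amplitude) mirroring the speed-predictive structure
  reported for such recordings;
* single trials with per-trial latency jitter applied jointly to the rise
  and all movement-locked components, and inhomogeneous-Poisson spiking;
* a muscle-like population whose components are condition-correlated but
  never condition-invariant;
* the analytic two-component counterexample ``g_c sin(t)`` / ``h_c sin(3t)``
  demonstrating that condition-correlated components need not admit a
  condition-invariant linear combination.

Each unit's rate is a rectified weighted sum of the components
(``r = max(0, baseline + scale * W x)``), with zero-mean unit-variance
mixing weights, so condition-invariant structure is distributed across the
whole population rather than carried by dedicated units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import SEG_MOVE, SEG_TARGET, PopulationResponse, SingleTrialDataset

__all__ = [
    "GeneratorConfig",
    "ComponentSet",
    "CounterexampleSpec",
    "make_components",
    "make_population",
    "make_trials",
    "make_muscle_population",
    "make_counterexample",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic population.

    Times are in ms, rates in spikes/s.  ``target_epoch`` / ``move_epoch``
    are inclusive ranges relative to target onset and movement onset.
    ``trial_counts`` may be an int (same count per condition for every entry
    of ``delays``) or a mapping ``{delay_ms: count}``; delays absent from
    the mapping are not simulated.
    """

    n_units: int = 116
    n_conditions: int = 27
    dt: float = 10.0
    target_epoch: tuple[float, float] = (-300.0, 400.0)
    move_epoch: tuple[float, float] = (-300.0, 600.0)
    n_ci_components: int = 2
    n_cs_components: int = 8
    ci_variance_share: float = 0.4
    ci_secondary_frac: float = 0.15
    rotation_frequency: float = 2.0
    trigger_lead: float = 150.0
    rise_width: float = 50.0
    ci_delay_drift: float = 0.5
    rt_jitter_sd: float = 50.0
    nominal_rt: float = 300.0
    trial_counts: object = 25
    delays: tuple[float, ...] = (0.0, 100.0, 200.0, 500.0)
    long_delay_ref: float = 500.0
    ci_coupling: float = 1.0
    residual_frac: float = 0.2
    ci_weight_mean: float = 0.6
    baseline_rate: float = 25.0
    rate_range: float = 40.0
    speed_lag: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 < self.ci_variance_share < 1.0:
            raise ValueError("ci_variance_share must lie in (0, 1)")
        for lo, hi in (self.target_epoch, self.move_epoch):
            if hi <= lo:
                raise ValueError("epochs must be nonempty")
        if self.n_ci_components < 1 or self.n_cs_components < 2:
            raise ValueError("need >= 1 CI and >= 2 CS components")
        # rotation must be resolvable on the grid: >= 2 samples per period
        period_ms = 1000.0 / self.rotation_frequency
        if self.dt > period_ms / 2.0:
            raise ValueError(
                f"dt={self.dt} ms cannot resolve {self.rotation_frequency} Hz "
                "rotations (need >= 2 samples per period)"
            )

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic sub-stream of the master seed for one stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))

    def target_grid(self) -> np.ndarray:
        lo, hi = self.target_epoch
        return np.arange(lo, hi + 0.5 * self.dt, self.dt)

    def move_grid(self) -> np.ndarray:
        lo, hi = self.move_epoch
        return np.arange(lo, hi + 0.5 * self.dt, self.dt)

    @property
    def nominal_move_time(self) -> float:
        """Nominal movement onset (re target) for the reference long delay."""
        return self.long_delay_ref + self.nominal_rt


@dataclass
class ComponentSet:
    """Ground-truth population-level components ``x_{i,c,t}``.

    ``x`` has shape ``(n_components, n_conditions, n_samples)`` where the
    sample axis concatenates the target-aligned and movement-aligned grids;
    ``segment``/``time`` label the samples.  ``labels`` tags each component
    ``"condition-invariant"`` or ``"condition-specific"``.
    """

    x: np.ndarray
    time: np.ndarray
    segment: np.ndarray
    labels: list
    model: object | None = None

    @property
    def n_components(self) -> int:
        return self.x.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.x.shape[1]

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(target-aligned, move-aligned) views of ``x``."""
        tgt = self.segment == SEG_TARGET
        return self.x[:, :, tgt], self.x[:, :, ~tgt]


@dataclass(frozen=True)
class CounterexampleSpec:
    """Condition scalars for the two-harmonic counterexample."""

    g: tuple
    h: tuple
    T: int = 100

    def validate(self) -> None:
        g, h = np.asarray(self.g, float), np.asarray(self.h, float)
        if g.size != h.size or g.size < 2:
            raise ValueError("g and h need one entry per condition (>= 2)")
        if np.any(g <= 0) or np.any(h <= 0):
            raise ValueError("condition scalars must be positive")
        if self.T < 4:
            raise ValueError("need at least 4 time samples to separate harmonics")


# ---------------------------------------------------------------------------
# component model


@dataclass
class _Component:
    kind: str  # ci_rise | ci_bump | prep | rot_sin | rot_cos | speed
    label: str
    amp: np.ndarray  # per-condition amplitude (ones for CI components)
    phase: np.ndarray | None = None
    freq_hz: float = 0.0
    mu: float = 0.0
    sd: float = 1.0
    scale: float = 1.0
    alpha: float = 0.0  # rise-profile component removed from CI transients
    # movement-epoch multiphasic transient (tuned components): bump centers,
    # widths and signed heights
    bump_mu: np.ndarray | None = None
    bump_sd: np.ndarray | None = None
    bump_a: np.ndarray | None = None


class ComponentModel:
    """Analytic component time courses, evaluable on arbitrary grids.

    Every component is a function of time relative to target onset
    (``t_t``) and/or time relative to movement onset (``t_m``); trials with
    jittered movement onset are generated by evaluating the same functions
    on the trial's own grid.
    """

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        c = config
        C = c.n_conditions
        comps: list[_Component] = []
        # condition-invariant: sigmoidal rise centered trigger_lead ms before
        # movement onset, then smaller transients for any extra CI components
        comps.append(
            _Component("ci_rise", "condition-invariant", np.ones(C),
                       mu=-c.trigger_lead, sd=c.rise_width / 4.0)
        )
        for i in range(1, c.n_ci_components):
            if i == 1:
                # time-elapsed ramp over the whole trial (sustained, so its
                # baseline-recentered mean is large)
                comps.append(_Component("ci_ramp", "condition-invariant", np.ones(C)))
            else:
                comps.append(
                    _Component("ci_bump", "condition-invariant", np.ones(C),
                               mu=-c.trigger_lead + 80.0 * (i - 1), sd=70.0)
                )
        # condition-specific layout: one condition-correlated speed component
        # (if room), up to two rotation pairs, preparatory plateaus for the rest
        n_cs = c.n_cs_components
        n_speed = 1 if n_cs >= 4 else 0
        rest = n_cs - n_speed
        n_pairs = max(1, min(2, (rest - 1) // 2)) if rest >= 2 else 0
        n_prep = rest - 2 * n_pairs
        for j in range(n_prep):
            amp = rng.normal(size=C)
            amp -= amp.mean()  # zero net structure across conditions
            # multiphasic movement-epoch transient: real tuned responses show
            # a series of peaks and valleys after movement onset
            nb = 3
            comps.append(
                _Component("prep", "condition-specific", amp, mu=100.0, sd=15.0,
                           bump_mu=rng.uniform(-100.0, 400.0, nb),
                           bump_sd=rng.uniform(40.0, 70.0, nb),
                           bump_a=rng.normal(0.0, 1.0, nb))
            )
        for p in range(n_pairs):
            freq = c.rotation_frequency * (1.0 if p == 0 else 1.6)
            amp = 0.5 + rng.uniform(0.0, 1.0, size=C)
            phase = rng.uniform(0.0, 2.0 * np.pi, size=C)
            # remove the across-condition mean of the complex amplitude so
            # the rotation pair carries no condition-invariant residue
            z = amp * np.exp(1j * phase)
            z = z - z.mean()
            amp, phase = np.abs(z), np.angle(z)
            comps.append(_Component("rot_sin", "condition-specific", amp,
                                    phase=phase, freq_hz=freq))
            comps.append(_Component("rot_cos", "condition-specific", amp,
                                    phase=phase, freq_hz=freq))
        if n_speed:
            amp = 0.02 + rng.gamma(1.0, 1.0, size=C)
            comps.append(_Component("speed", "condition-specific", amp,
                                    mu=150.0, sd=90.0))
        self.components = comps
        self._set_scales()

    # -- evaluation ---------------------------------------------------------

    def _rise_profile(self, t_target: np.ndarray, t_move_ci: np.ndarray) -> np.ndarray:
        """The CIS_1 time course (sudden rise plus delay-period drift)."""
        c = self.config
        prof = _sigmoid((t_move_ci + c.trigger_lead) / (c.rise_width / 4.0))
        if c.ci_delay_drift:
            lo = c.target_epoch[0]
            hi = c.nominal_move_time + c.move_epoch[1]
            prof = prof + c.ci_delay_drift * np.clip((t_target - lo) / (hi - lo), 0.0, 1.0)
        return prof

    def evaluate(self, t_target: np.ndarray, t_move: np.ndarray,
                 t_move_ci: np.ndarray | None = None) -> np.ndarray:
        """Component values on a grid; returns ``(n_comp, n_cond, T)``.

        ``t_move_ci`` optionally decouples the CI rise from the other
        movement-locked terms (robustness experiments).
        """
        c = self.config
        if t_move_ci is None:
            t_move_ci = t_move
        C = c.n_conditions
        out = np.empty((len(self.components), C, t_target.size))
        rise_t = _sigmoid((t_target - 100.0) / 15.0)
        fall_m = _sigmoid(-(t_move + c.trigger_lead) / 15.0)
        env = _sigmoid((t_move + c.trigger_lead) / 20.0)
        for i, comp in enumerate(self.components):
            if comp.kind == "ci_rise":
                # sudden rise before movement onset, on top of a gentle
                # condition-invariant drift through the delay period
                out[i] = self._rise_profile(t_target, t_move_ci)[None, :]
            elif comp.kind == "ci_ramp":
                lo = c.target_epoch[0]
                hi = c.nominal_move_time + c.move_epoch[1]
                ramp = np.clip((t_target - lo) / (hi - lo), 0.0, 1.0)
                out[i] = (ramp - comp.alpha * self._rise_profile(t_target, t_move_ci))[None, :]
            elif comp.kind == "ci_bump":
                prof = (_gauss(t_move_ci, comp.mu, comp.sd)
                        - comp.alpha * self._rise_profile(t_target, t_move_ci))
                out[i] = prof[None, :]
            elif comp.kind == "prep":
                prof = rise_t * fall_m
                if comp.bump_mu is not None:
                    trans = np.zeros_like(t_move)
                    for mu_b, sd_b, a_b in zip(comp.bump_mu, comp.bump_sd, comp.bump_a):
                        trans += a_b * _gauss(t_move, mu_b, sd_b)
                    prof = prof + trans
                out[i] = comp.amp[:, None] * prof[None, :]
            elif comp.kind in ("rot_sin", "rot_cos"):
                ang = (2.0 * np.pi * comp.freq_hz / 1000.0
                       * (t_move + c.trigger_lead))[None, :] + comp.phase[:, None]
                osc = np.sin(ang) if comp.kind == "rot_sin" else np.cos(ang)
                out[i] = comp.amp[:, None] * env[None, :] * osc
            elif comp.kind == "speed":
                prof = _gauss(t_move, comp.mu, comp.sd)
                out[i] = comp.amp[:, None] * prof[None, :]
            else:  # pragma: no cover
                raise AssertionError(comp.kind)
            out[i] *= comp.scale
        return out

    def evaluate_reference(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Components on the standard two-alignment grids (concatenated)."""
        c = self.config
        tg, mg = c.target_grid(), c.move_grid()
        M = c.nominal_move_time
        x_t = self.evaluate(tg, tg - M)
        x_m = self.evaluate(mg + M, mg)
        time = np.concatenate([tg, mg])
        seg = np.concatenate([np.full(tg.size, SEG_TARGET, np.int8),
                              np.full(mg.size, SEG_MOVE, np.int8)])
        return np.concatenate([x_t, x_m], axis=2), time, seg

    def condition_speed(self) -> np.ndarray:
        """Behavioral hand-speed profile per condition on the move grid.

        The speed envelope shares the planted speed component's
        per-condition amplitudes but lags the neural time course by
        ``speed_lag`` ms.
        """
        c = self.config
        mg = c.move_grid()
        for comp in self.components:
            if comp.kind == "speed":
                prof = _gauss(mg - c.speed_lag, comp.mu, comp.sd)
                return comp.amp[:, None] * prof[None, :]
        # no planted speed component: use rotation-amplitude bell as fallback
        for comp in self.components:
            if comp.kind == "rot_sin":
                prof = _gauss(mg - c.speed_lag, 150.0, 90.0)
                return comp.amp[:, None] * prof[None, :]
        raise ValueError("no movement component to derive a speed from")

    # -- variance normalization --------------------------------------------

    def _variance_targets(self) -> np.ndarray:
        c = self.config
        labels = [comp.label for comp in self.components]
        n_ci = labels.count("condition-invariant")
        v = np.empty(len(labels))
        rest = 1.0 - c.ci_variance_share
        ci_extra = rest * c.ci_secondary_frac
        cs_total = rest - (ci_extra if n_ci > 1 else 0.0)
        # relative weights among CS components: preps and the first rotation
        # pair dominate; second pair and speed component are smaller
        w = []
        pair_seen = 0
        for comp in self.components:
            if comp.label == "condition-invariant":
                continue
            if comp.kind == "prep":
                w.append(1.0)
            elif comp.kind in ("rot_sin", "rot_cos"):
                if comp.kind == "rot_sin":
                    pair_seen += 1
                w.append(1.0 if pair_seen == 1 else 0.45)
            else:  # speed
                w.append(0.6)
        w = np.asarray(w)
        w = w / w.sum() * cs_total
        k = 0
        ci_seen = 0
        for i, comp in enumerate(self.components):
            if comp.label == "condition-invariant":
                if ci_seen == 0:
                    v[i] = c.ci_variance_share
                else:
                    v[i] = ci_extra / max(n_ci - 1, 1)
                ci_seen += 1
            else:
                v[i] = w[k]
                k += 1
        return v

    def _set_scales(self) -> None:
        for comp in self.components:
            comp.scale = 1.0
            comp.alpha = 0.0
        # decorrelate the secondary CI transients from the main rise so the
        # planted CI components are orthogonal in time (clean ground truth)
        c = self.config
        tg, mg = c.target_grid(), c.move_grid()
        M = c.nominal_move_time
        t_m = np.concatenate([tg - M, mg])
        rise = self._rise_profile(np.concatenate([tg, mg + M]), t_m)
        rise_c = rise - rise.mean()
        denom = float(rise_c @ rise_c)
        lo = c.target_epoch[0]
        hi = c.nominal_move_time + c.move_epoch[1]
        t_t = np.concatenate([tg, mg + M])
        for comp in self.components:
            if comp.kind == "ci_bump":
                prof = _gauss(t_m, comp.mu, comp.sd)
            elif comp.kind == "ci_ramp":
                prof = np.clip((t_t - lo) / (hi - lo), 0.0, 1.0)
            else:
                continue
            comp.alpha = float((prof - prof.mean()) @ rise_c / denom)
        x, _, _ = self.evaluate_reference()
        raw = x.reshape(x.shape[0], -1)
        raw_var = raw.var(axis=1)
        targets = self._variance_targets()
        for comp, rv, tv in zip(self.components, raw_var, targets):
            if rv <= 0:
                raise ValueError(f"degenerate component {comp.kind}")
            comp.scale = float(np.sqrt(tv / rv))

    @property
    def labels(self) -> list:
        return [comp.label for comp in self.components]


class ResidualModel:
    """Unit-idiosyncratic smooth response detail.

    Real PSTHs are multiphasic well beyond what a handful of shared
    components reconstructs; a low-dimensional generator without this tail
    would be unrealistically band-limited (and its phase-randomized
    surrogates degenerate).  Each unit and condition receives a smooth
    random curve built from two banks of Gaussian bumps — one locked to
    target onset, one to movement onset — with i.i.d. coefficients, scaled
    so the residual carries ``residual_frac`` of the shared-component
    variance.  Target-locked parts stay put under latency jitter;
    move-locked parts shift with movement onset, like the components.
    """

    BUMP_SPACING = 60.0  # ms
    BUMP_SD = 35.0  # ms

    def __init__(self, config: GeneratorConfig, n_units: int, rng: np.random.Generator):
        self.config = config
        c = config
        self.centers_t = np.arange(c.target_epoch[0], c.target_epoch[1] + 1.0,
                                   self.BUMP_SPACING)
        self.centers_m = np.arange(c.move_epoch[0], c.move_epoch[1] + 1.0,
                                   self.BUMP_SPACING)
        n_basis = self.centers_t.size + self.centers_m.size
        self.coef = rng.standard_normal((n_units, c.n_conditions, n_basis))
        # normalize so the mean residual variance equals residual_frac
        self.scale = 1.0
        x, _, _ = self._reference()
        self.scale = float(np.sqrt(c.residual_frac / x.var()))

    def _basis(self, t_target: np.ndarray, t_move: np.ndarray) -> np.ndarray:
        bt = _gauss(t_target[None, :], self.centers_t[:, None], self.BUMP_SD)
        bm = _gauss(t_move[None, :], self.centers_m[:, None], self.BUMP_SD)
        return np.concatenate([bt, bm], axis=0)  # (n_basis, T)

    def evaluate(self, t_target: np.ndarray, t_move: np.ndarray) -> np.ndarray:
        """Residual curves on a grid -> (n_units, n_conditions, T)."""
        B = self._basis(t_target, t_move)
        return self.scale * np.einsum("ucb,bt->uct", self.coef, B)

    def evaluate_condition(self, cond: int, t_target: np.ndarray,
                           t_move: np.ndarray) -> np.ndarray:
        B = self._basis(t_target, t_move)
        return self.scale * (self.coef[:, cond, :] @ B)

    def _reference(self):
        c = self.config
        tg, mg = c.target_grid(), c.move_grid()
        M = c.nominal_move_time
        x_t = self.evaluate(tg, tg - M)
        x_m = self.evaluate(mg + M, mg)
        return np.concatenate([x_t, x_m], axis=2), tg, mg

    def reference_split(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.config
        tg, mg = c.target_grid(), c.move_grid()
        M = c.nominal_move_time
        return self.evaluate(tg, tg - M), self.evaluate(mg + M, mg)


# ---------------------------------------------------------------------------
# public operations


def make_components(config: GeneratorConfig) -> ComponentSet:
    """Generate the ground-truth component set for ``config``.

    The largest condition-invariant component is scaled to carry exactly
    ``config.ci_variance_share`` of the total component variance (variances
    measured over conditions and both reference grids).
    """
    config.validate()
    model = ComponentModel(config, config.rng(0))
    x, time, seg = model.evaluate_reference()
    return ComponentSet(x=x, time=time, segment=seg, labels=model.labels, model=model)


def make_population(components: ComponentSet, config: GeneratorConfig) -> PopulationResponse:
    """Mix components into unit firing rates (rectified weighted sums).

    Each unit's rate is ``max(0, baseline + scale * (W x + residual))``
    where the residual is the unit's idiosyncratic smooth response detail
    (see :class:`ResidualModel`); set ``residual_frac = 0`` for purely
    low-dimensional rates.
    """
    config.validate()
    rng = config.rng(1)
    W = rng.standard_normal((config.n_units, components.n_components))
    # most units' rates rise with the condition-invariant signal: the
    # population-average response shows a clear net increase around movement,
    # so the largest CI component's weights have a positive mean
    W[:, 0] += config.ci_weight_mean
    scale = config.rate_range / 4.0
    x_t, x_m = components.split()
    sig_t = np.einsum("ni,ict->nct", W, x_t)
    sig_m = np.einsum("ni,ict->nct", W, x_m)
    residual = None
    if config.residual_frac > 0:
        residual = ResidualModel(config, config.n_units, config.rng(4))
        res_t, res_m = residual.reference_split()
        sig_t = sig_t + res_t
        sig_m = sig_m + res_m
    tgt = np.clip(config.baseline_rate + scale * sig_t, 0.0, None)
    mov = np.clip(config.baseline_rate + scale * sig_m, 0.0, None)
    model = components.model
    pop = PopulationResponse(
        target_rates=tgt,
        move_rates=mov,
        target_time=config.target_grid(),
        move_time=config.move_grid(),
        meta={"kind": "neural", "seed": config.seed},
        ground_truth={
            "weights": W,
            "components": components,
            "model": model,
            "residual_model": residual,
            "scale": scale,
            "baseline": config.baseline_rate,
            "config": config,
            "condition_speed": None if model is None else model.condition_speed(),
        },
    )
    pop.validate()
    return pop


def _counts_per_delay(config: GeneratorConfig) -> dict:
    tc = config.trial_counts
    if isinstance(tc, dict):
        return {float(d): int(n) for d, n in tc.items() if n > 0}
    return {float(d): int(tc) for d in config.delays if int(tc) > 0}


def make_trials(population: PopulationResponse, config: GeneratorConfig) -> SingleTrialDataset:
    """Simulate single trials with latency jitter and Poisson spiking.

    Per trial a zero-mean latency offset (SD ``rt_jitter_sd``) shifts
    movement onset — and with it the condition-invariant rise and all
    movement-locked components — relative to the go cue; spikes are drawn
    from an inhomogeneous Poisson process at the shifted rates, placed
    uniformly within ``dt`` bins.  Trials that would have a nonpositive RT
    are redrawn (count logged in ``meta['n_redraws']``).
    """
    gt = population.ground_truth
    if gt is None or gt.get("model") is None:
        raise ValueError("population lacks generator ground truth")
    model: ComponentModel = gt["model"]
    residual: ResidualModel | None = gt.get("residual_model")
    W, scale, baseline = gt["weights"], gt["scale"], gt["baseline"]
    rng = config.rng(2)
    dt = config.dt
    dt_s = dt / 1000.0
    start = config.target_epoch[0]
    tail = config.move_epoch[1]

    spike_units, spike_times = [], []
    conds, delays, gos, moves, rts = [], [], [], [], []
    n_redraws = 0
    for delay, count in sorted(_counts_per_delay(config).items()):
        for c in range(config.n_conditions):
            for _ in range(count):
                while True:
                    offset = rng.normal(0.0, config.rt_jitter_sd)
                    rt = config.nominal_rt + offset
                    if rt > 0:
                        break
                    n_redraws += 1
                move = delay + rt
                grid = np.arange(start, move + tail + 0.5 * dt, dt)
                t_m = grid - move
                if config.ci_coupling != 1.0:
                    move_ci = delay + config.nominal_rt + config.ci_coupling * offset
                    x = model.evaluate(grid, t_m, grid - move_ci)
                else:
                    x = model.evaluate(grid, t_m)
                sig = W @ x[:, c, :]
                if residual is not None:
                    sig = sig + residual.evaluate_condition(c, grid, t_m)
                rate = np.clip(baseline + scale * sig, 0.0, None)
                counts = rng.poisson(rate * dt_s)
                units, bins = np.nonzero(counts)
                reps = counts[units, bins]
                u = np.repeat(units, reps).astype(np.int32)
                t = np.repeat(grid[bins], reps) + rng.uniform(0.0, dt, size=u.size)
                spike_units.append(u)
                spike_times.append(t)
                conds.append(c)
                delays.append(delay)
                gos.append(delay)
                moves.append(move)
                rts.append(rt)
    return SingleTrialDataset(
        spike_units=spike_units,
        spike_times=spike_times,
        condition=np.asarray(conds, int),
        delay=np.asarray(delays, float),
        go_time=np.asarray(gos, float),
        move_time=np.asarray(moves, float),
        rt=np.asarray(rts, float),
        n_units=config.n_units,
        dt=dt,
        meta={"n_redraws": n_redraws, "seed": config.seed},
    )


def make_muscle_population(config: GeneratorConfig, n_channels: int = 10,
                           equal_amplitudes: bool = False) -> PopulationResponse:
    """Muscle-like population: condition-correlated, never condition-invariant.

    Channels mix two shared temporal profiles whose per-condition amplitudes
    are positive but strongly variable (gamma-distributed), plus a
    condition-specific oscillatory pair.  With ``equal_amplitudes=True`` the
    amplitudes of the shared profiles are forced equal across conditions,
    which degenerately turns them into condition-invariant components — the
    documented negative control of the control.
    """
    config.validate()
    rng = config.rng(3)
    C = config.n_conditions
    tg, mg = config.target_grid(), config.move_grid()
    M = config.nominal_move_time

    def profiles(t_m):
        return np.stack([_gauss(t_m, 100.0, 110.0), _gauss(t_m, 280.0, 140.0)])

    if equal_amplitudes:
        amps = np.ones((2, C))
    else:
        # strongly dispersed positive amplitudes (CV > 1.5): muscle envelopes
        # share a temporal profile but their magnitude varies severalfold
        # across reach conditions
        amps = 0.02 + rng.gamma(0.35, 1.0, size=(2, C))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=C)
    osc_amp = 0.5 + rng.uniform(0.0, 1.0, size=C)

    def comps_on(t_m):
        prof = profiles(t_m)  # (2, T)
        shared = amps[:, :, None] * prof[:, None, :]
        env = _sigmoid((t_m + config.trigger_lead) / 20.0)
        ang = (2.0 * np.pi * config.rotation_frequency / 1000.0
               * (t_m + config.trigger_lead))[None, :] + phase[:, None]
        osc = np.stack([osc_amp[:, None] * env * np.sin(ang),
                        osc_amp[:, None] * env * np.cos(ang)])
        return np.concatenate([shared, osc], axis=0)  # (4, C, T)

    x_t = comps_on(tg - M)
    x_m = comps_on(mg)
    # unit-variance normalization over the concatenated grids
    x_all = np.concatenate([x_t, x_m], axis=2)
    sd = x_all.reshape(4, -1).std(axis=1)
    sd[sd == 0] = 1.0
    x_t, x_m, x_all = x_t / sd[:, None, None], x_m / sd[:, None, None], x_all / sd[:, None, None]

    Wm = np.empty((n_channels, 4))
    Wm[:, :2] = 0.4 + np.abs(rng.standard_normal((n_channels, 2)))
    Wm[:, 2:] = 0.35 * rng.standard_normal((n_channels, 2))
    scale = config.rate_range / 4.0
    tgt = np.clip(5.0 + scale * np.einsum("ni,ict->nct", Wm, x_t), 0.0, None)
    mov = np.clip(5.0 + scale * np.einsum("ni,ict->nct", Wm, x_m), 0.0, None)

    time = np.concatenate([tg, mg])
    seg = np.concatenate([np.full(tg.size, SEG_TARGET, np.int8),
                          np.full(mg.size, SEG_MOVE, np.int8)])
    labels = (["condition-invariant"] * 2 if equal_amplitudes
              else ["condition-specific"] * 2) + ["condition-specific"] * 2
    comp_set = ComponentSet(x=x_all, time=time, segment=seg, labels=labels)
    pop = PopulationResponse(
        target_rates=tgt,
        move_rates=mov,
        target_time=tg,
        move_time=mg,
        meta={"kind": "muscle", "seed": config.seed},
        ground_truth={"weights": Wm, "components": comp_set, "model": None,
                      "scale": scale, "baseline": 5.0, "config": config,
                      "condition_speed": None},
    )
    pop.validate()
    return pop


def make_counterexample(spec: CounterexampleSpec) -> ComponentSet:
    """``x1 = g_c sin(t)``, ``x2 = h_c sin(3t)`` on ``T`` samples of [0, 2pi).

    Both components are perfectly condition-correlated (scalar multiples of
    one shared time course) yet, for generic ``g``/``h``, no linear
    combination of them is condition-invariant.
    """
    spec.validate()
    g = np.asarray(spec.g, float)
    h = np.asarray(spec.h, float)
    t = np.linspace(0.0, 2.0 * np.pi, spec.T, endpoint=False)
    x1 = g[:, None] * np.sin(t)[None, :]
    x2 = h[:, None] * np.sin(3.0 * t)[None, :]
    return ComponentSet(
        x=np.stack([x1, x2]),
        time=t,
        segment=np.zeros(spec.T, np.int8),
        labels=["condition-specific", "condition-specific"],
    )
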