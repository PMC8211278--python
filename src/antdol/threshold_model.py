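"""Fixed response-threshold model of task allocation with type heterogeneity.

Implements a seeded agent-based simulator of a colony of ``n`` agents facing
``m`` tasks.  Each task ``j`` carries a stimulus ``s_j`` signalling group-level
demand.  The stimulus grows at a constant demand rate ``delta_j`` and is
reduced by active workers in proportion to their type-specific efficiency
``alpha_j``:

    s_{j,t+1} = max(0, s_{j,t} + delta_j - (sum_types alpha_j^k * n_{j,t}^k) / n)

Each agent ``i`` holds a fixed threshold ``theta_ij`` per task, drawn once at
t = 0 from Normal(mu_j, sigma_j * mu_j) (sigma is the s.d. expressed as a
fraction of the mean).  An inactive agent inspecting stimulus ``s_j`` commits
to task ``j`` with probability

    P_ij = s_j^eta / (s_j^eta + theta_ij^eta),

where ``eta`` sets the steepness of the response function.  Active agents
quit spontaneously with probability ``tau`` per step and cannot switch tasks
without quitting first.

The simulator advances in synchronous steps: (1) active agents quit with
probability tau (quitters do not re-evaluate this step); (2) each agent that
was inactive at the start of the step inspects the m stimuli in an
independently shuffled order and commits to the first task whose response
probability exceeds a fresh uniform draw, all agents seeing the step-start
stimulus values; (3) stimuli update once from the post-commitment active
counts, floored at zero.

Replicates are vectorized: a batch of replicate colonies advances in lockstep,
but every replicate consumes its own RNG stream (spawned from the master seed
by replicate index), so any single replicate re-run alone is bit-identical to
its slice of the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TypeParams",
    "SimConfig",
    "SimResult",
    "BatchResult",
    "INACTIVE",
    "sample_thresholds",
    "response_probability",
    "update_stimuli",
    "step",
    "run_simulation",
    "run_batch",
]

#: Task-state code for an agent not performing any task.
INACTIVE = -1

# Steps of random draws generated per RNG request; fixed so that a replicate's
# stream is identical whether it runs alone or inside a batch.
_CHUNK = 1024


def _as_task_vector(value, m: int, name: str) -> np.ndarray:
    """Broadcast a scalar or length-m sequence to a float vector of length m."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(m, float(arr))
    if arr.shape != (m,):
        raise ValueError(f"{name} must be a scalar or length-{m} vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class TypeParams:
    """Per-type behavioral parameters, one entry per task.

    Parameters
    ----------
    label : str
        Type name (e.g. ``"X"`` or ``"Y"``).
    mu : float or sequence of float
        Mean response threshold per task (stimulus units, > 0).
    sigma : float or sequence of float
        Normalized threshold s.d. per task, expressed as a fraction of the
        corresponding mean (dimensionless, >= 0).
    alpha : float or sequence of float
        Task performance efficiency per task: the rate at which one active
        worker reduces the stimulus (stimulus units per agent per step, > 0).
    """

    label: str
    mu: float | Sequence[float]
    sigma: float | Sequence[float] = 0.1
    alpha: float | Sequence[float] = 2.0

    def vectors(self, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Validated (mu, sigma, alpha) vectors of length m."""
        mu = _as_task_vector(self.mu, m, "mu")
        sigma = _as_task_vector(self.sigma, m, "sigma")
        alpha = _as_task_vector(self.alpha, m, "alpha")
        if np.any(mu <= 0):
            raise ValueError("mu must be > 0 for every task")
        if np.any(sigma < 0):
            raise ValueError("sigma must be >= 0")
        if np.any(alpha <= 0):
            raise ValueError("alpha must be > 0")
        return mu, sigma, alpha


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one colony simulation.

    ``composition`` lists (TypeParams, count) pairs; agents are laid out in
    that order, so type labels of the result follow the composition order.
    """

    composition: tuple[tuple[TypeParams, int], ...]
    m: int = 2
    delta: float | Sequence[float] = 0.6
    eta: float = 7.0
    tau: float = 0.2
    T: int = 10_000
    seed: int = 0
    initial_stimulus: float | Sequence[float] = 0.0

    def __post_init__(self):
        object.__setattr__(self, "composition", tuple((tp, int(c)) for tp, c in self.composition))
        if self.n < 1:
            raise ValueError("colony must contain at least one agent")
        if any(c < 0 for _, c in self.composition):
            raise ValueError("type counts must be non-negative")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must be in [0, 1]")
        if not (self.eta > 0):
            raise ValueError("eta must be > 0")
        delta = _as_task_vector(self.delta, self.m, "delta")
        if np.any(delta < 0):
            raise ValueError("delta must be >= 0")
        s0 = _as_task_vector(self.initial_stimulus, self.m, "initial_stimulus")
        if np.any(s0 < 0):
            raise ValueError("initial_stimulus must be >= 0")

    @property
    def n(self) -> int:
        return sum(c for _, c in self.composition)

    @property
    def type_labels(self) -> np.ndarray:
        """Length-n array of type labels, in composition order."""
        return np.asarray(
            [tp.label for tp, c in self.composition for _ in range(c)], dtype=object
        )

    def delta_vector(self) -> np.ndarray:
        return _as_task_vector(self.delta, self.m, "delta")

    def initial_stimulus_vector(self) -> np.ndarray:
        return _as_task_vector(self.initial_stimulus, self.m, "initial_stimulus")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class BatchResult:
    """Stacked output of ``run_batch``: R replicate colonies run in lockstep.

    Attributes
    ----------
    task_history : (R, T, n) int8 array
        Post-step task state of each agent; ``INACTIVE`` (-1) or task index.
    stimulus_history : (R, T, m) float array
        Stimulus vector after each step's update.
    thresholds : (R, n, m) float array
        Thresholds sampled at t = 0.
    type_labels : (n,) object array
        Type label per agent (identical across replicates).
    config : SimConfig
    """

    task_history: np.ndarray
    stimulus_history: np.ndarray
    thresholds: np.ndarray
    type_labels: np.ndarray
    config: SimConfig

    @property
    def n_replicates(self) -> int:
        return self.task_history.shape[0]

    def replicate(self, r: int) -> "SimResult":
        return SimResult(
            task_history=self.task_history[r],
            stimulus_history=self.stimulus_history[r],
            thresholds=self.thresholds[r],
            type_labels=self.type_labels,
            config=self.config,
        )


@dataclass
class SimResult:
    """Output of a single colony simulation (see ``BatchResult`` for fields,
    without the leading replicate axis)."""

    task_history: np.ndarray  # (T, n) int8
    stimulus_history: np.ndarray  # (T, m)
    thresholds: np.ndarray  # (n, m)
    type_labels: np.ndarray  # (n,)
    config: SimConfig


def sample_thresholds(type_params: TypeParams, count: int, rng: np.random.Generator, m: int = 2) -> np.ndarray:
    """Sample a (count, m) threshold matrix for agents of one type.

    Each column j is drawn from Normal(mu_j, sigma_j * mu_j); non-positive
    draws are resampled so thresholds stay strictly positive without
    distorting the distribution shape (at the sigma values of interest,
    sigma <= 0.5, the resampling probability is negligible).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    mu, sigma, _ = type_params.vectors(m)
    theta = rng.normal(mu, sigma * mu, size=(count, m))
    # Resample non-positive draws (probability ~ Phi(-1/sigma) per entry).
    bad = theta <= 0
    while np.any(bad):
        idx = np.nonzero(bad)
        theta[idx] = rng.normal(mu[idx[1]], (sigma * mu)[idx[1]])
        bad = theta <= 0
    return theta


def response_probability(s, theta, eta):
    """Probability that stimulus level ``s`` triggers an agent with threshold
    ``theta``: s^eta / (s^eta + theta^eta).  Returns 0 at s = 0 and exactly
    0.5 at s = theta for any eta.
    """
    s = np.asarray(s, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
        raise ValueError("theta must be positive and finite")
    if np.any(s < 0):
        raise ValueError("stimulus must be >= 0")
    if not np.all(np.asarray(eta) > 0):
        raise ValueError("eta must be > 0")
    # Work with the ratio (s / theta)^eta for numerical stability at large eta.
    ratio = np.where(s > 0, s / theta, 0.0)
    with np.errstate(over="ignore"):
        r_eta = ratio**eta
        p = r_eta / (1.0 + r_eta)
    # Overflowed ratios correspond to p -> 1.
    p = np.where(np.isfinite(r_eta), p, 1.0)
    return p if p.ndim else float(p)


def update_stimuli(stimulus: np.ndarray, config: SimConfig, active_counts: np.ndarray) -> np.ndarray:
    """One demand/work update of the stimulus vector.

    ``active_counts`` is a (n_types, m) array of the number of active workers
    per type and task.  The work term is the efficiency-weighted count divided
    by colony size n; the result is floored at zero.
    """
    counts = np.asarray(active_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("active counts must be non-negative")
    alphas = np.stack([tp.vectors(config.m)[2] for tp, _ in config.composition])
    if counts.shape != alphas.shape:
        raise ValueError(f"active_counts must have shape {alphas.shape}")
    for k, (_, n_k) in enumerate(config.composition):
        if counts[k].sum() > n_k:
            raise ValueError("active counts exceed type population")
    work = (alphas * counts).sum(axis=0) / config.n
    return np.maximum(0.0, np.asarray(stimulus, dtype=float) + config.delta_vector() - work)


@dataclass
class ColonyState:
    """Mutable state of one colony between steps."""

    thresholds: np.ndarray  # (n, m)
    task_state: np.ndarray  # (n,) int, INACTIVE or task index
    stimulus: np.ndarray  # (m,)
    t: int = 0

    def active_counts(self, config: SimConfig) -> np.ndarray:
        """(n_types, m) active-worker counts in composition order."""
        counts = np.zeros((len(config.composition), config.m))
        start = 0
        for k, (_, n_k) in enumerate(config.composition):
            states = self.task_state[start : start + n_k]
            for j in range(config.m):
                counts[k, j] = np.count_nonzero(states == j)
            start += n_k
        return counts


def step(state: ColonyState, config: SimConfig, rng: np.random.Generator) -> ColonyState:
    """Advance one colony by one synchronous step (reference implementation).

    The batch engine in :func:`run_batch` is the performance path; this
    explicit version defines the update semantics and backs the unit tests.
    """
    n, m = state.thresholds.shape
    task = state.task_state.copy()
    s0 = state.stimulus.copy()

    was_inactive = task == INACTIVE
    # Phase 1: active agents quit with probability tau; quitters do not
    # re-evaluate stimuli until the next step.
    active = ~was_inactive
    quits = active & (rng.random(n) < config.tau)
    task[quits] = INACTIVE

    # Phase 2: agents inactive at step start inspect stimuli in a shuffled
    # order; all use the step-start stimulus values, so processing order
    # across agents is immaterial.
    evaluators = np.nonzero(was_inactive)[0]
    rng.shuffle(evaluators)  # kept for parity with the narrative; no effect
    p = response_probability(s0[None, :], state.thresholds, config.eta)
    for i in evaluators:
        order = rng.permutation(m)
        for j in order:
            if rng.random() < p[i, j]:
                task[i] = j
                break

    # Phase 3: one stimulus update from post-commitment active counts.
    new_state = ColonyState(state.thresholds, task, s0, state.t + 1)
    new_state.stimulus = update_stimuli(s0, config, new_state.active_counts(config))
    return new_state


def _batch_engine(
    thresholds: np.ndarray,
    alphas_by_agent: np.ndarray,
    delta: np.ndarray,
    eta: float,
    tau: float,
    T: int,
    s0: np.ndarray,
    rngs: list[np.random.Generator],
) -> tuple[np.ndarray, np.ndarray]:
    """Lockstep simulation of R replicates.

    thresholds: (R, n, m); alphas_by_agent: (n, m) efficiency of each agent's
    type; delta: (m,); s0: (m,).  Returns (task_history (R, T, n) int8,
    stimulus_history (R, T, m)).

    Random draws are generated per replicate in fixed chunks of _CHUNK steps,
    so replicate streams do not depend on the batch size.

    For m = 2 the sequential inspect-in-random-order rule is sampled in closed
    form: enumerating the two equally likely inspection orders gives outcome
    probabilities q_0 = (p_0 + (1-p_1) p_0) / 2, q_1 = (p_1 + (1-p_0) p_1) / 2
    and 1 - q_0 - q_1 for staying inactive, which one uniform draw per agent
    samples exactly.  For m > 2 the order is materialized via argsort and
    tasks are inspected sequentially.
    """
    R, n, m = thresholds.shape
    inv_theta = 1.0 / thresholds  # thresholds fixed; precompute
    int_eta = int(eta) if float(eta).is_integer() and 1 <= eta <= 64 else None

    task = np.full((R, n), INACTIVE, dtype=np.int8)
    s = np.tile(s0, (R, 1))
    inv_n = 1.0 / n

    task_hist = np.empty((R, T, n), dtype=np.int8)
    stim_hist = np.empty((R, T, m), dtype=float)

    rows = np.arange(R)[:, None]
    cols = np.arange(n)[None, :]
    closed_form = m == 2

    for t0 in range(0, T, _CHUNK):
        chunk = min(_CHUNK, T - t0)
        quit_draws = np.empty((R, chunk, n))
        if closed_form:
            select_draws = np.empty((R, chunk, n))
            for r, rng in enumerate(rngs):
                quit_draws[r] = rng.random((chunk, n))
                select_draws[r] = rng.random((chunk, n))
        else:
            resp_draws = np.empty((R, chunk, n, m))
            order_keys = np.empty((R, chunk, n, m))
            for r, rng in enumerate(rngs):
                quit_draws[r] = rng.random((chunk, n))
                resp_draws[r] = rng.random((chunk, n, m))
                order_keys[r] = rng.random((chunk, n, m))
            order = np.argsort(order_keys, axis=-1)

        for k in range(chunk):
            was_inactive = task == INACTIVE
            # Phase 1: spontaneous quitting.
            task = np.where(~was_inactive & (quit_draws[:, k] < tau), INACTIVE, task)

            # Phase 2: response probabilities from step-start stimuli,
            # computed from the ratio (s/theta)^eta for stability at large eta.
            ratio = s[:, None, :] * inv_theta  # (R, n, m)
            if int_eta is not None:
                r_eta = _int_power(ratio, int_eta)
            else:
                with np.errstate(over="ignore"):
                    r_eta = ratio**eta
            with np.errstate(invalid="ignore"):
                p = r_eta / (1.0 + r_eta)
            p = np.where(np.isfinite(r_eta), p, 1.0)

            if closed_form:
                p0, p1 = p[:, :, 0], p[:, :, 1]
                q0 = 0.5 * (p0 + (1.0 - p1) * p0)
                q1 = 0.5 * (p1 + (1.0 - p0) * p1)
                u = select_draws[:, k]
                chosen = np.where(u < q0, 0, np.where(u < q0 + q1, 1, INACTIVE)).astype(np.int8)
            else:
                chosen = np.full((R, n), INACTIVE, dtype=np.int8)
                undecided = was_inactive.copy()
                for pos in range(m):
                    j = order[:, k, :, pos]  # (R, n) task inspected at this position
                    u = resp_draws[rows, k, cols, j]
                    pj = np.take_along_axis(p, j[:, :, None], axis=2)[:, :, 0]
                    commit = undecided & (u < pj)
                    chosen = np.where(commit, j.astype(np.int8), chosen)
                    undecided &= ~commit
            task = np.where(was_inactive, chosen, task)

            # Phase 3: stimulus update from post-commitment counts.
            work = np.zeros((R, m))
            for j in range(m):
                work[:, j] = ((task == j) * alphas_by_agent[None, :, j]).sum(axis=1)
            s = np.maximum(0.0, s + delta[None, :] - work * inv_n)

            task_hist[:, t0 + k] = task
            stim_hist[:, t0 + k] = s

    return task_hist, stim_hist


def _int_power(x: np.ndarray, k: int) -> np.ndarray:
    """x**k for small integer k by squaring (faster than float pow, and
    overflow-free to inf)."""
    with np.errstate(over="ignore"):
        result = None
        base = x
        while k:
            if k & 1:
                result = base if result is None else result * base
            k >>= 1
            if k:
                base = base * base
        return result


def _replicate_rngs(seed: int, n_replicates: int) -> list[np.random.Generator]:
    """Independent per-replicate generators spawned from the master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n_replicates)]


def run_batch(config: SimConfig, n_replicates: int, seed: int | None = None) -> BatchResult:
    """Run ``n_replicates`` independent colonies under one configuration.

    Thresholds are resampled per replicate.  The master seed defaults to
    ``config.seed``; replicate r uses the r-th spawned stream, so results are
    reproducible per replicate regardless of batch size.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    master = config.seed if seed is None else int(seed)
    rngs = _replicate_rngs(master, n_replicates)

    m, n = config.m, config.n
    thresholds = np.empty((n_replicates, n, m))
    for r, rng in enumerate(rngs):
        start = 0
        for tp, count in config.composition:
            if count == 0:
                continue
            thresholds[r, start : start + count] = sample_thresholds(tp, count, rng, m)
            start += count

    alphas_by_agent = np.empty((n, m))
    start = 0
    for tp, count in config.composition:
        alphas_by_agent[start : start + count] = tp.vectors(m)[2]
        start += count

    task_hist, stim_hist = _batch_engine(
        thresholds,
        alphas_by_agent,
        config.delta_vector(),
        config.eta,
        config.tau,
        config.T,
        config.initial_stimulus_vector(),
        rngs,
    )
    return BatchResult(task_hist, stim_hist, thresholds, config.type_labels, config)


def run_simulation(config: SimConfig) -> SimResult:
    """Run a single colony for ``config.T`` steps; reproducible from the seed."""
    return run_batch(config, 1, seed=config.seed).replicate(0)
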