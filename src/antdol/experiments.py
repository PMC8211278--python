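"""Seeded simulation campaigns: pure/mixed scenarios, the efficiency-threshold
phase map, composition-ratio sweeps, and short stimulus traces.

The named scenarios pit a focal type X against a reference type Y with
efficiency alpha = 2 and mean threshold mu = 10:

* ``baseline`` — threshold-mean difference only (mu_X = 10, mu_Y = 20).
* ``variance_only`` — threshold-variance difference only (sigma 0.1 vs 0.5).
* ``x1_high_demand`` / ``x1_low_demand`` — X = (alpha 4.5, mu 11) under
  demand delta = 1.3 / 0.6: asymmetric behavioral convergence, upward or
  downward depending on whether the less efficient type can keep up alone.
* ``x3_divergence`` — X = (alpha 3, mu 15): divergence.
* ``x2_no_effect`` — X = (alpha 1.5, mu 7.5): no effect of mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from antdol.dol_metrics import (
    MixingReport,
    behavioral_variation,
    frequency_array,
    mixing_effect,
    replicate_type_means,
    specialization,
    specialization_by_task,
    task_performance_frequency,
)
from antdol.threshold_model import BatchResult, SimConfig, TypeParams, run_batch

__all__ = [
    "Scenario",
    "ScenarioResult",
    "PhaseGrid",
    "SCENARIOS",
    "get_scenario",
    "run_scenario",
    "run_phase_grid",
    "run_ratio_sweep",
    "run_stimulus_traces",
]


@dataclass(frozen=True)
class Scenario:
    """A pure-X / pure-Y / mixed campaign with shared global parameters."""

    name: str
    type_x: TypeParams
    type_y: TypeParams
    n: int = 16
    mixed_ratio: tuple[int, int] | None = None  # defaults to a 1:1 mix
    delta: float = 0.6
    eta: float = 7.0
    tau: float = 0.2
    T: int = 10_000
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        ratio = self.mixed_ratio
        if ratio is not None and sum(ratio) != self.n:
            raise ValueError("mixed_ratio must sum to the colony size n")

    def ratio(self) -> tuple[int, int]:
        return self.mixed_ratio if self.mixed_ratio is not None else (self.n // 2, self.n - self.n // 2)

    def config(self, composition: str, seed: int = 0) -> SimConfig:
        """SimConfig for one arm: 'pure_x', 'pure_y', or 'mixed'."""
        if composition == "pure_x":
            comp = ((self.type_x, self.n),)
        elif composition == "pure_y":
            comp = ((self.type_y, self.n),)
        elif composition == "mixed":
            nx, ny = self.ratio()
            comp = ((self.type_x, nx), (self.type_y, ny))
        else:
            raise ValueError(f"unknown composition {composition!r}")
        return SimConfig(
            composition=comp, delta=self.delta, eta=self.eta, tau=self.tau, T=self.T, seed=seed
        )


def _arm_seeds(master: int, n_arms: int = 3) -> list[int]:
    """Deterministic per-arm seeds derived from a master seed."""
    return [int(s) for s in np.random.SeedSequence(int(master)).generate_state(n_arms)]


_Y = TypeParams("Y", mu=10.0, sigma=0.1, alpha=2.0)

SCENARIOS: dict[str, Scenario] = {
    "baseline": Scenario(
        "baseline",
        type_x=TypeParams("X", mu=10.0, sigma=0.1, alpha=2.0),
        type_y=TypeParams("Y", mu=20.0, sigma=0.1, alpha=2.0),
    ),
    "variance_only": Scenario(
        "variance_only",
        type_x=TypeParams("X", mu=10.0, sigma=0.1, alpha=2.0),
        type_y=TypeParams("Y", mu=10.0, sigma=0.5, alpha=2.0),
    ),
    "x1_high_demand": Scenario(
        "x1_high_demand", type_x=TypeParams("X1", mu=11.0, sigma=0.1, alpha=4.5), type_y=_Y, delta=1.3
    ),
    "x1_low_demand": Scenario(
        "x1_low_demand", type_x=TypeParams("X1", mu=11.0, sigma=0.1, alpha=4.5), type_y=_Y, delta=0.6
    ),
    "x3_divergence": Scenario(
        "x3_divergence", type_x=TypeParams("X3", mu=15.0, sigma=0.1, alpha=3.0), type_y=_Y, delta=0.6
    ),
    "x2_no_effect": Scenario(
        "x2_no_effect", type_x=TypeParams("X2", mu=7.5, sigma=0.1, alpha=1.5), type_y=_Y, delta=0.6
    ),
}


def get_scenario(name: str, **overrides) -> Scenario:
    """Look up a named scenario, optionally overriding fields (e.g. seed=...)."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    sc = SCENARIOS[name]
    return replace(sc, **overrides) if overrides else sc


@dataclass
class ScenarioResult:
    """Per-composition batches, tidy DOL summary, and the mixing report."""

    scenario: Scenario
    batches: dict[str, BatchResult]
    summary: pd.DataFrame
    report: MixingReport
    task: int = 0

    def frequency_table(self, composition: str) -> pd.DataFrame:
        return task_performance_frequency(self.batches[composition])


def _summarize_batch(batch: BatchResult, composition: str, window: int) -> pd.DataFrame:
    """Per-(replicate, task) mean behavior, variation, and specialization."""
    freq = frequency_array(batch)  # (R, n, m)
    R, n, m = freq.shape
    spec = specialization_by_task(batch, window=window)  # (R, m)
    rows = []
    labels = batch.type_labels
    for j in range(m):
        row = {
            "composition": composition,
            "task": j,
            "replicate": np.arange(R),
            "mean_behavior": freq[:, :, j].mean(axis=1),
            "variation": freq[:, :, j].std(axis=1, ddof=1),
            "specialization": spec[:, j],
        }
        for lab in pd.unique(labels):
            mask = labels == lab
            row[f"mean_{lab}"] = freq[:, mask, j].mean(axis=1)
        rows.append(pd.DataFrame(row))
    return pd.concat(rows, ignore_index=True)


def run_scenario(
    scenario: Scenario | str,
    seed: int | None = None,
    task: int = 0,
    window: int = 200,
    alpha: float = 0.05,
    keep_batches: bool = True,
) -> ScenarioResult:
    """Run the three compositions of a scenario and compute DOL metrics.

    Each composition arm gets an independent seed stream derived from the
    master seed, and each replicate within an arm its own spawned stream, so
    any arm or replicate can be re-run bit-exactly in isolation.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    master = scenario.seed if seed is None else int(seed)
    seeds = _arm_seeds(master)
    batches: dict[str, BatchResult] = {}
    summaries = []
    for arm_seed, comp in zip(seeds, ("pure_x", "pure_y", "mixed")):
        batch = run_batch(scenario.config(comp), scenario.replicates, seed=arm_seed)
        batches[comp] = batch
        summaries.append(_summarize_batch(batch, comp, window))
    summary = pd.concat(summaries, ignore_index=True)

    lab_x, lab_y = scenario.type_x.label, scenario.type_y.label
    report = mixing_effect(
        replicate_type_means(batches["pure_x"], lab_x, task),
        replicate_type_means(batches["pure_y"], lab_y, task),
        replicate_type_means(batches["mixed"], lab_x, task),
        replicate_type_means(batches["mixed"], lab_y, task),
        labels=(lab_x, lab_y),
        alpha=alpha,
    )
    if not keep_batches:
        batches = {}
    return ScenarioResult(scenario, batches, summary, report, task)


@dataclass(frozen=True)
class PhaseGrid:
    """Grid over type X's efficiency and mean threshold, Y held fixed."""

    alpha_x: tuple[float, ...] = tuple(np.linspace(1.0, 5.0, 25))
    mu_x: tuple[float, ...] = tuple(np.linspace(5.0, 20.0, 25))
    type_y: TypeParams = _Y
    sigma_x: float = 0.1
    n: int = 16
    delta: float = 0.6
    eta: float = 7.0
    tau: float = 0.2
    T: int = 10_000
    replicates: int = 50
    seed: int = 0

    def __post_init__(self):
        if len(self.alpha_x) == 0 or len(self.mu_x) == 0:
            raise ValueError("grid must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def run_phase_grid(grid: PhaseGrid, task: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Mixing effect per (alpha_x, mu_x) cell, with Y fixed.

    The pure-Y arm does not depend on the cell and is simulated once.  Each
    cell's pure-X and mixed arms use seeds derived from (master, cell index),
    so any single cell reproduces bit-exactly in isolation.
    """
    base = Scenario(
        "phase_cell",
        type_x=TypeParams("X", mu=1.0, sigma=grid.sigma_x, alpha=1.0),
        type_y=grid.type_y,
        n=grid.n,
        delta=grid.delta,
        eta=grid.eta,
        tau=grid.tau,
        T=grid.T,
        replicates=grid.replicates,
    )
    y_seed = int(np.random.SeedSequence(int(grid.seed)).generate_state(1)[0])
    pure_y = run_batch(base.config("pure_y"), grid.replicates, seed=y_seed)
    y_means = replicate_type_means(pure_y, grid.type_y.label, task)

    rows = []
    for ia, a_x in enumerate(grid.alpha_x):
        for im, m_x in enumerate(grid.mu_x):
            cell_seed = np.random.SeedSequence([int(grid.seed), ia, im])
            sx, sm = (int(s) for s in cell_seed.generate_state(2))
            sc = replace(base, type_x=TypeParams("X", mu=float(m_x), sigma=grid.sigma_x, alpha=float(a_x)))
            pure_x = run_batch(sc.config("pure_x"), grid.replicates, seed=sx)
            mixed = run_batch(sc.config("mixed"), grid.replicates, seed=sm)
            report = mixing_effect(
                replicate_type_means(pure_x, "X", task),
                y_means,
                replicate_type_means(mixed, "X", task),
                replicate_type_means(mixed, grid.type_y.label, task),
                labels=("X", grid.type_y.label),
                alpha=alpha,
            )
            rows.append(
                {
                    "alpha_x": float(a_x),
                    "mu_x": float(m_x),
                    "effect": report.effect,
                    "effect_se": report.effect_se,
                    "p_value": report.p_value,
                    "classification": report.classification,
                }
            )
    return pd.DataFrame(rows)


def run_ratio_sweep(
    scenario: Scenario | str,
    ratios: list[tuple[int, int]] | None = None,
    seed: int | None = None,
    task: int = 0,
) -> pd.DataFrame:
    """Colony and type means across X:Y composition ratios.

    Includes a ``linear_null`` column: the linear interpolation between the
    two pure endpoints' colony means as a function of the X fraction, the
    null hypothesis of linear behavioral effects of mixing.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    n = scenario.n
    if ratios is None:
        ratios = [(nx, n - nx) for nx in range(0, n + 1, 2)]
    for nx, ny in ratios:
        if nx + ny != n or nx < 0 or ny < 0:
            raise ValueError(f"ratio {nx}:{ny} incompatible with colony size {n}")
    master = scenario.seed if seed is None else int(seed)
    rows = []
    for idx, (nx, ny) in enumerate(ratios):
        comp = tuple((tp, c) for tp, c in ((scenario.type_x, nx), (scenario.type_y, ny)) if c > 0)
        cfg = SimConfig(
            composition=comp, delta=scenario.delta, eta=scenario.eta, tau=scenario.tau, T=scenario.T
        )
        arm_seed = int(np.random.SeedSequence([master, idx]).generate_state(1)[0])
        batch = run_batch(cfg, scenario.replicates, seed=arm_seed)
        freq = frequency_array(batch)[:, :, task]  # (R, n)
        labels = batch.type_labels
        row = {
            "n_x": nx,
            "n_y": ny,
            "fraction_x": nx / n,
            "colony_mean": float(freq.mean()),
            "colony_se": float(freq.mean(axis=1).std(ddof=1) / np.sqrt(len(freq))),
            "mean_x": float(freq[:, labels == scenario.type_x.label].mean()) if nx else np.nan,
            "mean_y": float(freq[:, labels == scenario.type_y.label].mean()) if ny else np.nan,
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    pure_y_mean = out.loc[out["n_x"] == 0, "colony_mean"]
    pure_x_mean = out.loc[out["n_y"] == 0, "colony_mean"]
    if len(pure_y_mean) and len(pure_x_mean):
        y0, x1 = float(pure_y_mean.iloc[0]), float(pure_x_mean.iloc[0])
        out["linear_null"] = y0 + (x1 - y0) * out["fraction_x"]
    else:
        out["linear_null"] = np.nan
    return out


def run_stimulus_traces(
    scenario: Scenario | str, T: int = 1000, seed: int | None = None, replicates: int = 1
) -> pd.DataFrame:
    """Short stimulus trajectories per composition for phase-plane inspection.

    Returns a tidy frame (composition, replicate, t, task, stimulus); t runs
    from 1 (after the first update) to T.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    scenario = replace(scenario, T=T)
    master = scenario.seed if seed is None else int(seed)
    seeds = _arm_seeds(master)
    frames = []
    for arm_seed, comp in zip(seeds, ("pure_x", "pure_y", "mixed")):
        batch = run_batch(scenario.config(comp), replicates, seed=arm_seed)
        R, T_, m = batch.stimulus_history.shape
        rep, t, task = np.meshgrid(np.arange(R), np.arange(1, T_ + 1), np.arange(m), indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "composition": comp,
                    "replicate": rep.ravel(),
                    "t": t.ravel(),
                    "task": task.ravel(),
                    "stimulus": batch.stimulus_history.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
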