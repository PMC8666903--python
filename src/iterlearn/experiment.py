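"""Batch experiments: replicate runs, crossover statistics, trace I/O, figures.

The headline observable is the *crossover generation*: the first generation
(one generation = ``n_agents`` iterations) at whose final iteration the oldest
agent assigns more posterior mass to combinatorial languages than to holistic
ones.  Crossover is evaluated per run and then summarized (median over runs,
with non-crossing runs counted as +inf), because the phenomenon of interest is
whether the *majority of runs* have crossed by a given generation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .language_space import CLASS_NAMES, COMBINATORIAL, HOLISTIC, LanguageSpace
from .population import ClassMassTrace, SimulationConfig, run_simulation

__all__ = [
    "BatchResult",
    "CrossoverSummary",
    "run_batch",
    "run_rng",
    "crossover_generation",
    "summarize_crossovers",
    "write_trace",
    "read_trace",
    "plot_panels",
]

_TRACE_MAGIC = "# iterlearn-trace "


class TraceFormatError(ValueError):
    """A trace file does not conform to the expected CSV layout."""


@dataclass
class BatchResult:
    """Replicate traces from one configuration plus their pointwise mean."""

    traces: list[ClassMassTrace]
    mean_masses: np.ndarray
    config: SimulationConfig
    base_seed: int
    n_runs: int

    @property
    def n_iterations(self) -> int:
        return self.mean_masses.shape[0]


@dataclass
class CrossoverSummary:
    """Per-run crossover generations and their aggregate statistics.

    ``per_run`` holds one entry per run: the first generation at which
    combinatorial mass exceeds holistic mass in the oldest agent, or None if
    the run never crossed.  ``median`` uses +inf for non-crossing runs so a
    majority of non-crossing runs yields an infinite median rather than a
    downward-biased finite one.
    """

    per_run: list[Optional[int]]
    median: float
    fraction_crossed_by: np.ndarray  # index g-1 → fraction of runs crossed by generation g
    n_generations: int

    @property
    def n_crossed(self) -> int:
        return sum(1 for g in self.per_run if g is not None)


def run_rng(base_seed: int, run_index: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one run of a batch."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(run_index,))
    )


def run_batch(
    config: SimulationConfig,
    n_runs: int,
    base_seed: int,
    space: LanguageSpace,
    progress: bool = False,
) -> BatchResult:
    """Run ``n_runs`` independent simulations and average their traces pointwise."""
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    traces = []
    for run_index in range(n_runs):
        trace = run_simulation(
            config,
            space,
            rng=run_rng(base_seed, run_index),
            metadata={"base_seed": base_seed, "run": run_index},
        )
        traces.append(trace)
        if progress:
            print(f"run {run_index + 1}/{n_runs} done")
    mean_masses = np.mean([t.masses for t in traces], axis=0)
    return BatchResult(
        traces=traces,
        mean_masses=mean_masses,
        config=config,
        base_seed=base_seed,
        n_runs=n_runs,
    )


def crossover_generation(trace: ClassMassTrace, n_agents: int) -> Optional[int]:
    """Generation containing the first iteration with combinatorial > holistic mass.

    Generation g (1-based) covers iterations (g-1)*n_agents + 1 .. g*n_agents.
    The trace is scanned iteration by iteration for the first recorded point at
    which the oldest agent assigns more mass to combinatorial than to holistic
    languages; that iteration's generation is returned (a crossover at
    iteration 35 with 10 agents is generation 4).  Returns None if the trace
    never crosses.
    """
    comb = trace.masses[:, COMBINATORIAL]
    hol = trace.masses[:, HOLISTIC]
    crossed = np.flatnonzero(comb > hol)
    if crossed.size == 0:
        return None
    first_iteration = int(crossed[0]) + 1
    return -(-first_iteration // n_agents)  # ceil division


def summarize_crossovers(batch: BatchResult) -> CrossoverSummary:
    """Median crossover generation and cumulative crossing fractions for a batch."""
    n_agents = batch.config.n_agents
    n_generations = batch.n_iterations // n_agents
    per_run = [crossover_generation(t, n_agents) for t in batch.traces]
    as_float = np.array([np.inf if g is None else float(g) for g in per_run])
    median = float(np.median(as_float))
    gens = np.arange(1, n_generations + 1)
    fraction = np.array([(as_float <= g).mean() for g in gens])
    return CrossoverSummary(
        per_run=per_run,
        median=median,
        fraction_crossed_by=fraction,
        n_generations=n_generations,
    )


# ---------------------------------------------------------------------------
# trace I/O: long-format CSV with a JSON metadata header line
# ---------------------------------------------------------------------------

def _config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_agents": config.n_agents,
        "episodes_per_iteration": config.episodes_per_iteration,
        "n_iterations": config.n_iterations,
        "epsilon": config.epsilon,
        "gamma": config.gamma,
        "condition": config.condition,
        "initial_language": list(config.initial_language.mapping),
        "seed": config.seed,
    }


def _config_from_dict(payload: dict) -> SimulationConfig:
    from .language_space import Language

    payload = dict(payload)
    payload["initial_language"] = Language(tuple(payload["initial_language"]))
    return SimulationConfig(**payload)


def write_trace(trace: ClassMassTrace, path) -> None:
    """Write a trace as tidy CSV (run, iteration, class, posterior_mass).

    The first line is a comment carrying the config and metadata as JSON, so a
    trace file is self-describing and round-trips exactly.
    """
    path = Path(path)
    run = trace.metadata.get("run", 0)
    header = _TRACE_MAGIC + json.dumps(
        {"config": _config_to_dict(trace.config), "metadata": trace.metadata}
    )
    n_iter = trace.n_iterations
    frame = pd.DataFrame(
        {
            "run": np.repeat(run, n_iter * len(CLASS_NAMES)),
            "iteration": np.repeat(np.arange(1, n_iter + 1), len(CLASS_NAMES)),
            "class": list(CLASS_NAMES) * n_iter,
            "posterior_mass": trace.masses.ravel(),
        }
    )
    with path.open("w") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_trace(path) -> ClassMassTrace:
    """Read a trace written by :func:`write_trace`; validates layout and masses."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith(_TRACE_MAGIC):
            raise TraceFormatError(f"{path}:1: missing trace metadata header")
        try:
            payload = json.loads(first[len(_TRACE_MAGIC):])
        except json.JSONDecodeError as exc:
            raise TraceFormatError(f"{path}:1: malformed metadata JSON: {exc}") from exc
        try:
            frame = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise TraceFormatError(f"{path}: malformed CSV body: {exc}") from exc
    required = {"run", "iteration", "class", "posterior_mass"}
    missing = required - set(frame.columns)
    if missing:
        raise TraceFormatError(f"{path}:2: missing columns {sorted(missing)}")
    wide = frame.pivot(index="iteration", columns="class", values="posterior_mass")
    try:
        masses = wide[list(CLASS_NAMES)].to_numpy()
    except KeyError as exc:
        raise TraceFormatError(f"{path}: missing class rows: {exc}") from exc
    sums = masses.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        warnings.warn(
            f"{path}: class masses deviate from 1 by up to {np.abs(sums - 1).max():.3g}",
            stacklevel=2,
        )
    config = _config_from_dict(payload["config"])
    return ClassMassTrace(masses=masses, config=config, metadata=payload.get("metadata", {}))


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

_CLASS_COLORS = {
    "degenerate": "tab:red",
    "holistic": "tab:blue",
    "combinatorial": "tab:green",
    "other": "tab:gray",
}


def plot_panels(
    batches: Sequence[BatchResult],
    path,
    titles: Optional[Sequence[str]] = None,
):
    """One panel per batch: mean class mass of the oldest agent vs iteration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(batches) == 0:
        raise ValueError("need at least one batch to plot")
    fig, axes = plt.subplots(
        1, len(batches), figsize=(4.2 * len(batches), 3.4), squeeze=False, sharey=True
    )
    for k, (ax, batch) in enumerate(zip(axes[0], batches)):
        iterations = np.arange(1, batch.n_iterations + 1)
        for c, name in enumerate(CLASS_NAMES):
            ax.plot(
                iterations,
                batch.mean_masses[:, c],
                label=name,
                color=_CLASS_COLORS[name],
            )
        ax.set_xlabel("iteration")
        ax.set_ylim(-0.02, 1.02)
        if titles is not None:
            ax.set_title(titles[k])
        else:
            ax.set_title(
                f"γ={batch.config.gamma:g}, {batch.config.condition}, "
                f"{batch.n_runs} runs"
            )
    axes[0][0].set_ylabel("mean posterior mass (oldest agent)")
    axes[0][-1].legend(loc="center right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return fig
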