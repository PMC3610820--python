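"""Synthetic-data generators for every input class the pipeline consumes.

Four generators emulate the study's data types:

* **Expression matrices** — hourly 48-h profiles, a configurable fraction of
  genes carrying a 24-h cosine component on a log-normal baseline:
  ``x_g(t) = b_g * (1 + a_g * cos(2*pi*(t - phi_g)/24)) + eps`` with
  Gaussian noise scaled to the baseline and strict positivity enforced by
  truncation at ``0.01 * b_g`` (the product-of-profiles complex statistic
  needs non-negative baselines to carry a 24-h component).
* **Interaction networks** — preferential-attachment (scale-free) graphs
  over the simulated genes, with a requested number of *planted dynamic
  edges* connecting rhythmic genes of similar phase.
* **Category annotations** — random gene -> category tables, genes possibly
  multi-annotated, every category nonempty.
* **Reporter traces** — damped cosine bioluminescence series sampled every
  30 min for ~6 days, with polynomial trend and Gaussian counting noise.

All generators are deterministic given their integer seed; a single global
seed can be fanned out to child seeds with :func:`child_seeds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import InteractionNetwork
from .phenotype import LuminescenceSeries

__all__ = [
    "ExpressionSimSpec",
    "NetworkSimSpec",
    "ReporterSimSpec",
    "simulate_expression",
    "simulate_network",
    "simulate_reporter",
    "simulate_annotation",
    "child_seeds",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of the synthetic circadian expression matrix.

    Defaults emulate a liver-like circadian transcriptome sampled hourly
    over 48 h: roughly a third of genes rhythmic, relative amplitudes of
    20-60% of baseline, phases uniform over the day, measurement noise a
    few percent of baseline.
    """

    n_genes: int
    frac_rhythmic: float = 0.3
    timepoints: tuple = tuple(range(48))  # hours
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    rel_amplitude_range: tuple[float, float] = (0.2, 0.6)
    noise_sd: float = 0.05  # fraction of baseline
    seed: int = 0


@dataclass(frozen=True)
class NetworkSimSpec:
    """Parameters of the synthetic scale-free interaction network."""

    n_nodes: int
    attachment_edges: int = 3
    planted_dynamic_edges: int = 0
    planted_phase_offset_max: float = 2.0  # hours
    seed: int = 0


@dataclass(frozen=True)
class ReporterSimSpec:
    """Parameters of a synthetic bioluminescence reporter trace."""

    period_h: float = 24.0
    amplitude: float = 1000.0  # counts
    damping_rate: float = 0.01  # per hour
    trend: tuple = (0.0,)  # polynomial coefficients, highest power first
    noise_sd: float = 0.0  # counts
    sampling_interval: float = 0.5  # hours
    duration: float = 144.0  # hours
    seed: int = 0


def simulate_expression(spec: ExpressionSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an expression matrix plus its ground-truth table.

    Returns
    -------
    expression : DataFrame
        ``n_genes`` x timepoints, strictly positive; columns are hours.
    truth : DataFrame
        Per gene: ``rhythmic`` flag, ``phase`` (h, NaN for flat genes),
        ``rel_amplitude``, ``baseline``.  Exactly
        ``round(n_genes * frac_rhythmic)`` genes are rhythmic.
    """
    if spec.n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not 0.0 <= spec.frac_rhythmic <= 1.0:
        raise ValueError("frac_rhythmic must lie in [0, 1]")
    t = np.asarray(spec.timepoints, dtype=float)
    if t.size < 8:
        raise ValueError("need at least 8 timepoints")

    rng = np.random.default_rng(spec.seed)
    n_r = int(round(spec.n_genes * spec.frac_rhythmic))
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    rhythmic = np.zeros(spec.n_genes, dtype=bool)
    rhythmic[rng.choice(spec.n_genes, size=n_r, replace=False)] = True

    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    lo, hi = spec.rel_amplitude_range
    amp = np.where(rhythmic, rng.uniform(lo, hi, spec.n_genes), 0.0)
    phase = np.where(rhythmic, rng.uniform(0.0, 24.0, spec.n_genes), np.nan)

    phase0 = np.nan_to_num(phase)  # flat genes have amp 0, phase value irrelevant
    clean = baseline[:, None] * (
        1.0 + amp[:, None] * np.cos(2 * np.pi * (t[None, :] - phase0[:, None]) / 24.0)
    )
    noise = rng.normal(0.0, 1.0, clean.shape) * (spec.noise_sd * baseline[:, None])
    values = np.maximum(clean + noise, 0.01 * baseline[:, None])

    expression = pd.DataFrame(values, index=genes, columns=t)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "rhythmic": rhythmic,
            "phase": phase,
            "rel_amplitude": amp,
            "baseline": baseline,
        }
    ).set_index("gene_id", drop=False)
    truth.index.name = None
    return expression, truth


def _circular_offset_h(a: float, b: float, period: float = 24.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def simulate_network(
    spec: NetworkSimSpec, truth: pd.DataFrame
) -> tuple[InteractionNetwork, list[tuple[str, str]]]:
    """Scale-free network over simulated genes with planted co-phase edges.

    The backbone is a Barabasi-Albert preferential-attachment graph (heavy
    tailed degrees, connected, simple) relabelled with gene identifiers
    drawn from ``truth``.  ``planted_dynamic_edges`` additional edges are
    placed between rhythmic genes whose circular phase offset is at most
    ``planted_phase_offset_max`` hours; these are the known-dynamic ground
    truth for recovery tests.

    Returns the network and the planted edge list (sorted pairs).
    """
    if spec.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if spec.n_nodes > len(truth):
        raise ValueError("not enough genes in truth table for requested n_nodes")
    seeds = child_seeds(spec.seed, 3)
    rng = np.random.default_rng(seeds[0])

    genes = truth["gene_id"].to_numpy()
    node_genes = rng.choice(genes, size=spec.n_nodes, replace=False)
    g = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment_edges, seed=seeds[1])
    mapping = {i: str(node_genes[i]) for i in range(spec.n_nodes)}
    g = nx.relabel_nodes(g, mapping)
    for _, _, d in g.edges(data=True):
        d["sources"] = {"EXT"}

    planted: list[tuple[str, str]] = []
    if spec.planted_dynamic_edges > 0:
        node_truth = truth.loc[[str(x) for x in node_genes]]
        rh = node_truth[node_truth["rhythmic"]]
        ids = rh["gene_id"].to_numpy()
        phases = rh["phase"].to_numpy()
        candidates = [
            (str(ids[i]), str(ids[j]))
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if _circular_offset_h(phases[i], phases[j]) <= spec.planted_phase_offset_max
            and not g.has_edge(str(ids[i]), str(ids[j]))
        ]
        if len(candidates) < spec.planted_dynamic_edges:
            raise ValueError(
                f"only {len(candidates)} rhythmic gene pairs satisfy the phase-offset "
                f"bound; cannot plant {spec.planted_dynamic_edges} edges"
            )
        chosen = rng.choice(len(candidates), size=spec.planted_dynamic_edges, replace=False)
        for k in chosen:
            a, b = candidates[int(k)]
            g.add_edge(a, b, sources={"Y2H"})
            planted.append(tuple(sorted((a, b))))

    rhythmic_set = set(truth.loc[truth["rhythmic"], "gene_id"].astype(str))
    planted_nodes = {n for e in planted for n in e}
    for n in g.nodes:
        if n in planted_nodes:
            g.nodes[n]["node_class"] = "core"
        elif n in rhythmic_set:
            g.nodes[n]["node_class"] = "regulatory"
        else:
            g.nodes[n]["node_class"] = "neighborhood"

    net = InteractionNetwork(g)
    return net, sorted(planted)


def simulate_reporter(spec: ReporterSimSpec, well_id: str = "well") -> LuminescenceSeries:
    """Simulate a bioluminescence trace.

    ``y(t) = amplitude * exp(-damping_rate * t) * cos(2*pi*t/period_h)
    + trend(t) + noise``; the trace has ``duration/sampling_interval + 1``
    samples.  With zero noise and zero trend the series is an exact damped
    cosine.
    """
    if spec.period_h <= 0:
        raise ValueError("period must be positive")
    if spec.sampling_interval <= 0:
        raise ValueError("sampling interval must be positive")
    if spec.duration < 2 * spec.period_h:
        raise ValueError("duration must cover at least two periods")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / spec.sampling_interval)) + 1
    t = np.arange(n) * spec.sampling_interval
    y = spec.amplitude * np.exp(-spec.damping_rate * t) * np.cos(2 * np.pi * t / spec.period_h)
    y = y + np.polyval(spec.trend, t)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, n)
    return LuminescenceSeries(id=well_id, t=t, y=y)


def simulate_annotation(
    genes,
    n_categories: int,
    genes_per_category: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene -> category annotation table.

    Every category receives ``min(genes_per_category, n_genes)`` distinct
    genes sampled uniformly; a gene may be annotated to several categories.
    Returns columns ``gene, category_id, category_name``.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    if genes_per_category < 1:
        raise ValueError("genes_per_category must be >= 1")
    genes = np.asarray(list(genes), dtype=object)
    rng = np.random.default_rng(seed)
    rows = []
    k = min(genes_per_category, len(genes))
    for c in range(n_categories):
        cat = f"C{c:03d}"
        for gname in rng.choice(genes, size=k, replace=False):
            rows.append({"gene": str(gname), "category_id": cat, "category_name": f"process_{c}"})
    return pd.DataFrame(rows)
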