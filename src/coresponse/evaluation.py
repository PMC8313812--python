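"""Validation utilities: null calibration, planted-module recovery, and
summary arithmetic on externally reported network counts.

These functions exist so that the statistical guarantees quoted in the
documentation are produced by code anyone can re-run, not by one-off
scripts: type-I error of the edge test on truly independent profile pairs,
end-to-end recovery of planted co-response modules through the full
pipeline, and the kingdom-partitioned ratio arithmetic applied to published
node/edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .metrics import NetworkSummary, summarize_graph
from .network import MEASURES, NetworkConfig, build_network, reboot_test
from .ratios import compute_ratios
from .synthetic import ModuleSpec, generate_paired_design
from .tables import TaxonomyMap, filter_prevalence, to_relative

__all__ = [
    "type_one_error_rates",
    "RecoveryReport",
    "module_recovery",
    "counts_graph",
    "summarize_counts",
]


def type_one_error_rates(
    n_pairs: int = 500,
    n_cols: int = 9,
    n_perm: int = 200,
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    measures: tuple[str, ...] = MEASURES,
) -> dict[str, float]:
    """Rejection rate of ``reboot_test`` at ``alpha`` on independent pairs.

    Profile pairs are drawn i.i.d. uniform on (0.1, 10), so any rejection is
    a false positive; a calibrated test rejects a fraction ~ ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = dict.fromkeys(measures, 0)
    for i in range(n_pairs):
        x = rng.uniform(0.1, 10.0, n_cols)
        y = rng.uniform(0.1, 10.0, n_cols)
        for m in measures:
            res = reboot_test(x, y, m, n_perm=n_perm, n_boot=n_boot,
                              seed=seed + 7919 * (i + 1))
            rejections[m] += res.p < alpha
    return {m: rejections[m] / n_pairs for m in measures}


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of repeated planted-module recovery runs."""

    n_runs: int
    n_recovered: int          # runs where every module was recovered
    edges_detected: int       # planted edges found, pooled over runs
    edges_correct_sign: int
    edges_planted: int

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_runs

    @property
    def sign_accuracy(self) -> float:
        return (self.edges_correct_sign / self.edges_detected
                if self.edges_detected else float("nan"))


def module_recovery(
    n_runs: int = 20,
    seed: int = 0,
    n_bacteria: int = 120,
    n_fungi: int = 30,
    modules: tuple = ((6, 1, 0.95), (6, -1, 0.95)),
    zero_rate: float = 0.3,
    n_perm: int = 200,
    n_boot: int = 200,
) -> RecoveryReport:
    """Run the full pipeline on planted communities and score recovery.

    A planted module counts as recovered when the correctly-signed detected
    planted edges span at least half of its members and no planted edge
    appears with the wrong sign; a run succeeds when every module is
    recovered.
    """
    module_spec = [ModuleSpec(*m) for m in modules]
    n_recovered = det = correct = planted_total = 0
    for run in range(n_runs):
        run_seed = seed + run
        table, taxonomy, design, truth = generate_paired_design(
            n_bacteria=n_bacteria, n_fungi=n_fungi, module_spec=module_spec,
            zero_rate=zero_rate, seed=run_seed)
        filtered = filter_prevalence(to_relative(table), design,
                                     "compartment", 4)["BS"]
        ratios = compute_ratios(filtered, design, "BS")
        net = build_network(ratios, taxonomy,
                            NetworkConfig(seed=run_seed, n_perm=n_perm,
                                          n_boot=n_boot))
        covered: dict[int, set[str]] = {}
        wrong = 0
        planted_total += len(truth.planted_edges)
        for a, b, sign in truth.planted_edges:
            edge = net.graph.get_edge_data(a, b)
            if edge is None:
                continue
            det += 1
            if (edge["sign"] == "positive") == (sign > 0):
                correct += 1
                covered.setdefault(truth.modules[a], set()).update((a, b))
            else:
                wrong += 1
        sizes = {i: len(truth.module_members(i)) for i in range(len(module_spec))}
        ok = wrong == 0 and all(
            len(covered.get(i, ())) >= sizes[i] / 2 for i in sizes)
        n_recovered += ok
    return RecoveryReport(n_runs=n_runs, n_recovered=n_recovered,
                          edges_detected=det, edges_correct_sign=correct,
                          edges_planted=planted_total)


def counts_graph(
    n_bacterial_nodes: int,
    n_fungal_nodes: int,
    bb: tuple[int, int],
    ff: tuple[int, int],
    bf: tuple[int, int],
) -> tuple[nx.Graph, TaxonomyMap]:
    """Deterministic signed graph realizing given kingdom-partitioned
    positive/negative edge counts (bb/ff/bf = (positive, negative))."""
    bact = [f"b{i}" for i in range(n_bacterial_nodes)]
    fungi = [f"f{i}" for i in range(n_fungal_nodes)]
    graph = nx.Graph()
    graph.add_nodes_from(bact + fungi)

    def _wire(pairs, n_pos, n_neg):
        it = iter(pairs)
        for _ in range(n_pos):
            a, b = next(it)
            graph.add_edge(a, b, sign="positive")
        for _ in range(n_neg):
            a, b = next(it)
            graph.add_edge(a, b, sign="negative")

    _wire(combinations(bact, 2), *bb)
    _wire(combinations(fungi, 2), *ff)
    _wire(((a, b) for a in bact for b in fungi), *bf)
    taxonomy = TaxonomyMap.from_strings(
        {o: "k__Bacteria;p__P" for o in bact} |
        {o: "k__Fungi;p__Q" for o in fungi})
    return graph, taxonomy


def summarize_counts(n_bacterial_nodes, n_fungal_nodes, bb, ff, bf) -> NetworkSummary:
    """Summary-table arithmetic (totals and +/- ratios) for given counts."""
    graph, taxonomy = counts_graph(n_bacterial_nodes, n_fungal_nodes, bb, ff, bf)
    return summarize_graph(graph, taxonomy)
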