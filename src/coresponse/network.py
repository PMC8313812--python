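"""Ensemble co-response network inference from DI/FI ratio profiles.

Edges between OTUs are scored with four similarity measures (Pearson and
Spearman correlation, Bray–Curtis dissimilarity, symmetrized
Kullback–Leibler divergence).  Per measure, edge significance is assessed
ReBoot-style against a permutation null of one profile relative to the
other, optionally complemented by a bootstrap distribution of the observed
score; the per-measure p-values of the measures that agree on a direction
(associated vs anti-associated) are combined by Brown's method (Fisher's
statistic corrected for the dependence among measures, estimated from the
permutation scores) and the merged p-values are Benjamini–Hochberg
controlled across all tested pairs.  Surviving edges carry a sign: positive
when the majority direction is "associated" (similar ratio patterns, a
shared response to water deficit), negative when it is "anti-associated".

The whole pipeline is deterministic given its seed: each unordered OTU pair
gets an independent random stream keyed on (seed, pair indices).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ratios import RatioMatrix
from .tables import TaxonomyMap

MEASURES = ("pearson", "spearman", "bray_curtis", "kld")
CORRELATION_MEASURES = frozenset({"pearson", "spearman"})

__all__ = [
    "MEASURES",
    "MeasurePanel",
    "RebootResult",
    "MergedEdge",
    "EdgeRecord",
    "CoResponseNetwork",
    "NetworkConfig",
    "score_pairs",
    "pair_score",
    "reboot_test",
    "merge_measures",
    "build_network",
]


# ---------------------------------------------------------------------------
# Similarity measures


def _rankdata_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of paired rows; NaN where degenerate."""
    Xc = X - X.mean(axis=-1, keepdims=True)
    Yc = Y - Y.mean(axis=-1, keepdims=True)
    num = (Xc * Yc).sum(axis=-1)
    den = np.sqrt((Xc**2).sum(axis=-1) * (Yc**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(out, -1.0, 1.0)  # NaN propagates through clip


def _bray_curtis_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return np.abs(X - Y).sum(axis=-1) / (X + Y).sum(axis=-1)


def _kld_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Symmetrized KL divergence of rows normalized to probability vectors."""
    P = X / X.sum(axis=-1, keepdims=True)
    Q = Y / Y.sum(axis=-1, keepdims=True)
    return 0.5 * ((P - Q) * (np.log(P) - np.log(Q))).sum(axis=-1)


def pair_score(x: np.ndarray, y: np.ndarray, measure: str) -> float:
    """Observed score of one pair of strictly positive ratio vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if measure == "pearson":
        return float(_pearson_rows(x[None, :], y[None, :])[0])
    if measure == "spearman":
        return float(_pearson_rows(_rankdata_rows(x[None, :]), _rankdata_rows(y[None, :]))[0])
    if measure == "bray_curtis":
        if (x < 0).any() or (y < 0).any():
            raise ValueError("Bray–Curtis requires non-negative vectors")
        return float(_bray_curtis_rows(x[None, :], y[None, :])[0])
    if measure == "kld":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("KL divergence requires strictly positive vectors")
        return float(_kld_rows(x[None, :], y[None, :])[0])
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


@dataclass(frozen=True)
class MeasurePanel:
    """All pairwise observed scores of one measure over a ratio matrix.

    ``scores`` is a condensed upper-triangle vector in
    ``itertools.combinations`` order over ``otu_ids``; undefined scores
    (zero-variance profiles under a correlation) are NaN.
    """

    measure: str
    otu_ids: tuple[str, ...]
    scores: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        pairs = list(combinations(self.otu_ids, 2))
        return pd.DataFrame(
            {"otu_a": [a for a, _ in pairs], "otu_b": [b for _, b in pairs],
             "score": self.scores}
        )

    def score(self, otu_a: str, otu_b: str) -> float:
        i, j = self.otu_ids.index(otu_a), self.otu_ids.index(otu_b)
        if i == j:
            raise ValueError("a pair needs two distinct OTUs")
        if i > j:
            i, j = j, i
        n = len(self.otu_ids)
        # condensed index of (i, j), i < j
        k = n * i - (i * (i + 1)) // 2 + (j - i - 1)
        return float(self.scores[k])


def score_pairs(ratios: RatioMatrix, measure: str) -> MeasurePanel:
    """Observed pairwise scores of one measure for every OTU pair."""
    V = ratios.values()
    if V.shape[1] < 3:
        raise ValueError("need at least three ratio columns")
    n = V.shape[0]
    if measure in ("pearson", "spearman"):
        M = _rankdata_rows(V) if measure == "spearman" else V
        sd = M.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(M)
        C = np.clip(C, -1.0, 1.0)
        C[sd == 0, :] = np.nan
        C[:, sd == 0] = np.nan
        scores = C[np.triu_indices(n, k=1)]
    elif measure == "bray_curtis":
        from scipy.spatial.distance import pdist

        scores = pdist(V, metric="braycurtis")
    elif measure == "kld":
        P = V / V.sum(axis=1, keepdims=True)
        L = np.log(P)
        # symmetrized KL via 0.5 * sum (p_i - q_i)(log p_i - log q_i)
        G = P @ L.T
        H = (P * L).sum(axis=1)
        D = 0.5 * (H[:, None] + H[None, :] - G - G.T)
        scores = D[np.triu_indices(n, k=1)]
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return MeasurePanel(measure, tuple(ratios.otu_ids), np.asarray(scores, dtype=float))


# ---------------------------------------------------------------------------
# ReBoot edge significance


@dataclass(frozen=True)
class RebootResult:
    measure: str
    observed: float
    p: float
    direction: str | None            # "associated" / "anti-associated" / None
    perm_scores: np.ndarray | None = None
    boot_scores: np.ndarray | None = None


def _measure_rows(x: np.ndarray, Y: np.ndarray, measure: str,
                  ranks: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Scores of x against every row of Y (all strictly positive)."""
    X = np.broadcast_to(x, Y.shape)
    if measure == "pearson":
        return _pearson_rows(X, Y)
    if measure == "spearman":
        rx = ranks[0] if ranks is not None else _rankdata_rows(x[None, :])[0]
        RY = ranks[1] if ranks is not None else _rankdata_rows(Y)
        return _pearson_rows(np.broadcast_to(rx, RY.shape), RY)
    if measure == "bray_curtis":
        return _bray_curtis_rows(X, Y)
    if measure == "kld":
        return _kld_rows(X, Y)
    raise ValueError(f"unknown measure {measure!r}")


def _null_and_boot(
    x: np.ndarray,
    y: np.ndarray,
    measures: Sequence[str],
    n_perm: int,
    n_boot: int,
    rng: np.random.Generator,
    renormalize: bool = False,
    need_boot: bool = True,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Permutation-null and bootstrap score distributions, shared index sets
    across measures so that cross-measure score correlations are estimable."""
    n = x.size
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y[perm_idx]
    perm: dict[str, np.ndarray] = {}
    if renormalize:
        # restore per-column totals of the 2-row submatrix after each shuffle
        tot = x + y
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = tot / (x[None, :] + Yp)
        Xp = x[None, :] * scale
        Ypr = Yp * scale
        for m in measures:
            out = np.empty(n_perm)
            for k in range(n_perm):
                out[k] = pair_score(Xp[k], Ypr[k], m)
            perm[m] = out
    else:
        ry = _rankdata_rows(y[None, :])[0]
        ranks = (_rankdata_rows(x[None, :])[0], ry[perm_idx])
        for m in measures:
            perm[m] = _measure_rows(x, Yp, m, ranks=ranks)
    boot: dict[str, np.ndarray] = {}
    if need_boot and n_boot > 0:
        boot_idx = rng.integers(0, n, size=(n_boot, n))
        Xb = x[boot_idx]
        Yb = y[boot_idx]
        row_fns = {"pearson": _pearson_rows, "bray_curtis": _bray_curtis_rows,
                   "kld": _kld_rows}
        for m in measures:
            if m == "spearman":
                boot[m] = _pearson_rows(_rankdata_rows(Xb), _rankdata_rows(Yb))
            else:
                boot[m] = row_fns[m](Xb, Yb)
    return perm, boot


def _stabilize(measure: str, scores: np.ndarray | float) -> np.ndarray | float:
    """Map scores onto an unbounded scale where the permutation null is
    closer to normal: Fisher's z for correlations, log for dissimilarities."""
    s = np.asarray(scores, dtype=float)
    if measure in CORRELATION_MEASURES:
        out = np.arctanh(np.clip(s, -1.0 + 1e-15, 1.0 - 1e-15))
    else:
        out = np.log(np.clip(s, 1e-12, None))
    return out if out.ndim else float(out)


def _p_and_direction(
    observed: float,
    perm: np.ndarray,
    boot: np.ndarray | None,
    measure: str,
    p_method: str,
    n_cols: int = 9,
) -> tuple[float, str | None]:
    perm = perm[np.isfinite(perm)]
    if not np.isfinite(observed) or perm.size == 0:
        return 1.0, None
    med = float(np.median(perm))
    if measure in CORRELATION_MEASURES:
        associated = observed > med
    else:
        associated = observed < med
    direction = "associated" if associated else "anti-associated"
    if p_method == "perm_z":
        # Empirical two-sided tail probability while the observed score lies
        # inside the sampled null; a z-score on the variance-stabilized scale
        # extrapolates beyond it, floored at the exact enumeration limit of
        # the permutation space (1/n_cols!).
        n_beyond = int(np.sum(np.abs(perm - med) >= abs(observed - med)))
        p_tail = (n_beyond + 1.0) / (perm.size + 1.0)
        if n_beyond > 0:
            return float(min(p_tail, 1.0)), direction
        t_perm = np.asarray(_stabilize(measure, perm))
        t_perm = t_perm[np.isfinite(t_perm)]
        sd = t_perm.std()
        if t_perm.size == 0 or sd == 0:
            return float(p_tail), direction
        z = (float(_stabilize(measure, observed)) - t_perm.mean()) / sd
        p_z = 2.0 * stats.norm.sf(abs(z))
        floor = max(1.0 / float(math.factorial(min(n_cols, 170))), 1e-300)
        p = min(p_tail, max(p_z, floor))
    elif p_method == "pooled_z":
        if boot is None or boot[np.isfinite(boot)].size == 0:
            raise ValueError("pooled_z requires bootstrap scores")
        b = boot[np.isfinite(boot)]
        denom = np.sqrt(b.var() + perm.var())
        if denom == 0:
            return (1.0, direction) if b.mean() == perm.mean() else (0.0, direction)
        z = (b.mean() - perm.mean()) / denom
        p = 2.0 * stats.norm.sf(abs(z))
    elif p_method == "perm_tail":
        # two-sided tail count with add-one correction
        dev = np.abs(perm - med)
        p = (np.sum(dev >= abs(observed - med)) + 1.0) / (perm.size + 1.0)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return float(min(p, 1.0)), direction


def reboot_test(
    x: Sequence[float],
    y: Sequence[float],
    measure: str,
    n_perm: int = 1000,
    n_boot: int = 1000,
    renormalize: bool = False,
    seed: int = 0,
    p_method: str = "perm_z",
    keep_scores: bool = False,
) -> RebootResult:
    """Permutation/bootstrap significance of one OTU pair under one measure.

    The permutation null shuffles one profile relative to the other
    (optionally renormalizing column totals, for compositional inputs); the
    bootstrap jointly resamples ratio columns with replacement.  ``p_method``
    selects how the two distributions become a p-value:

    - ``"perm_z"`` (default): z-score of the observed score against the
      permutation null, two-sided normal tail — approximately calibrated.
    - ``"pooled_z"``: z of (bootstrap mean − permutation mean) over the
      pooled standard deviation, a deliberately stricter variant that also
      penalizes unstable scores.
    - ``"perm_tail"``: plain two-sided permutation tail probability.

    Degenerate (constant) profiles give p = 1 with no direction.  The result
    is symmetric in x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors with at least 3 entries")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be unstable", stacklevel=2)
    # canonical argument order makes the test exactly symmetric in (x, y)
    if tuple(y) < tuple(x):
        x, y = y, x
    observed = pair_score(x, y, measure)
    if x.std() == 0 or y.std() == 0:
        return RebootResult(measure, observed, 1.0, None)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    need_boot = p_method == "pooled_z" or keep_scores
    perm, boot = _null_and_boot(x, y, [measure], n_perm, n_boot, rng,
                                renormalize=renormalize, need_boot=need_boot)
    p, direction = _p_and_direction(observed, perm[measure], boot.get(measure),
                                    measure, p_method, n_cols=x.size)
    return RebootResult(
        measure, observed, p, direction,
        perm_scores=perm[measure] if keep_scores else None,
        boot_scores=boot.get(measure) if keep_scores else None,
    )


# ---------------------------------------------------------------------------
# Measure merging (Brown / Fisher)

_BROWN_C = (3.263, 0.710, 0.027)  # Kost–McDermott polynomial for cov(-2 ln p)


@dataclass(frozen=True)
class MergedEdge:
    p: float
    sign: int                 # +1 positive co-response, -1 negative
    support: int              # measures agreeing with the majority direction
    measures: tuple[str, ...]  # the agreeing measures


def merge_measures(
    results: Sequence[RebootResult],
    method: str = "brown",
    min_support: int = 2,
    score_correlations: np.ndarray | None = None,
) -> MergedEdge | None:
    """Combine per-measure evidence for one pair into a single signed edge.

    Measures with an undefined direction are dropped; the majority direction
    wins, a tie rejects the edge, and fewer than ``min_support`` agreeing
    measures reject it too.  The agreeing measures' p-values are combined by
    Fisher's method or Brown's dependence-corrected variant, where the
    covariance of the -2 ln p terms is estimated from the absolute
    correlation of the measures' permutation scores
    (``score_correlations``, aligned with ``results``).
    """
    if method not in ("brown", "fisher"):
        raise ValueError("method must be 'brown' or 'fisher'")
    valid = [(i, r) for i, r in enumerate(results) if r.direction is not None]
    if not valid:
        return None
    n_assoc = sum(1 for _, r in valid if r.direction == "associated")
    n_anti = len(valid) - n_assoc
    if n_assoc == n_anti:
        return None
    majority = "associated" if n_assoc > n_anti else "anti-associated"
    agreeing = [(i, r) for i, r in valid if r.direction == majority]
    if len(agreeing) < min_support:
        return None
    ps = np.clip([r.p for _, r in agreeing], 1e-300, 1.0)
    k = len(ps)
    X = -2.0 * np.log(ps).sum()
    if method == "fisher" or k == 1:
        p = float(stats.chi2.sf(X, 2 * k))
    else:
        mean = 2.0 * k
        var = 4.0 * k
        if score_correlations is not None:
            idx = [i for i, _ in agreeing]
            for a in range(k):
                for b in range(a + 1, k):
                    rho = abs(float(score_correlations[idx[a], idx[b]]))
                    if np.isfinite(rho):
                        var += 2.0 * (_BROWN_C[0] * rho + _BROWN_C[1] * rho**2
                                      + _BROWN_C[2] * rho**3)
        c = var / (2.0 * mean)
        f = 2.0 * mean**2 / var
        p = float(stats.chi2.sf(X / c, f))
    sign = 1 if majority == "associated" else -1
    return MergedEdge(p=min(p, 1.0), sign=sign, support=len(agreeing),
                      measures=tuple(r.measure for _, r in agreeing))


# ---------------------------------------------------------------------------
# Network assembly


@dataclass
class EdgeRecord:
    otu_a: str
    otu_b: str
    scores: dict[str, float]
    pvalues: dict[str, float]
    directions: dict[str, str | None]
    merged_p: float
    sign: int
    support: int
    q: float = float("nan")


@dataclass
class NetworkConfig:
    """Settings of the edge-inference stage; ``seed`` is mandatory."""

    seed: int
    measures: tuple[str, ...] = MEASURES
    n_perm: int = 1000
    n_boot: int = 1000
    p_method: str = "perm_z"
    merge_method: str = "brown"
    min_support: int = 2
    alpha_edge: float = 0.05
    prefilter_quantile: float | None = None  # e.g. 0.02 keeps each measure's 2% tails
    renormalize: bool = False

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed), "measures": list(self.measures),
            "n_perm": int(self.n_perm), "n_boot": int(self.n_boot),
            "p_method": self.p_method, "merge_method": self.merge_method,
            "min_support": int(self.min_support), "alpha_edge": float(self.alpha_edge),
            "prefilter_quantile": self.prefilter_quantile,
            "renormalize": bool(self.renormalize),
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class CoResponseNetwork:
    """Signed co-response network: the graph plus full edge evidence."""

    graph: nx.Graph
    edges: list[EdgeRecord]
    n_pairs_tested: int
    config: NetworkConfig
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for e in self.edges:
            row = {"otu_a": e.otu_a, "otu_b": e.otu_b,
                   "sign": "positive" if e.sign > 0 else "negative",
                   "merged_p": e.merged_p, "q": e.q, "support": e.support}
            for m in self.config.measures:
                row[f"score_{m}"] = e.scores.get(m, float("nan"))
                row[f"p_{m}"] = e.pvalues.get(m, float("nan"))
            rows.append(row)
        cols = (["otu_a", "otu_b", "sign", "merged_p", "q", "support"]
                + [f"score_{m}" for m in self.config.measures]
                + [f"p_{m}" for m in self.config.measures])
        return pd.DataFrame(rows, columns=cols)

    def write_edge_list(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _pair_rng(seed: int, i: int, j: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, i, j]))


def build_network(
    ratios: RatioMatrix,
    taxonomy: TaxonomyMap | None,
    config: NetworkConfig,
) -> CoResponseNetwork:
    """Infer the signed co-response network for one compartment.

    Scores every OTU pair under every configured measure (optionally only
    the pairs in each measure's extreme score quantiles), runs the ReBoot
    permutation test per pair and measure with a pair-specific random
    stream, merges the per-measure evidence, applies Benjamini–Hochberg
    control at ``alpha_edge`` across all merged pairs, and assembles the
    graph from the surviving edges.  Isolated OTUs do not appear: nodes
    exist only through significant edges.
    """
    otu_ids = ratios.otu_ids
    if len(otu_ids) < 2:
        raise ValueError("need at least two OTUs to build a network")
    V = ratios.values()
    n = len(otu_ids)
    measures = tuple(config.measures)

    panels = {m: score_pairs(ratios, m) for m in measures}
    all_pairs = list(combinations(range(n), 2))
    if config.prefilter_quantile:
        q = float(config.prefilter_quantile)
        keep = np.zeros(len(all_pairs), dtype=bool)
        for m in measures:
            s = panels[m].scores
            finite = s[np.isfinite(s)]
            if finite.size == 0:
                continue
            lo, hi = np.quantile(finite, [q, 1.0 - q])
            with np.errstate(invalid="ignore"):
                keep |= np.isfinite(s) & ((s <= lo) | (s >= hi))
        pairs = [p for p, k in zip(all_pairs, keep) if k]
    else:
        pairs = all_pairs

    need_boot = config.p_method == "pooled_z"
    candidates: list[EdgeRecord] = []
    for i, j in pairs:
        x, y = V[i], V[j]
        if x.std() == 0 or y.std() == 0:
            continue
        if tuple(y) < tuple(x):
            xx, yy = y, x
        else:
            xx, yy = x, y
        rng = _pair_rng(config.seed, i, j)
        perm, boot = _null_and_boot(xx, yy, measures, config.n_perm, config.n_boot,
                                    rng, renormalize=config.renormalize,
                                    need_boot=need_boot)
        results = []
        for m in measures:
            obs = pair_score(xx, yy, m)
            p, direction = _p_and_direction(obs, perm[m], boot.get(m), m,
                                            config.p_method, n_cols=V.shape[1])
            results.append(RebootResult(m, obs, p, direction))
        if config.merge_method == "brown" and len(measures) > 1:
            P = np.vstack([perm[m] for m in measures])
            with np.errstate(invalid="ignore", divide="ignore"):
                R = np.corrcoef(P)
        else:
            R = None
        merged = merge_measures(results, method=config.merge_method,
                                min_support=config.min_support,
                                score_correlations=R)
        if merged is None:
            continue
        candidates.append(EdgeRecord(
            otu_a=otu_ids[i], otu_b=otu_ids[j],
            scores={r.measure: r.observed for r in results},
            pvalues={r.measure: r.p for r in results},
            directions={r.measure: r.direction for r in results},
            merged_p=merged.p, sign=merged.sign, support=merged.support,
        ))

    if candidates:
        reject, qvals, *_ = multipletests([e.merged_p for e in candidates],
                                          alpha=config.alpha_edge, method="fdr_bh")
        for e, qv in zip(candidates, qvals):
            e.q = float(qv)
        passing = [e for e, r in zip(candidates, reject) if r]
    else:
        passing = []

    graph = nx.Graph()
    for e in passing:
        attrs = {}
        for node in (e.otu_a, e.otu_b):
            if node not in graph:
                if taxonomy is not None:
                    lin = taxonomy[node]
                    graph.add_node(node, kingdom=lin.kingdom, phylum=lin.phylum)
                else:
                    graph.add_node(node)
        graph.add_edge(e.otu_a, e.otu_b,
                       sign="positive" if e.sign > 0 else "negative",
                       weight=e.sign, merged_p=e.merged_p, q=e.q, support=e.support)
    return CoResponseNetwork(
        graph=graph, edges=passing, n_pairs_tested=len(pairs), config=config,
        provenance={
            "compartment": ratios.compartment,
            "zero_replacement": ratios.zero_replacement,
            "n_otus": n, "n_pairs_tested": len(pairs),
            "config_hash": config.hash(),
        },
    )
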