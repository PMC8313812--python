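"""Alpha/beta diversity stage: rarefaction, Shannon, group comparison,
Bray–Curtis ordination (PCoA), UPGMA clustering and per-taxon differential
abundance between irrigation treatments.

Rarefaction follows the survey convention of subsampling without
replacement on a depth grid (e.g. increments of 3,900 reads up to a
standardized 39,000 for 16S libraries; 1,400 up to 14,000 for ITS) with a
fixed number of iterations per depth; the final-depth iterations, pooled
across replicates, feed the Kruskal–Wallis / Dunn comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

from .tables import OtuTable, SampleDesign, TaxonomyMap, DegenerateInputError, RANKS

__all__ = [
    "RarefactionResult", "DistanceMatrix", "AlphaComparison", "Ordination",
    "rarefy", "rarefaction_series", "shannon", "compare_alpha",
    "bray_curtis", "aggregate_to_rank", "pcoa", "upgma", "differential_taxa",
]


# ---------------------------------------------------------------------------
# Alpha diversity


def shannon(vector, base: float = 2.0) -> float:
    """Shannon index H = -sum p_i log_base(p_i) over the positive entries."""
    v = np.asarray(vector, dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    total = v.sum()
    if total == 0:
        raise DegenerateInputError("Shannon index of an all-zero vector is undefined")
    p = v[v > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def rarefy(counts, depth: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Subsample `depth` reads without replacement from a count vector.

    The marginal count of each OTU is hypergeometric with mean
    depth * count / total.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("rarefy needs integer counts")
        counts = np.round(counts).astype(np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


@dataclass(frozen=True)
class RarefactionResult:
    """Long-format rarefaction records and the standardized depth used."""

    records: pd.DataFrame  # columns: sample, depth, iteration, richness, shannon
    max_depth: int
    increment: int
    iterations: int

    def final_depth_values(self, metric: str) -> pd.DataFrame:
        """Per-sample iteration values at the standardized depth."""
        sel = self.records[self.records["depth"] == self.max_depth]
        return sel[["sample", "iteration", metric]]

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def rarefaction_series(
    table: OtuTable,
    increment: int,
    iterations: int = 10,
    max_depth: int | None = None,
    seed: int = 0,
    shannon_base: float = 2.0,
) -> RarefactionResult:
    """Rarefaction curves on the grid increment, 2*increment, ..., max_depth.

    Samples whose total is below ``max_depth`` are excluded with a warning.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    totals = table.values().sum(axis=0)
    if max_depth is None:
        max_depth = (int(totals.min()) // increment) * increment
        if max_depth <= 0:
            raise ValueError("shallowest sample is below one increment")
    depths = list(range(increment, max_depth + 1, increment))
    if depths[-1] != max_depth:
        raise ValueError("max_depth must be a multiple of increment")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, total in zip(table.sample_ids, totals):
        if total < max_depth:
            warnings.warn(
                f"sample {sample} (total {int(total)}) below standardized depth "
                f"{max_depth}; excluded", stacklevel=2)
            continue
        counts = np.round(table.data[sample].to_numpy()).astype(np.int64)
        for depth in depths:
            for it in range(iterations):
                sub = rarefy(counts, depth, rng)
                rows.append((sample, depth, it,
                             int((sub > 0).sum()), shannon(sub, base=shannon_base)))
    records = pd.DataFrame(rows, columns=["sample", "depth", "iteration",
                                          "richness", "shannon"])
    return RarefactionResult(records, max_depth=max_depth, increment=increment,
                             iterations=iterations)


# ---------------------------------------------------------------------------
# Group comparison (Kruskal–Wallis + Dunn)


@dataclass(frozen=True)
class AlphaComparison:
    metric: str
    kruskal_h: float
    kruskal_p: float
    dunn: pd.DataFrame          # group_a, group_b, z, p, p_bh
    letters: dict[str, str]     # compact letter display at alpha
    group_values: dict[str, np.ndarray]


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[start:start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((a, b, z, p))
    frame = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    if len(frame):
        frame["p_bh"] = multipletests(frame["p"], method="fdr_bh")[1]
    else:
        frame["p_bh"] = []
    return frame


def _letter_display(labels: list[str], means: dict[str, float],
                    dunn: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Compact letters: groups share a letter iff not significantly different."""
    same = nx.Graph()
    same.add_nodes_from(labels)
    for _, row in dunn.iterrows():
        if row["p"] >= alpha:
            same.add_edge(row["group_a"], row["group_b"])
    cliques = [tuple(sorted(c, key=lambda g: -means[g])) for c in nx.find_cliques(same)]
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in labels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return letters


def compare_alpha(
    result: RarefactionResult,
    design: SampleDesign,
    metric: str = "shannon",
    alpha: float = 0.05,
) -> AlphaComparison:
    """Kruskal–Wallis across compartment x treatment groups with Dunn post hoc.

    Each group pools its replicates' final-depth iteration values (three
    replicates x ten iterations = thirty observations under the study
    layout).  Letters derive from the unadjusted Dunn p-values at ``alpha``;
    BH-adjusted p-values are reported alongside.
    """
    values = result.final_depth_values(metric)
    groups: dict[str, list[float]] = {}
    for _, row in values.iterrows():
        label = design.group_label(row["sample"])
        groups.setdefault(label, []).append(float(row[metric]))
    groups_arr = {g: np.asarray(v) for g, v in sorted(groups.items())}
    small = [g for g, v in groups_arr.items() if len(v) < 2]
    if small or len(groups_arr) < 2:
        raise ValueError(f"need >=2 groups with >=2 observations each (bad: {small})")
    samples = list(groups_arr.values())
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):  # no variation at all: no evidence
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    dunn = _dunn_posthoc(groups_arr)
    means = {g: float(np.mean(v)) for g, v in groups_arr.items()}
    letters = _letter_display(list(groups_arr), means, dunn, alpha)
    return AlphaComparison(metric=metric, kruskal_h=float(h), kruskal_p=float(p),
                           dunn=dunn, letters=letters, group_values=groups_arr)


# ---------------------------------------------------------------------------
# Beta diversity


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.sample_ids),) * 2:
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(m) != 0).any():
            raise ValueError("distance matrix diagonal must be exactly 0")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity d(a,b) = sum|a_i-b_i| / sum(a_i+b_i)
    between samples (columns)."""
    V = table.values().T  # samples x OTUs
    if V.shape[0] < 2:
        raise ValueError("need at least two samples")
    zero = V.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise DegenerateInputError(f"Bray–Curtis undefined between all-zero samples {bad}")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(V, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(table.sample_ids), d)


def aggregate_to_rank(table: OtuTable, taxonomy: TaxonomyMap, rank: str) -> OtuTable:
    """Sum OTU rows sharing the same lineage prefix up to ``rank``."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    keys = [";".join(taxonomy[o].prefix(rank)) for o in table.otu_ids]
    grouped = table.data.groupby(pd.Index(keys, name="taxon"), sort=True).sum()
    return OtuTable(grouped, table.value_kind)


@dataclass(frozen=True)
class Ordination:
    coordinates: pd.DataFrame   # samples x retained axes
    eigenvalues: np.ndarray     # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix) -> Ordination:
    """Classical (Gower-centered) principal coordinates analysis.

    Axes belonging to negative eigenvalues are dropped from the coordinates
    but the eigenvalues themselves are reported.
    """
    dm = _SkbioDM(dist.matrix, ids=list(dist.sample_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    keep = eig > 1e-12
    coords = res.samples.iloc[:, np.nonzero(keep)[0]]
    prop = res.proportion_explained.to_numpy()[keep]
    return Ordination(coordinates=coords, eigenvalues=eig, proportion_explained=prop)


def upgma(dist: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) agglomeration; returns a Newick string.

    Branch lengths are ultrametric (merge height = distance / 2).  Ties in
    the minimum inter-cluster distance are broken by the lexicographically
    smallest pair of cluster leaf-name tuples, so the output is
    deterministic.
    """
    n = len(dist.sample_ids)
    if n < 2:
        raise ValueError("need at least two samples")
    clusters: dict[int, dict] = {
        i: {"leaves": (str(dist.sample_ids[i]),), "size": 1, "height": 0.0,
            "newick": str(dist.sample_ids[i])}
        for i in range(n)
    }
    d = {frozenset((i, j)): float(dist.matrix[i, j])
         for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best = None
        for key, val in d.items():
            i, j = sorted(key)
            pair_rank = tuple(sorted((clusters[i]["leaves"], clusters[j]["leaves"])))
            cand = (val, pair_rank, i, j)
            if best is None or cand < best:
                best = cand
        dist_ij, _, i, j = best
        height = dist_ij / 2.0
        ci, cj = clusters.pop(i), clusters.pop(j)
        bl_i = height - ci["height"]
        bl_j = height - cj["height"]
        merged = {
            "leaves": tuple(sorted(ci["leaves"] + cj["leaves"])),
            "size": ci["size"] + cj["size"],
            "height": height,
            "newick": f"({ci['newick']}:{bl_i:.17g},{cj['newick']}:{bl_j:.17g})",
        }
        # average-linkage update
        new_d = {}
        for key, val in d.items():
            if i in key or j in key:
                continue
            new_d[key] = val
        for k in clusters:
            dik = d[frozenset((i, k))]
            djk = d[frozenset((j, k))]
            new_d[frozenset((next_id, k))] = (
                (dik * ci["size"] + djk * cj["size"]) / (ci["size"] + cj["size"])
            )
        clusters[next_id] = merged
        d = new_d
        next_id += 1
    root = next(iter(clusters.values()))
    return root["newick"] + ";"


# ---------------------------------------------------------------------------
# Differential abundance


def differential_taxa(
    table: OtuTable,
    design: SampleDesign,
    compartment: str,
    taxonomy: TaxonomyMap | None = None,
    level: str = "otu",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon two-sample Student's t-test (equal variance) of relative
    abundances between FI and DI within one compartment.

    Returns a frame with columns taxon, mean_FI, mean_DI, t, p, significant,
    direction ("DI" when over-represented under deficit irrigation, "FI"
    otherwise, empty when not significant or untestable).
    """
    if level != "otu":
        if taxonomy is None:
            raise ValueError("aggregating to a rank requires a taxonomy")
        table = aggregate_to_rank(table, taxonomy, level)
    fi = [s for s in design.samples(compartment, "FI") if s in table.data.columns]
    di = [s for s in design.samples(compartment, "DI") if s in table.data.columns]
    if len(fi) < 2 or len(di) < 2:
        raise ValueError("need at least two replicates per treatment")
    rows = []
    for taxon in table.otu_ids:
        a = table.data.loc[taxon, fi].to_numpy(dtype=float)
        b = table.data.loc[taxon, di].to_numpy(dtype=float)
        if a.std() == 0 and b.std() == 0:
            rows.append((taxon, a.mean(), b.mean(), np.nan, np.nan, False, ""))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        sig = bool(p < alpha)
        direction = ("DI" if b.mean() > a.mean() else "FI") if sig else ""
        rows.append((taxon, a.mean(), b.mean(), float(t), float(p), sig, direction))
    return pd.DataFrame(rows, columns=["taxon", "mean_FI", "mean_DI", "t", "p",
                                       "significant", "direction"])
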