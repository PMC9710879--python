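"""DIANA clustering of genotype expression profiles into rescue classes.

Genes are represented by z-scored genotype-mean profiles, clustered
top-down with DIvisive ANAlysis (Kaufman & Rousseeuw), and each cluster is
annotated by where its mean double-heterozygote z-value sits between the
wild-type and single-heterozygote values: near WT means the dysregulation is
gone (complete rescue), near the single mutant means it persists (no
rescue), in between is partial rescue — separately for up- and
down-regulated patterns, giving six classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from generescue.constants import GENOTYPES
from generescue.rescue import genotype_means

UNCLASSIFIED = "unclassified"
RESCUE_CLASSES = (
    "complete-up", "partial-up", "none-up",
    "complete-down", "partial-down", "none-down",
)


def zscore_profiles(
    profile: pd.DataFrame,
    genes: Iterable[str] | None = None,
    genotype_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores of genotype means (population SD, divide by n).

    Returns the z-matrix and the list of constant-profile genes that were
    excluded (their z-score is undefined).
    """
    if genotype_order is not None:
        profile = profile[list(genotype_order)]
    if profile.shape[1] < 2:
        raise ValueError("need at least 2 genotype groups to z-score")
    if genes is not None:
        profile = profile.loc[list(genes)]
    arr = profile.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] < 1e-12
    excluded = list(profile.index[constant])
    z = (arr[~constant] - mean[~constant]) / sd[~constant]
    return pd.DataFrame(z, index=profile.index[~constant],
                        columns=profile.columns), excluded


def correlation_dissimilarity(z: pd.DataFrame) -> np.ndarray:
    """(1 - Pearson correlation) / 2 between gene profiles, in [0, 1]."""
    c = np.corrcoef(z.to_numpy(dtype=float))
    c = np.clip(np.atleast_2d(c), -1.0, 1.0)
    d = (1.0 - c) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def euclidean_dissimilarity(z: pd.DataFrame) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(z.to_numpy(dtype=float)))


@dataclass
class DianaTree:
    """Divisive hierarchy: ordered splits with non-increasing heights.

    ``splits[i]`` is (height, members, splinter, remainder); applying the
    first k-1 splits in order yields the k-cluster partition, because DIANA
    always divides the current largest-diameter cluster.
    """

    n: int
    splits: list[tuple[float, tuple[int, ...], tuple[int, ...], tuple[int, ...]]]
    labels: list[str] = field(default_factory=list)

    @property
    def heights(self) -> list[float]:
        return [s[0] for s in self.splits]


def _diameter(d: np.ndarray, members: np.ndarray) -> float:
    if len(members) < 2:
        return 0.0
    return float(d[np.ix_(members, members)].max())


def _split_cluster(
    d: np.ndarray, members: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One DIANA division: seed a splinter group, then migrate objects.

    The seed is the object with the largest average dissimilarity to its
    cluster-mates; objects then move to the splinter while some object's
    average dissimilarity to the remainder exceeds its average dissimilarity
    to the splinter. Ties broken by lowest object index.
    """
    m = len(members)
    sub = d[np.ix_(members, members)]
    avg_within = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmin(np.where(avg_within == avg_within.max(), members, np.inf)))
    # seed is position in `members` of the tied object with lowest index
    in_splinter = np.zeros(m, dtype=bool)
    in_splinter[seed] = True
    while in_splinter.sum() < m - 1:
        rem = np.flatnonzero(~in_splinter)
        spl = np.flatnonzero(in_splinter)
        n_rem = len(rem)
        to_rest = sub[np.ix_(rem, rem)].sum(axis=1) / (n_rem - 1)
        to_spl = sub[np.ix_(rem, spl)].mean(axis=1)
        diff = to_rest - to_spl
        best = diff.max()
        if best <= 0:
            break
        tied = rem[diff == best]
        mover = tied[np.argmin(members[tied])]
        in_splinter[mover] = True
    return members[in_splinter], members[~in_splinter]


def diana(dissimilarity: np.ndarray | pd.DataFrame) -> DianaTree:
    """Divisive analysis clustering of a dissimilarity matrix.

    Repeatedly splits the cluster of largest diameter until all clusters are
    singletons, recording each split at the parent cluster's diameter.
    Deterministic: all ties are broken by lowest object index.
    """
    labels: list[str] = []
    if isinstance(dissimilarity, pd.DataFrame):
        labels = [str(x) for x in dissimilarity.index]
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if (d < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = d.shape[0]

    clusters: list[np.ndarray] = [np.arange(n)]
    splits: list[tuple[float, tuple[int, ...], tuple[int, ...], tuple[int, ...]]] = []
    while True:
        divisible = [(i, _diameter(d, c)) for i, c in enumerate(clusters)
                     if len(c) > 1]
        if not divisible:
            break
        max_diam = max(h for _, h in divisible)
        # tie-break: the candidate containing the lowest object index
        candidates = [i for i, h in divisible if h == max_diam]
        idx = min(candidates, key=lambda i: clusters[i].min())
        parent = clusters.pop(idx)
        splinter, remainder = _split_cluster(d, parent)
        splits.append(
            (max_diam, tuple(parent), tuple(splinter), tuple(remainder))
        )
        clusters.append(splinter)
        clusters.append(remainder)
    return DianaTree(n=n, splits=splits, labels=labels)


def cut_tree(
    tree: DianaTree,
    k: int,
    min_cluster_size: int = 1,
) -> pd.Series:
    """Flat partition into k clusters (the k-1 highest splits).

    Cluster ids are 1..k ordered by each cluster's lowest object index.
    Clusters smaller than ``min_cluster_size`` are dissolved: their objects
    get cluster id 0, meaning unclassified downstream.
    """
    if not 1 <= k <= tree.n:
        raise ValueError(f"k must lie in [1, {tree.n}]")
    parts: list[tuple[int, ...]] = [tuple(range(tree.n))]
    for height, parent, splinter, remainder in tree.splits[: k - 1]:
        parts.remove(parent)
        parts.append(splinter)
        parts.append(remainder)
    parts.sort(key=min)
    assign = np.zeros(tree.n, dtype=int)
    cid = 0
    for part in parts:
        if len(part) >= min_cluster_size:
            cid += 1
            assign[list(part)] = cid
    index = tree.labels if tree.labels else list(range(tree.n))
    return pd.Series(assign, index=index, name="cluster")


def classify_rescue(
    cluster_profiles: pd.DataFrame,
    wt: str = "WT",
    double: str = "Double",
    single: str = "NipblHet",
    thresholds: tuple[float, float] = (0.25, 0.75),
) -> pd.Series:
    """Annotate cluster mean z-profiles with a rescue class.

    direction = sign(z_single - z_WT); position rho = (z_double - z_WT) /
    (z_single - z_WT). rho <= lower threshold: complete rescue; rho >= upper:
    no rescue; otherwise partial. A flat single-vs-WT contrast (|difference|
    < 1e-6) is unclassified.
    """
    lo, hi = thresholds
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("thresholds must satisfy 0 < lower < upper < 1")
    for col in (wt, double, single):
        if col not in cluster_profiles.columns:
            raise KeyError(f"genotype column {col!r} missing from profiles")
    out = {}
    for cid, row in cluster_profiles.iterrows():
        span = row[single] - row[wt]
        if abs(span) < 1e-6:
            out[cid] = UNCLASSIFIED
            continue
        rho = (row[double] - row[wt]) / span
        direction = "up" if span > 0 else "down"
        if rho <= lo:
            grade = "complete"
        elif rho >= hi:
            grade = "none"
        else:
            grade = "partial"
        out[cid] = f"{grade}-{direction}"
    return pd.Series(out, name="rescue_class")


def rescue_classes(
    norm_counts: pd.DataFrame,
    samples: pd.DataFrame,
    deg_genes: Sequence[str],
    single: str = "NipblHet",
    k: int = 6,
    min_cluster_size: int = 15,
    distance: str = "correlation",
    thresholds: tuple[float, float] = (0.25, 0.75),
    genotype_order: Sequence[str] | None = None,
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """End-to-end: z-profiles -> DIANA -> cut -> per-gene rescue class.

    Returns (per-gene class, per-gene cluster id, cluster mean z-profiles).
    Genes in dissolved clusters, in clusters with a flat single-vs-WT
    contrast, or with constant profiles are "unclassified".
    ``genotype_order`` restricts and orders the genotype columns used for
    clustering (e.g. ("WT", "NipblHet", "Double") to drop the other single
    mutant's class-irrelevant variation from the profiles).
    """
    required = tuple(genotype_order) if genotype_order is not None else GENOTYPES
    profile = genotype_means(norm_counts, samples, required=required)
    z, excluded = zscore_profiles(
        profile, genes=deg_genes, genotype_order=genotype_order
    )
    if distance == "correlation":
        d = correlation_dissimilarity(z)
    elif distance == "euclidean":
        d = euclidean_dissimilarity(z)
    else:
        raise ValueError("distance must be 'correlation' or 'euclidean'")
    tree = diana(pd.DataFrame(d, index=z.index, columns=z.index))
    clusters = cut_tree(tree, k=k, min_cluster_size=min_cluster_size)
    cluster_profiles = (
        z.assign(cluster=clusters).query("cluster > 0").groupby("cluster").mean()
    )
    class_of_cluster = classify_rescue(
        cluster_profiles, single=single, thresholds=thresholds
    )
    gene_class = clusters.map(
        lambda c: class_of_cluster.get(c, UNCLASSIFIED) if c > 0 else UNCLASSIFIED
    )
    for g in excluded:
        gene_class[g] = UNCLASSIFIED
        clusters[g] = 0
    gene_class.name = "rescue_class"
    return gene_class, clusters, cluster_profiles


@dataclass(frozen=True)
class RescueSummary:
    """Per-class counts and the two rescued-gene percentages."""

    counts: dict[str, int]
    n_classified: int
    n_total: int

    @property
    def percent_rescued_of_classified(self) -> float:
        if self.n_classified == 0:
            return float("nan")
        rescued = sum(
            n for cls, n in self.counts.items()
            if cls.startswith(("complete", "partial"))
        )
        return 100.0 * rescued / self.n_classified

    @property
    def percent_rescued_of_total(self) -> float:
        if self.n_total == 0:
            return float("nan")
        rescued = sum(
            n for cls, n in self.counts.items()
            if cls.startswith(("complete", "partial"))
        )
        return 100.0 * rescued / self.n_total


def rescue_summary(assignments: pd.Series) -> RescueSummary:
    """Tally rescue classes; percentages over classified genes and all genes."""
    counts = {cls: 0 for cls in RESCUE_CLASSES}
    counts[UNCLASSIFIED] = 0
    for cls in assignments:
        counts[cls] = counts.get(cls, 0) + 1
    n_total = int(len(assignments))
    n_classified = n_total - counts[UNCLASSIFIED]
    return RescueSummary(counts=counts, n_classified=n_classified, n_total=n_total)
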