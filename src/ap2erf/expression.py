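"""FPKM, normalization and the series-test-of-cluster (STC) chain.

Expression of each gene in each tissue is quantified as FPKM
(C * 1e9 / (N * L) for C fragments, N mapped fragments and L exonic bp),
log2(x+1)-transformed and row-standardized to Z-scores.  Tissue-specific
gene sets are found STEM-style: K-means clustering of the Z profiles
(K = 10, 20 random starts by default) followed by a hypergeometric test
of subfamily over-representation per cluster with Bonferroni correction
at alpha = 0.05, plus a centroid rule that names the tissue a cluster is
specific to (one component >= 1 Z, all others <= 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "EnrichmentResult",
    "compute_fpkm",
    "log_z_normalize",
    "order_heatmap",
    "stc_filter",
    "kmeans_stc",
    "cluster_enrichment",
    "call_tissue_specific",
]


@dataclass
class ClusterAssignment:
    """Gene -> cluster labels with the winning start's centroids."""

    labels: pd.Series  # index = genes, values in 0..K-1
    centroids: pd.DataFrame  # K x tissues
    inertia: float

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of a subfamily in a cluster."""

    subfamily: str
    cluster: int
    k: int       # overlap
    m: int       # subfamily size
    Kc: int      # cluster size
    n: int       # analyzed genes
    p_raw: float
    p_adj: float
    significant: bool


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series,
                 totals: pd.Series) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (totals * length), genes x tissues."""
    lengths = lengths.reindex(counts.index)
    totals = totals.reindex(counts.columns)
    bad_gene = lengths.index[(lengths.isna()) | (lengths <= 0)]
    if len(bad_gene):
        raise ValueError(f"zero/missing exonic length for gene {bad_gene[0]}")
    bad_tissue = totals.index[(totals.isna()) | (totals <= 0)]
    if len(bad_tissue):
        raise ValueError(f"zero/missing mapped total for tissue {bad_tissue[0]}")
    return counts.mul(1e9).div(totals, axis=1).div(lengths, axis=0)


def log_z_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) then per-row standardization; constant rows -> zeros."""
    if m.empty:
        raise ValueError("empty expression matrix")
    logged = np.log2(m + 1.0)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=0)
    z = logged.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def order_heatmap(z: pd.DataFrame, method: str = "average",
                  metric: str = "euclidean") -> tuple[list[str], list[str]]:
    """Row and column leaf orders from agglomerative clustering."""

    def _order(frame: pd.DataFrame) -> list[str]:
        if len(frame) < 2:
            return list(frame.index)
        lk = linkage(pdist(frame.values, metric=metric), method=method)
        return [frame.index[i] for i in leaves_list(lk)]

    return _order(z), _order(z.T)


def stc_filter(fpkm: pd.DataFrame, min_max_fpkm: float = 1.0) -> pd.DataFrame:
    """Drop genes never expressed above min_max_fpkm or with zero variance.

    Mirrors the detected-gene reduction a clustering program applies
    before fitting profiles; a gene whose maximum FPKM reaches the floor
    is always retained unless its profile is flat.
    """
    keep = (fpkm.max(axis=1) >= min_max_fpkm) & (fpkm.var(axis=1) > 0)
    return fpkm.loc[keep]


def kmeans_stc(z: pd.DataFrame, k: int = 10, n_starts: int = 20,
               seed: int = 0) -> ClusterAssignment:
    """K-means (Lloyd) on Z rows; best of n_starts random initializations."""
    if k > len(z):
        raise ValueError(f"K={k} exceeds number of genes {len(z)}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    km = KMeans(n_clusters=k, init="random", n_init=n_starts,
                random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(z.values)
    return ClusterAssignment(
        labels=pd.Series(labels, index=z.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=z.columns),
        inertia=float(km.inertia_),
    )


def cluster_enrichment(assign: ClusterAssignment, labels: dict[str, str],
                       alpha: float = 0.05) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of subfamilies in clusters.

    p_raw = P(X >= k) drawing Kc genes without replacement from n with m
    successes; Bonferroni over (#subfamilies x #non-empty clusters).
    """
    genes = list(assign.labels.index)
    missing = [g for g in genes if g not in labels]
    if missing:
        raise ValueError(f"unlabeled gene: {missing[0]}")
    n = len(genes)
    subfamilies = sorted({labels[g] for g in genes})
    clusters = sorted(assign.labels.unique())
    tests = len(subfamilies) * len(clusters)
    results: list[EnrichmentResult] = []
    for sf in subfamilies:
        m = sum(1 for g in genes if labels[g] == sf)
        for c in clusters:
            members = assign.members(c)
            Kc = len(members)
            k = sum(1 for g in members if labels[g] == sf)
            p_raw = float(hypergeom.sf(k - 1, n, m, Kc))
            p_adj = min(1.0, p_raw * tests)
            results.append(EnrichmentResult(
                subfamily=sf, cluster=int(c), k=k, m=m, Kc=Kc, n=n,
                p_raw=p_raw, p_adj=p_adj, significant=p_adj <= alpha))
    return results


def call_tissue_specific(assign: ClusterAssignment, high_z: float = 1.0,
                         low_z: float = 0.0) -> dict[int, str | None]:
    """Name the tissue each cluster is specific to, if any.

    A cluster is specific to tissue t iff its centroid is >= high_z at t
    and <= low_z everywhere else; otherwise it gets None.
    """
    calls: dict[int, str | None] = {}
    for c, centroid in assign.centroids.iterrows():
        above = centroid[centroid >= high_z]
        rest_ok = (centroid.drop(above.index) <= low_z).all()
        if len(above) == 1 and rest_ok:
            calls[int(c)] = str(above.index[0])
        else:
            calls[int(c)] = None
    return calls


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subfamily\tcluster\tk\tm\tKc\tn\tp_raw\tp_adj\tsignificant\n")
        for r in results:
            fh.write(f"{r.subfamily}\t{r.cluster}\t{r.k}\t{r.m}\t{r.Kc}\t"
                     f"{r.n}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\t{r.significant}\n")
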