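"""Descriptive methylome profiling.

Methylation-state binning (LMS / PMS / HMS with the 0.2 / 0.7 beta
thresholds; 0.2 and 0.7 themselves count as partially methylated),
decile histograms of beta, annotation-stratified mean +/- sd summaries
with pairwise two-sample t-tests, sample clustering (average-linkage
hierarchical with newick export, k-means, PCA) and replicate
concordance via Pearson correlation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from skbio import TreeNode
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .manifest_io import ProbeManifest

STATE_ORDER = ("LMS", "PMS", "HMS")


@dataclass
class StateBinning:
    thresholds: tuple[float, float]
    counts: pd.DataFrame  # samples x (LMS, PMS, HMS)
    fractions: pd.DataFrame
    histogram: pd.DataFrame  # samples x 10 decile bins
    mean_beta: pd.Series


def classify_states(
    beta: pd.DataFrame, thresholds: tuple[float, float] = (0.2, 0.7)
) -> StateBinning:
    """Bin every beta value into LMS (< low), PMS ([low, high]), HMS (> high).

    Also returns the per-sample histogram in 0.1 increments (bins
    right-closed except the first, which includes 0).
    """
    low, high = thresholds
    if not (0 < low < high < 1):
        raise ValueError("thresholds must be strictly increasing inside (0, 1)")
    vals = beta.values
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    lms = (vals < low).sum(axis=0)
    hms = (vals > high).sum(axis=0)
    pms = vals.shape[0] - lms - hms
    counts = pd.DataFrame(
        {"LMS": lms, "PMS": pms, "HMS": hms}, index=beta.columns
    )[list(STATE_ORDER)]
    fractions = counts.div(counts.sum(axis=1), axis=0)
    bin_idx = np.clip(np.ceil(vals * 10).astype(int) - 1, 0, 9)
    hist = np.stack(
        [np.bincount(bin_idx[:, j], minlength=10) for j in range(vals.shape[1])]
    )
    labels = [f"({i/10:.1f},{(i+1)/10:.1f}]" for i in range(10)]
    labels[0] = "[0.0,0.1]"
    histogram = pd.DataFrame(hist, index=beta.columns, columns=labels)
    return StateBinning(
        thresholds=thresholds,
        counts=counts,
        fractions=fractions,
        histogram=histogram,
        mean_beta=beta.mean(axis=0),
    )


@dataclass
class AnnotationSummary:
    grouping: str
    table: pd.DataFrame  # rows: annotation group, columns: (sample_type, mean/sd/n)
    pvalues: pd.DataFrame  # rows: annotation group, columns: "typeA|typeB"


def annotation_summary(
    beta: pd.DataFrame,
    manifest: ProbeManifest,
    grouping: str,
    group_labels: Mapping[str, str],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> AnnotationSummary:
    """Mean +/- sd beta per (annotation group x sample type) with pair tests.

    grouping is one of compartment / cgi_relation / hil_class /
    cpg_context (an alias of cgi_relation).  Per-probe means within each
    sample type are compared between types by a two-sample t-test.
    Empty annotation groups are reported with missing means and no test.
    """
    column = "cgi_relation" if grouping == "cpg_context" else grouping
    if column not in ("compartment", "cgi_relation", "hil_class"):
        raise ValueError(f"unknown grouping {grouping!r}")
    ann = manifest.df.loc[beta.index, column]
    labels = pd.Series(group_labels)
    sample_types = list(dict.fromkeys(labels.loc[beta.columns]))
    # per-probe mean beta within each sample type
    type_means = {
        t: beta[labels.index[labels == t].intersection(beta.columns)].mean(axis=1)
        for t in sample_types
    }
    if pairs is None:
        pairs = list(combinations(sample_types, 2))
    groups = sorted(ann.unique())
    stats_rows, p_rows = [], []
    for g in groups:
        probes = ann.index[ann == g]
        row = {}
        for t in sample_types:
            vals = type_means[t].loc[probes]
            row[(t, "mean")] = vals.mean() if len(vals) else np.nan
            row[(t, "sd")] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[(t, "n")] = len(vals)
        stats_rows.append(row)
        p_row = {}
        for a, b in pairs:
            if len(probes) < 2:
                p_row[f"{a}|{b}"] = np.nan
            else:
                va = type_means[a].loc[probes].values
                vb = type_means[b].loc[probes].values
                if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
                    # degenerate constant groups: no evidence either way
                    p_row[f"{a}|{b}"] = 1.0 if np.isclose(va.mean(), vb.mean()) else 0.0
                else:
                    p_row[f"{a}|{b}"] = stats.ttest_ind(va, vb).pvalue
        p_rows.append(p_row)
    table = pd.DataFrame(stats_rows, index=groups)
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    pvalues = pd.DataFrame(p_rows, index=groups)
    return AnnotationSummary(grouping=grouping, table=table, pvalues=pvalues)


@dataclass
class ClusteringResult:
    method: str
    newick: str | None = None
    linkage_matrix: np.ndarray | None = None
    labels: pd.Series | None = None
    scores: pd.DataFrame | None = None
    explained_variance_ratio: np.ndarray | None = None


def cluster_samples(
    beta: pd.DataFrame,
    method: str = "hierarchical_average",
    k: int | None = None,
    n_components: int = 2,
    seed: int = 0,
) -> ClusteringResult:
    """Cluster samples (columns) of a beta matrix.

    hierarchical_average: average linkage on Euclidean distance over
    probes, exported as a newick tree with sample labels.
    kmeans: assignments for k clusters (10 restarts, fixed seed).
    pca: per-sample scores of the top principal components.
    """
    n_samples = beta.shape[1]
    if n_samples < 3:
        raise ValueError("need >= 3 samples to cluster")
    x = beta.values.T  # samples x probes
    if method == "hierarchical_average":
        z = linkage(pdist(x, metric="euclidean"), method="average")
        tree = TreeNode.from_linkage_matrix(z, list(beta.columns))
        buf = io.StringIO()
        tree.write(buf)
        return ClusteringResult(method=method, newick=buf.getvalue().strip(), linkage_matrix=z)
    if method == "kmeans":
        if k is None:
            raise ValueError("kmeans needs k")
        if k > n_samples:
            raise ValueError(f"k={k} exceeds the number of samples ({n_samples})")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        return ClusteringResult(
            method=method, labels=pd.Series(km.labels_, index=beta.columns, name="cluster")
        )
    if method == "pca":
        n_components = min(n_components, n_samples)
        pca = PCA(n_components=n_components, random_state=seed)
        scores = pca.fit_transform(x - x.mean(axis=0))
        return ClusteringResult(
            method=method,
            scores=pd.DataFrame(
                scores,
                index=beta.columns,
                columns=[f"PC{i+1}" for i in range(scores.shape[1])],
            ),
            explained_variance_ratio=pca.explained_variance_ratio_,
        )
    raise ValueError(f"unknown clustering method {method!r}")


def cut_tree_k(linkage_matrix: np.ndarray, sample_ids: Sequence[str], k: int) -> pd.Series:
    """Flat cluster assignment from a hierarchical tree cut into k groups."""
    from scipy.cluster.hierarchy import fcluster

    return pd.Series(
        fcluster(linkage_matrix, t=k, criterion="maxclust"), index=list(sample_ids)
    )


def replicate_concordance(
    beta: pd.DataFrame, replicate_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and t-based p) between replicate samples.

    Zero-variance samples yield missing correlations.
    """
    ids = list(replicate_ids)
    if len(ids) < 2:
        raise ValueError("need >= 2 replicates")
    sub = beta[ids]
    n = sub.shape[0]
    r_mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    p_mat = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for a, b in combinations(ids, 2):
        xa, xb = sub[a].values, sub[b].values
        if xa.std() == 0 or xb.std() == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(xa, xb)
        r_mat.loc[a, b] = r_mat.loc[b, a] = r
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
    return r_mat, p_mat
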