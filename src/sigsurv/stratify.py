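"""Gene-gene correlation structure and immune-based patient stratification.

The tumor cohort is stratified into immune-low / mixed / immune-high
subtypes by agglomerative clustering of the per-patient signature profiles
(uncentered-Pearson dissimilarity, average linkage), cutting the tree into
k clusters and ranking the clusters by their mean expression over the
ten-gene immune core.  Supporting statistics: pairwise Pearson correlations
with Holm step-down correction, variance-equality-routed group comparisons
(Student/Welch t, ANOVA/Tukey or Welch-ANOVA/Games-Howell), chi-square
tests and PCA embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix
from .signature import GeneSignature

__all__ = [
    "CorrelationResult",
    "Dendrogram",
    "SubtypeAssignment",
    "GroupComparisonResult",
    "correlation_matrix",
    "hcluster",
    "assign_subtypes",
    "compare_groups",
    "chi_square_2xk",
    "pca_embed",
]


# ---------------------------------------------------------------------------
# correlation matrix


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n_used: int


def correlation_matrix(expr: ExpressionMatrix) -> CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-based p-values and
    Holm step-down adjustment over the unique off-diagonal pairs.

    Constant genes yield undefined correlations (NaN) with a warning.
    Diagonal convention: r = 1, p = 0.
    """
    df = expr.values
    if df.isna().any().any():
        raise ValueError("correlation_matrix requires a complete matrix (impute first)")
    n, p = df.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant gene(s) {list(df.columns[constant])}: correlations undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p_raw[np.isinf(t)] = 0.0
    np.fill_diagonal(p_raw, 0.0)

    iu = np.triu_indices(p, k=1)
    flat = p_raw[iu]
    ok = ~np.isnan(flat)
    adj_flat = np.full_like(flat, np.nan)
    if ok.sum():
        adj_flat[ok] = multipletests(flat[ok], method="holm")[1]
    p_adj = np.full_like(p_raw, np.nan)
    p_adj[iu] = adj_flat
    p_adj.T[iu] = adj_flat
    np.fill_diagonal(p_adj, 0.0)

    idx = df.columns
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p_raw=pd.DataFrame(p_raw, index=idx, columns=idx),
        p_adj=pd.DataFrame(p_adj, index=idx, columns=idx),
        n_used=n,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class Dendrogram:
    """Agglomeration result in scipy linkage convention: leaves are
    0..n-1, the merge at step s creates cluster n+s."""

    merges: list  # (child_a, child_b, height, size)
    leaf_order: list
    labels: list
    metric: str
    linkage: str = "average"

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (0..k-1) after breaking the k-1 last (largest)
        merges; labels are numbered by first appearance."""
        n = len(self.labels)
        if k < 1 or k > n:
            raise ValueError("k must be in 1..n")
        parent = list(range(n + len(self.merges)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for s, (a, b, _, _) in enumerate(self.merges[: len(self.merges) - (k - 1)]):
            new = n + s
            parent[find(int(a))] = new
            parent[find(int(b))] = new
        roots: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for i in range(n):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            labels[i] = roots[r]
        return labels


def _pearson_uncentered_dissim(X: np.ndarray, labels) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        raise ValueError(
            f"zero-norm item(s) under the uncentered-Pearson metric: "
            f"{[labels[i] for i in np.flatnonzero(zero)]}"
        )
    u = (X @ X.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(u, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def hcluster(
    items: np.ndarray | pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of matrix rows.

    Metrics: ``euclidean`` or ``pearson_uncentered`` (dissimilarity
    1 - sum(x*y)/(||x|| ||y||)).  Average linkage (UPGMA): the unweighted
    mean pairwise dissimilarity between cluster members.  When two merges
    tie on distance, the pair whose clusters contain the smallest leaf
    indices (lexicographically) merges first.
    """
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    if isinstance(items, pd.DataFrame):
        labels = list(items.index)
        X = items.to_numpy(dtype=float)
    else:
        X = np.asarray(items, dtype=float)
        labels = list(range(X.shape[0]))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    elif metric == "pearson_uncentered":
        d = _pearson_uncentered_dissim(X, labels)
    else:
        raise ValueError("metric must be 'euclidean' or 'pearson_uncentered'")

    # O(n^3) agglomeration on the cluster-distance matrix
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    dist = {}
    for ii in range(n):
        for jj in range(ii + 1, n):
            dist[(ii, jj)] = d[ii, jj]
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        best_key = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                key = (a, b) if a < b else (b, a)
                dd = dist[key]
                la, lb = min_leaf[a], min_leaf[b]
                tie_key = (dd, min(la, lb), max(la, lb))
                if best is None or tie_key < best_key:
                    best = key
                    best_key = tie_key
        a, b = best
        dd = best_key[0]
        merges.append((a, b, float(dd), sizes[a] + sizes[b]))
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            dist[(min(new, c), max(new, c))] = (
                sizes[a] * dist[ka] + sizes[b] * dist[kb]
            ) / (sizes[a] + sizes[b])
        sizes[new] = sizes[a] + sizes[b]
        min_leaf[new] = min(min_leaf[a], min_leaf[b])
        active.remove(a)
        active.remove(b)
        active.append(new)

    # leaf order by recursive traversal
    children = {n + s: (m[0], m[1]) for s, m in enumerate(merges)}
    order: list[int] = []
    stack = [active[0]]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            a, b = children[node]
            stack.append(b)
            stack.append(a)
    return Dendrogram(
        merges=merges, leaf_order=order, labels=labels, metric=metric
    )


# ---------------------------------------------------------------------------
# subtype assignment


@dataclass
class SubtypeAssignment:
    labels: pd.Series  # immune_low / mixed / immune_high per sample
    immune_core: tuple[str, ...]
    cluster_means: dict  # cluster id -> mean immune-core expression
    k: int
    min_separation: float
    dendrogram: Dendrogram


def assign_subtypes(
    expr: ExpressionMatrix,
    signature: GeneSignature,
    k: int = 3,
    min_separation: float = 0.5,
) -> SubtypeAssignment:
    """Cluster patients on the full signature and label the extreme
    clusters by immune content.

    Patients are clustered by uncentered-Pearson average-linkage on their
    signature profiles and the tree is cut into ``k`` clusters (breaking
    the k-1 largest merges).  Clusters are ranked by mean expression over
    the immune core; the lowest becomes immune_low, the highest
    immune_high, the rest mixed.  If the immune-core means of the extreme
    clusters differ by less than ``min_separation`` (log2 units) the cohort
    is considered unstratified: every sample is labeled mixed.
    """
    genes = [g for g in signature.genes if g in expr.values.columns]
    core = [g for g in signature.immune_core if g in expr.values.columns]
    if not core:
        raise ValueError("no immune-core genes present in the expression matrix")
    mat = expr.values.loc[:, genes]
    if mat.isna().any().any():
        raise ValueError("assign_subtypes requires a complete matrix")
    n = mat.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    dend = hcluster(mat, metric="pearson_uncentered")
    cl = dend.cut(k)
    core_mean = expr.values.loc[:, core].mean(axis=1).to_numpy()
    cluster_means = {c: float(core_mean[cl == c].mean()) for c in np.unique(cl)}
    ranked = sorted(cluster_means, key=cluster_means.get)
    spread = cluster_means[ranked[-1]] - cluster_means[ranked[0]]
    labels = np.full(n, "mixed", dtype=object)
    if spread >= min_separation and k >= 2:
        labels[cl == ranked[0]] = "immune_low"
        labels[cl == ranked[-1]] = "immune_high"
    return SubtypeAssignment(
        labels=pd.Series(labels, index=mat.index, name="subtype"),
        immune_core=tuple(core),
        cluster_means=cluster_means,
        k=k,
        min_separation=min_separation,
        dendrogram=dend,
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparisonResult:
    table: pd.DataFrame
    posthoc: dict  # gene -> pairwise post-hoc DataFrame (>2 groups only)
    alpha_levene: float = 0.05


def _two_group_test(a: np.ndarray, b: np.ndarray, equal_var: bool):
    if np.ptp(np.concatenate([a, b])) == 0:
        return ("student_t" if equal_var else "welch_t"), 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    name = "student_t" if equal_var else "welch_t"
    return name, float(res.statistic), float(res.pvalue)


def compare_groups(
    expr: ExpressionMatrix,
    labels: pd.Series | np.ndarray,
    alpha_levene: float = 0.05,
) -> GroupComparisonResult:
    """Per-gene group comparison routed by Levene's variance-equality test.

    Two groups: Student's t (equal variances) or Welch's t.  More groups:
    one-way ANOVA with Tukey HSD, or Welch's ANOVA with Games-Howell.
    Two-sided p-values; Holm-adjusted p across genes.  Groups with fewer
    than 2 samples make a gene untestable (flagged, NaN statistics).
    """
    import pingouin as pg

    if isinstance(labels, pd.Series):
        lab = labels.reindex(expr.values.index).to_numpy()
    else:
        lab = np.asarray(labels)
    groups = [g for g in pd.unique(lab) if not pd.isna(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    posthoc: dict[str, pd.DataFrame] = {}
    for gene in expr.values.columns:
        x = expr.values[gene].to_numpy(dtype=float)
        samples = [x[lab == g] for g in groups]
        if min(len(s) for s in samples) < 2:
            rows.append(
                dict(gene=gene, test="untestable", statistic=np.nan,
                     levene_p=np.nan, p_raw=np.nan, direction=None,
                     **{f"mean_{g}": float(np.mean(s)) if len(s) else np.nan
                        for g, s in zip(groups, samples)})
            )
            continue
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(x) == 0:
            lev_p = 1.0
        else:
            lev_p = float(stats.levene(*samples, center="mean").pvalue)
            if np.isnan(lev_p):
                lev_p = 1.0
        equal_var = lev_p >= alpha_levene
        if len(groups) == 2:
            test, statistic, p = _two_group_test(samples[0], samples[1], equal_var)
        else:
            df_long = pd.DataFrame({"y": x, "g": lab}).dropna()
            if equal_var:
                test = "anova_tukey"
                res = stats.f_oneway(*samples)
                statistic, p = float(res.statistic), float(res.pvalue)
                if np.isnan(statistic):
                    statistic, p = 0.0, 1.0
                ph = stats.tukey_hsd(*samples)
                posthoc[gene] = pd.DataFrame(
                    [
                        {"group_a": groups[i], "group_b": groups[j],
                         "p": float(ph.pvalue[i, j])}
                        for i in range(len(groups))
                        for j in range(i + 1, len(groups))
                    ]
                )
            else:
                test = "welch_anova_games_howell"
                aov = pg.welch_anova(data=df_long, dv="y", between="g")
                statistic = float(aov["F"].iloc[0])
                pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
                p = float(aov[pcol].iloc[0])
                gh = pg.pairwise_gameshowell(data=df_long, dv="y", between="g")
                posthoc[gene] = gh.rename(
                    columns={"A": "group_a", "B": "group_b", "pval": "p"}
                )[["group_a", "group_b", "p"]]
        means = {f"mean_{g}": float(np.mean(s)) for g, s in zip(groups, samples)}
        direction = max(groups, key=lambda g: means[f"mean_{g}"])
        rows.append(
            dict(gene=gene, test=test, statistic=statistic, levene_p=lev_p,
                 p_raw=p, direction=direction, **means)
        )
    table = pd.DataFrame(rows).set_index("gene")
    ok = table["p_raw"].notna()
    table["p_holm"] = np.nan
    if ok.sum():
        table.loc[ok, "p_holm"] = multipletests(table.loc[ok, "p_raw"], method="holm")[1]
    return GroupComparisonResult(table=table, posthoc=posthoc, alpha_levene=alpha_levene)


def chi_square_2xk(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction; df = (r-1)(c-1)."""
    tab = np.asarray(table)
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("contingency table must hold non-negative integer counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    stat, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(stat), int(df), float(p)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame
    variance_fractions: np.ndarray  # over ALL components (sums to 1)
    n_components: int
    genes_used: list


def pca_embed(
    expr: ExpressionMatrix,
    n_components: int = 3,
    prefilter_p: float | None = None,
    labels: pd.Series | np.ndarray | None = None,
) -> PCAResult:
    """Column-centered SVD embedding of the samples.

    With ``prefilter_p`` (requires ``labels``), only genes whose
    group-comparison p-value falls below the cutoff enter the embedding.
    """
    df = expr.values
    if df.isna().any().any():
        raise ValueError("pca_embed requires a complete matrix")
    genes = list(df.columns)
    if prefilter_p is not None:
        if labels is None:
            raise ValueError("prefilter_p requires group labels")
        cmp_res = compare_groups(expr, labels)
        keep = cmp_res.table["p_raw"] < prefilter_p
        genes = list(cmp_res.table.index[keep])
        if not genes:
            raise ValueError("prefilter removed every gene")
        df = df.loc[:, genes]
    X = df.to_numpy(dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    scores = u[:, :n_components] * s[:n_components]
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=df.index,
            columns=[f"PC{i+1}" for i in range(n_components)],
        ),
        variance_fractions=frac,
        n_components=n_components,
        genes_used=genes,
    )
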