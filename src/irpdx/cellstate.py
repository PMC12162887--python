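"""Single-cell state analysis and the recurrence-associated cilia signature.

The workflow mirrors a standard droplet scRNA-seq analysis of PDX tumour
cells: highly-variable-gene selection, PCA on scaled data, a k-nearest
neighbour graph and Louvain community detection (resolution 0.25), one-vs-
rest Wilcoxon rank-sum cluster markers, cross-patient marker overlap as
Jaccard indices, and derivation of a recurrence-associated cilia (RAC)
signature: the most highly expressed genes of the two patients' ciliated-
cluster marker intersection.  Cells are scored for gene modules by mean
signature expression minus the mean of expression-bin-matched random
control genes, and cohorts are compared via the fraction of cells scoring
above mean + 2 SD and a rank-sum test on per-tumour mean scores.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

DEFAULT_N_HVG = 2000
DEFAULT_N_PCS = 15
DEFAULT_K = 20
DEFAULT_RESOLUTION = 0.25
MARKER_ALPHA = 0.05
MARKER_MIN_LFC = 0.25
MARKER_MIN_PCT = 0.10
MODULE_N_BINS = 25
MODULE_N_CTRL = 100
RAC_N_TOP = 50


# ---------------------------------------------------------------------------
# variable genes, embedding, clustering


def hvg_select(adata: AnnData, n: int = DEFAULT_N_HVG, n_mean_bins: int = 20) -> list[str]:
    """Top-``n`` genes by variance-stabilised dispersion.

    Expression is de-logged (expm1), per-gene dispersion = variance/mean is
    z-scored within equal-frequency bins of mean expression (so highly
    expressed genes are not favoured merely for their scale), and genes are
    ranked by the normalised dispersion.  Ties break lexicographically on
    the gene name, making the selection fully deterministic.
    """
    if n > adata.n_vars:
        warnings.warn(
            f"requested {n} variable genes but matrix has {adata.n_vars}; using all"
        )
        return sorted(adata.var_names)
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    vals = np.expm1(X)
    mean = vals.mean(axis=0)
    var = vals.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    df = pd.DataFrame({"mean": mean, "disp": disp}, index=adata.var_names)
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), q=min(n_mean_bins, len(df)), labels=False)
    grouped = df.groupby("bin")["disp"]
    mu, sd = grouped.transform("mean"), grouped.transform("std").replace(0, np.nan)
    df["disp_norm"] = ((df["disp"] - mu) / sd).fillna(0.0)
    order = sorted(zip(-df["disp_norm"].to_numpy(), df.index))
    return [g for _, g in order[:n]]


def embed_cluster(
    adata: AnnData,
    hvgs: list[str] | None = None,
    n_pcs: int = DEFAULT_N_PCS,
    k: int = DEFAULT_K,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
    center_by: str | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """PCA on scaled HVGs, kNN graph, Louvain communities.

    Returns the cluster assignment (categorical Series indexed by cell) and
    the PCA embedding.  ``center_by`` optionally names an ``obs`` column
    whose groups are centred in PC space (a simple stand-in for batch
    correction; synthetic fixtures carry no batch effect by default).
    Deterministic given ``seed``.
    """
    if hvgs is None:
        hvgs = hvg_select(adata)
    sub = adata[:, list(hvgs)].copy()
    if n_pcs >= min(sub.n_obs, sub.n_vars):
        raise ValueError("n_pcs must be smaller than both cell and gene counts")
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = np.clip((X - mu) / sd, -10, 10)
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(Xs)
    if center_by is not None:
        groups = adata.obs[center_by]
        for g in groups.unique():
            m = (groups == g).to_numpy()
            pcs[m] -= pcs[m].mean(axis=0)
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(pcs))).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {(i, j) if i < j else (j, i) for i, row in enumerate(idx) for j in row[1:]}
    graph = ig.Graph(n=len(pcs), edges=sorted(edges))
    random.seed(seed)
    part = graph.community_multilevel(resolution=resolution)
    labels = pd.Series(
        pd.Categorical([str(m) for m in part.membership]), index=adata.obs_names, name="cluster"
    )
    return labels, pcs


# ---------------------------------------------------------------------------
# markers


@dataclass
class MarkerResult:
    """One-vs-rest Wilcoxon rank-sum markers per cluster."""

    table: pd.DataFrame  # cluster, gene, lfc, stat, p, padj, pct
    alpha: float = MARKER_ALPHA
    min_lfc: float = MARKER_MIN_LFC
    min_pct: float = MARKER_MIN_PCT

    def marker_sets(
        self,
        alpha: float | None = None,
        min_lfc: float | None = None,
        min_pct: float | None = None,
    ) -> dict[str, set]:
        alpha = self.alpha if alpha is None else alpha
        min_lfc = self.min_lfc if min_lfc is None else min_lfc
        min_pct = self.min_pct if min_pct is None else min_pct
        t = self.table
        sig = t[(t["padj"] < alpha) & (t["lfc"] > min_lfc) & (t["pct"] >= min_pct)]
        return {cl: set(g["gene"]) for cl, g in sig.groupby("cluster", observed=True)}


def cluster_markers(adata: AnnData, clusters: pd.Series) -> MarkerResult:
    """Wilcoxon rank-sum one-vs-rest markers with BH adjustment."""
    clusters = pd.Series(clusters, index=adata.obs_names).astype(str)
    sizes = clusters.value_counts()
    groups = sorted(sizes.index[sizes >= 2])
    for cl in sorted(sizes.index[sizes < 2]):
        warnings.warn(f"cluster {cl!r} has fewer than 2 cells; skipped")
    if len(groups) < 2:
        raise ValueError("need at least two clusters with >= 2 cells")
    tmp = adata.copy()
    tmp.obs["cluster"] = pd.Categorical(clusters)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(
            tmp, "cluster", groups=groups, method="wilcoxon", pts=True, tie_correct=True
        )
    frames = []
    for cl in groups:
        df = sc.get.rank_genes_groups_df(tmp, group=cl)
        df = df.rename(
            columns={
                "names": "gene",
                "logfoldchanges": "lfc",
                "scores": "stat",
                "pvals": "p",
                "pvals_adj": "padj",
                "pct_nz_group": "pct",
            }
        )
        df["cluster"] = cl
        frames.append(df[["cluster", "gene", "lfc", "stat", "p", "padj", "pct"]])
    return MarkerResult(table=pd.concat(frames, ignore_index=True))


def marker_jaccard(sets_a: dict[str, set], sets_b: dict[str, set]) -> pd.DataFrame:
    """Jaccard index |A∩B|/|A∪B| for every cluster pair."""
    out = pd.DataFrame(index=sorted(sets_a), columns=sorted(sets_b), dtype=float)
    for ca, a in sets_a.items():
        for cb, b in sets_b.items():
            union = a | b
            if not union:
                warnings.warn(f"both marker sets empty for ({ca!r}, {cb!r}); J=0")
                out.loc[ca, cb] = 0.0
            else:
                out.loc[ca, cb] = len(a & b) / len(union)
    return out


# ---------------------------------------------------------------------------
# RAC signature and module scoring


def rac_signature(
    intersect_genes: list[str], adata_ciliated: AnnData, n_top: int = RAC_N_TOP
) -> list[str]:
    """Top-``n_top`` most highly expressed intersect genes in ciliated cells.

    Genes are ranked by mean normalised expression within the supplied
    ciliated-cell matrix; ties break lexicographically.  Returns
    ``min(n_top, |intersect|)`` genes.
    """
    genes = [g for g in dict.fromkeys(intersect_genes) if g in set(adata_ciliated.var_names)]
    if not genes:
        raise ValueError("empty intersection with the expression matrix")
    sub = adata_ciliated[:, genes]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    means = pd.Series(X.mean(axis=0), index=genes)
    order = sorted(zip(-means.to_numpy(), means.index))
    return [g for _, g in order[: min(n_top, len(genes))]]


@dataclass
class SignatureScore:
    """Per-cell module scores with the high-scorer threshold."""

    genes: list[str]
    scores: pd.Series
    n_bins: int
    n_ctrl: int
    seed: int
    control_genes: list[str] = field(default_factory=list)

    @property
    def threshold(self) -> float:
        return float(self.scores.mean() + 2.0 * self.scores.std(ddof=1))


def module_score(
    adata: AnnData,
    genes: list[str],
    n_bins: int = MODULE_N_BINS,
    n_ctrl: int = MODULE_N_CTRL,
    seed: int = 0,
) -> SignatureScore:
    """Bin-matched module score per cell.

    All genes are binned into ``n_bins`` equal-size bins of mean expression
    across cells; for each signature gene, ``n_ctrl`` control genes are
    drawn (seeded, without replacement) from its bin.  The per-cell score
    is mean signature expression minus mean control expression.
    """
    present = [g for g in dict.fromkeys(genes) if g in set(adata.var_names)]
    dropped = set(genes) - set(present)
    if dropped:
        warnings.warn(f"{len(dropped)} signature genes absent from the matrix; dropped")
    if not present:
        raise ValueError("no signature genes present in the matrix")
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    gene_means = pd.Series(X.mean(axis=0), index=adata.var_names)
    order = np.argsort(gene_means.to_numpy(), kind="mergesort")
    bins = np.empty(adata.n_vars, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    bin_of = pd.Series(bins, index=adata.var_names)
    rng = np.random.default_rng(seed)
    control: set[str] = set()
    for g in present:
        # lexicographic pool order makes the draw independent of gene order
        pool = sorted(bin_of.index[(bin_of == bin_of[g]).to_numpy()])
        pool = [p for p in pool if p != g]
        take = min(n_ctrl, len(pool))
        control.update(rng.choice(pool, size=take, replace=False)) if take else None
    if not control:
        raise ValueError("no control genes available")
    control_genes = sorted(control)
    col = {g: i for i, g in enumerate(adata.var_names)}
    sig_idx = [col[g] for g in present]
    ctrl_idx = [col[g] for g in control_genes]
    scores = X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return SignatureScore(
        genes=present,
        scores=pd.Series(scores, index=adata.obs_names, name="score"),
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        control_genes=control_genes,
    )


def cell_cycle_assign(
    adata: AnnData,
    s_genes: list[str],
    g2m_genes: list[str],
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """G1/S/G2M assignment from the two cycle module scores (max-score rule).

    A cell is G1 when both phase scores are negative, otherwise the
    higher-scoring phase wins.
    """
    s = module_score(adata, s_genes, seed=seed, **kwargs).scores
    g2m = module_score(adata, g2m_genes, seed=seed + 1, **kwargs).scores
    phase = np.where((s < 0) & (g2m < 0), "G1", np.where(s >= g2m, "S", "G2M"))
    return pd.DataFrame({"s_score": s, "g2m_score": g2m, "phase": phase}, index=adata.obs_names)


# ---------------------------------------------------------------------------
# cohort comparison


def cohort_compare(
    scores: pd.Series,
    tumour: pd.Series,
    condition: pd.Series,
    threshold: str = "pooled",
) -> dict:
    """High-scorer fractions and rank-sum comparison of per-tumour means.

    The high-score threshold is mean + 2 SD of the scored population
    (pooled across conditions by default; per-condition by flag).  The
    rank-sum p compares per-tumour mean scores between each condition pair
    (two-sided); a pair where either side has < 2 tumours is reported as
    undefined (NaN).
    """
    df = pd.DataFrame({"score": scores, "tumour": tumour, "condition": condition})
    out: dict = {"threshold_mode": threshold}
    sd = df["score"].std(ddof=1)
    if threshold == "pooled":
        thr = df["score"].mean() + 2.0 * sd if sd > 0 else np.inf
        df["high"] = df["score"] > thr if np.isfinite(thr) else False
        out["threshold"] = thr if np.isfinite(thr) else np.nan
    elif threshold == "per_condition":
        def _thr(g):
            s = g.std(ddof=1)
            return g.mean() + 2.0 * s if s > 0 else np.inf
        thresholds = df.groupby("condition", observed=True)["score"].transform(_thr)
        df["high"] = df["score"] > thresholds
        out["threshold"] = np.nan
    else:
        raise ValueError("threshold must be 'pooled' or 'per_condition'")
    out["high_fraction"] = (
        df.groupby("condition", observed=True)["high"].mean().to_dict()
    )
    tumour_means = (
        df.groupby(["condition", "tumour"], observed=True)["score"].mean().reset_index()
    )
    out["tumour_means"] = tumour_means
    conditions = sorted(df["condition"].unique())
    pvals = {}
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            xa = tumour_means.loc[tumour_means["condition"] == a, "score"]
            xb = tumour_means.loc[tumour_means["condition"] == b, "score"]
            if len(xa) < 2 or len(xb) < 2 or sd == 0:
                pvals[(a, b)] = np.nan
            else:
                pvals[(a, b)] = float(
                    stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
                )
    out["ranksum_p"] = pvals
    return out
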