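"""Cross-omic set logic: DE tables, methylation/expression concordance,
model capture fractions, subtype scoring, and semi-supervised clustering.

Differential tables ("DiffTables") are tidy frames with columns
``gene, effect, p, padj, contrast`` where ``effect`` is a log2 fold change
for expression or a methylation difference (Δβ / ΔM).  The capture
fraction quantifies how much of the true primary-vs-recurrence signal a
model contrast reproduces: |sig(model) ∩ sig(truth)| / |sig(truth)|,
optionally requiring matching effect signs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from scipy.cluster import hierarchy

from .cellstate import module_score

DIFF_COLUMNS = ("gene", "effect", "p", "padj", "contrast")
DEFAULT_ALPHA = 0.05
TOP_N_EXPR = 5000
TOP_N_METH = 10_000


def _check_diff(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("gene", "effect", "padj") if c not in df.columns]
    if missing:
        raise ValueError(f"DiffTable missing columns: {missing}")
    return df


def simple_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    contrast: str = "",
    cpm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Rank-sum differential expression between two groups of samples.

    ``counts`` is genes x samples (raw counts); ``groups`` labels each
    sample with one of exactly two levels.  Genes with < 1 count per
    million in *all* samples are removed first.  Samples are normalised by
    median-of-ratios size factors (robust to library-composition shifts
    from strongly regulated genes); effects are log2 fold changes of mean
    normalised counts (pseudocount 1), p-values are two-sided Mann-Whitney
    on normalised counts, BH-adjusted.
    """
    groups = pd.Series(groups, index=counts.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a, b = levels
    if (groups == a).sum() < 2 or (groups == b).sum() < 2:
        raise ValueError("need at least two samples per group")
    totals = counts.sum(axis=0)
    keep = (counts / totals * 1e6 >= cpm_threshold).any(axis=1)
    kept = counts.loc[keep].astype(float)
    positive = (kept > 0).all(axis=1)
    if positive.sum() >= 50:
        logref = np.log(kept.loc[positive]).mean(axis=1)
        sf = np.exp(np.log(kept.loc[positive]).sub(logref, axis=0).median(axis=0))
    else:  # too few always-expressed genes: fall back to total-count scaling
        sf = totals / totals.mean()
    norm = kept / sf
    xa = norm.loc[:, (groups == a).to_numpy()].to_numpy()
    xb = norm.loc[:, (groups == b).to_numpy()].to_numpy()
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(xb, xa, axis=1, alternative="two-sided", method="asymptotic")
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    effect = np.log2(xb.mean(axis=1) + 1.0) - np.log2(xa.mean(axis=1) + 1.0)
    padj = stats.false_discovery_control(p)
    return pd.DataFrame(
        {
            "gene": norm.index,
            "effect": effect,
            "p": p,
            "padj": padj,
            "contrast": contrast or f"{a}_vs_{b}",
        }
    ).reset_index(drop=True)


def concordant_genes(
    expr: pd.DataFrame, meth: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> dict[str, set]:
    """Concordantly regulated genes across expression and methylation.

    ``hypo_up``: significant in both omics, hypomethylated (effect < 0) and
    overexpressed (effect > 0); ``hyper_down``: the mirror image.  Returns
    both sets plus their union (the sets are disjoint by construction).
    """
    expr, meth = _check_diff(expr), _check_diff(meth)
    shared = set(expr["gene"]) & set(meth["gene"])
    if not shared:
        raise ValueError("expression and methylation tables share no genes")
    e = expr[expr["gene"].isin(shared)].set_index("gene")
    m = meth[meth["gene"].isin(shared)].set_index("gene")
    sig = (e["padj"] < alpha) & (m["padj"] < alpha)
    hypo_up = set(e.index[sig & (m["effect"] < 0) & (e["effect"] > 0)])
    hyper_down = set(e.index[sig & (m["effect"] > 0) & (e["effect"] < 0)])
    return {"hypo_up": hypo_up, "hyper_down": hyper_down, "union": hypo_up | hyper_down}


def aggregate_probes(meth_probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level methylation results to gene level.

    For each gene, the probe with the smallest adjusted p carries the
    gene-level effect.  Expects a ``gene`` column alongside the DiffTable
    columns (probe rows may repeat genes).
    """
    meth_probes = _check_diff(meth_probes)
    idx = meth_probes.groupby("gene")["padj"].idxmin()
    return meth_probes.loc[idx].reset_index(drop=True)


def capture_fraction(
    model: pd.DataFrame,
    truth: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    direction_matched: bool = True,
) -> dict:
    """Fraction of true significant changes reproduced by the model.

    fraction = |sig(model) ∩ sig(truth), same sign if requested| /
    |sig(truth)|.  Also emits Venn counts (model-only, shared, truth-only).
    Undefined (NaN) when the truth has no significant genes.
    """
    model, truth = _check_diff(model), _check_diff(truth)
    m = model[model["padj"] < alpha].set_index("gene")["effect"]
    t = truth[truth["padj"] < alpha].set_index("gene")["effect"]
    shared = set(m.index) & set(t.index)
    if direction_matched:
        shared = {g for g in shared if np.sign(m[g]) == np.sign(t[g])}
    n_truth = len(t)
    fraction = len(shared) / n_truth if n_truth else np.nan
    if not n_truth:
        warnings.warn("truth contrast has no significant genes; fraction undefined")
    return {
        "fraction": fraction,
        "shared": shared,
        "venn": {
            "model_only": len(set(m.index) - set(t.index)),
            "shared": len(shared),
            "truth_only": n_truth - len(set(m.index) & set(t.index)),
        },
        "n_truth_sig": n_truth,
        "n_model_sig": len(m),
    }


def subtype_scores(
    profiles: pd.DataFrame,
    signatures: dict[str, list[str]],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Signature scores per sample per subtype, with an argmax call.

    ``profiles`` is genes x samples (normalised pseudo-bulk).  Each subtype
    signature is scored with the bin-matched module score, treating samples
    as the scored units.  Ties at the argmax (e.g. an all-constant profile,
    where every score is 0) are reported as "tie".
    """
    adata = AnnData(
        X=profiles.to_numpy(dtype=float).T,
        obs=pd.DataFrame(index=profiles.columns.astype(str)),
        var=pd.DataFrame(index=profiles.index.astype(str)),
    )
    cols = {}
    for subtype, genes in sorted(signatures.items()):
        present = [g for g in genes if g in set(profiles.index)]
        coverage = len(present) / len(genes) if genes else 0.0
        if coverage < 1.0:
            warnings.warn(f"signature {subtype!r}: only {coverage:.0%} of genes present")
        cols[subtype] = module_score(adata, present, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed).scores
    out = pd.DataFrame(cols)
    arr = out.to_numpy()
    best = out.columns[arr.argmax(axis=1)]
    is_tie = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    out["call"] = np.where(is_tie, "tie", best)
    return out


def semisupervised_cluster(
    features: pd.DataFrame,
    top_n: int = TOP_N_EXPR,
    linkage_method: str = "complete",
    metric: str = "euclidean",
) -> dict:
    """Hierarchical clustering of samples on the most variable features.

    Selects the ``top_n`` features by standard deviation across samples
    (``features`` is features x samples), z-scores them, and clusters the
    samples (complete linkage, Euclidean distance).  Returns the selected
    features, linkage matrix and leaf order.
    """
    if features.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if top_n > len(features):
        warnings.warn(
            f"requested top {top_n} features but only {len(features)} available; using all"
        )
        top_n = len(features)
    sds = features.std(axis=1, ddof=1)
    order = sorted(zip(-sds.to_numpy(), sds.index))
    selected = [f for _, f in order[:top_n]]
    sub = features.loc[selected]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1).replace(0, 1.0)
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    Z = hierarchy.linkage(z.to_numpy().T, method=linkage_method, metric=metric)
    leaves = hierarchy.leaves_list(Z)
    return {
        "features": selected,
        "linkage": Z,
        "leaf_order": [features.columns[i] for i in leaves],
        "samples": list(features.columns),
    }


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
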