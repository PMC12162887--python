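"""Xenograft species deconvolution and single-cell QC.

PDX single-cell libraries contain contaminating murine cells.  Reads are
aligned to both the human (GRCh38) and mouse (Mm10) references and each
cell's species assignment is decided from the two aligned-read counts:

- per-cell: ``logfc_hs_mm = log2((human + pc) / (mouse + pc))`` with
  pseudocount ``pc = 1``; cells with logFC < 1 (less than a two-fold human
  excess) are excluded as contaminants, the boundary value 1 is kept;
- per-cluster: clusters whose mean per-cell (human+pc)/(mouse+pc) ratio is
  strictly below 3 are removed wholesale.

Quality filtering keeps cells with >= 500 detected genes, >= 1000 counts
and <= 20% mitochondrial counts; expression is then library-size corrected
to 10,000 counts per cell and log1p transformed (raw counts preserved in
``layers["counts"]``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

DEFAULT_PSEUDOCOUNT = 1.0
LOGFC_THRESHOLD = 1.0
CLUSTER_RATIO_THRESHOLD = 3.0
MIN_GENES = 500
MIN_COUNTS = 1000
MAX_PCT_MITO = 20.0
TARGET_SUM = 10_000.0
MITO_PREFIX = "MT-"


def species_score(
    cells: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Score cells by human/mouse aligned-read log ratio and flag keepers.

    ``cells`` must have columns ``counts_human`` and ``counts_mouse``.
    Adds ``logfc_hs_mm`` (log2 with pseudocount) and ``keep``
    (logFC >= 1; the boundary is kept).
    """
    for col in ("counts_human", "counts_mouse"):
        if col not in cells.columns:
            raise ValueError(f"missing column {col!r}")
        if cells[col].isna().any():
            raise ValueError(f"missing values in {col!r}")
        if (cells[col] < 0).any():
            raise ValueError(f"negative counts in {col!r}")
    out = cells.copy()
    out["logfc_hs_mm"] = np.log2(
        (out["counts_human"] + pseudocount) / (out["counts_mouse"] + pseudocount)
    )
    out["keep"] = out["logfc_hs_mm"] >= LOGFC_THRESHOLD
    return out


def cluster_species_filter(
    cells: pd.DataFrame,
    clusters: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = CLUSTER_RATIO_THRESHOLD,
) -> pd.DataFrame:
    """Remove whole clusters with mean human:mouse ratio below ``threshold``.

    The cluster statistic is the mean over member cells of
    ``(counts_human + pc) / (counts_mouse + pc)``; clusters with mean < 3
    are removed (boundary 3.0 retained).  Returns the surviving cells.
    """
    if clusters is None:
        if "cluster_id" not in cells.columns:
            raise ValueError("no cluster assignment provided")
        clusters = cells["cluster_id"]
    clusters = pd.Series(clusters, index=cells.index)
    if clusters.isna().any():
        raise ValueError("every cell must be assigned a cluster")
    ratio = (cells["counts_human"] + pseudocount) / (cells["counts_mouse"] + pseudocount)
    means = ratio.groupby(clusters).mean()
    for cl in means.index[means.isna()]:
        warnings.warn(f"cluster {cl!r} is empty; skipped")
    removed = set(means.index[means < threshold])
    return cells.loc[~clusters.isin(removed)].copy()


def _qc_metrics(adata: AnnData, mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    X = adata.layers.get("counts", adata.X)
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    n_counts = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    is_mito = adata.var_names.str.upper().str.startswith(mito_prefix.upper())
    mito_counts = np.asarray(X[:, is_mito].sum(axis=1)).ravel() if is_mito.any() else np.zeros(X.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_counts > 0, 100.0 * mito_counts / n_counts, 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes, "n_counts": n_counts, "pct_mito": pct_mito},
        index=adata.obs_names,
    )


def qc_filter(
    adata: AnnData,
    min_genes: int = MIN_GENES,
    min_counts: int = MIN_COUNTS,
    max_pct_mito: float = MAX_PCT_MITO,
    mito_prefix: str = MITO_PREFIX,
) -> tuple[AnnData, pd.DataFrame]:
    """Remove low-quality cells; report removals by criterion.

    Keeps cells with ``n_genes >= 500``, ``n_counts >= 1000`` and
    ``pct_mito <= 20`` (boundaries kept).  Returns the filtered AnnData
    (with QC fields in ``.obs``) and a one-row report of removal counts.
    """
    if "counts" not in adata.layers:
        adata = adata.copy()
        adata.layers["counts"] = adata.X.copy()
    qc = _qc_metrics(adata, mito_prefix=mito_prefix)
    fail_genes = qc["n_genes"] < min_genes
    fail_counts = qc["n_counts"] < min_counts
    fail_mito = qc["pct_mito"] > max_pct_mito
    keep = ~(fail_genes | fail_counts | fail_mito)
    if not keep.any():
        raise ValueError("QC filtering removed every cell")
    report = pd.DataFrame(
        {
            "n_input": [len(qc)],
            "removed_low_genes": [int(fail_genes.sum())],
            "removed_low_counts": [int(fail_counts.sum())],
            "removed_high_mito": [int(fail_mito.sum())],
            "n_kept": [int(keep.sum())],
        }
    )
    out = adata[keep.values].copy()
    out.obs = out.obs.drop(columns=qc.columns, errors="ignore").join(qc.loc[keep.values])
    return out, report


def normalize_log(adata: AnnData, target_sum: float = TARGET_SUM) -> AnnData:
    """Library-size correct each cell to ``target_sum`` counts, then log1p.

    Raw counts are preserved in ``layers["counts"]``; ``X`` becomes the
    normalised log layer and ``uns["normalized"]`` is set.
    """
    adata = adata.copy()
    if "counts" not in adata.layers:
        adata.layers["counts"] = adata.X.copy()
    X = adata.layers["counts"]
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr().copy()
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-count cell encountered; run qc_filter first")
    scaled = sp.diags(target_sum / totals) @ X
    scaled.data = np.log1p(scaled.data)
    adata.X = scaled.tocsr()
    adata.uns["normalized"] = {"target_sum": target_sum, "log1p": True}
    return adata
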