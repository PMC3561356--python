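"""Normalization and projection of expression matrices.

Microarray intensities are quantile normalized across samples and log2
transformed before any statistics are computed; multiple probes mapping
to the same gene are collapsed to the highest-mean probe; a 2-component
PCA of samples visualizes the global structure of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, LoadReport, ValidationError

__all__ = [
    "quantile_normalize",
    "log2_transform",
    "collapse_probes",
    "pca_project",
    "PCAResult",
]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto a common value distribution.

    The reference distribution is the row-wise mean of the per-column
    sorted values; each column's values are replaced by the reference
    value at their within-column rank.  Ties within a column receive the
    mean of the reference values over the tied rank span, so the map is
    well defined and rank order is preserved up to ties.
    """
    if m.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    X = m.values.to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    sorted_X = np.take_along_axis(X, order, axis=0)
    reference = sorted_X.mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = np.empty(X.shape[0])
        col[order[:, j]] = reference
        # average reference values over tied input values
        ties = pd.Series(col).groupby(pd.Series(X[:, j])).transform("mean")
        out[:, j] = ties.to_numpy()
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=df, scale=m.scale)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2; only valid on a raw-scale (positive) matrix."""
    if m.scale != "raw":
        raise ValidationError("matrix is already on the log2 scale")
    df = np.log2(m.values)
    return ExpressionMatrix(values=df, scale="log2")


def collapse_probes(
    m: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> tuple[ExpressionMatrix, LoadReport]:
    """Collapse probe rows to gene rows, keeping the highest-mean probe.

    Probes absent from the mapping are dropped.  When several probes map
    to one gene, the probe with the highest mean across samples is kept
    (ties broken by probe order), which keeps values on the original
    scale rather than averaging across probes of different brightness.
    """
    if not probe_to_gene:
        raise ValidationError("probe-to-gene mapping is empty")
    probes = [p for p in m.values.index if p in probe_to_gene]
    n_dropped = m.shape[0] - len(probes)
    sub = m.values.loc[probes]
    genes = pd.Series([probe_to_gene[p] for p in probes], index=sub.index)
    means = sub.mean(axis=1)
    # within each gene keep the probe with maximal mean (stable tie-break)
    best = (
        pd.DataFrame({"gene": genes, "mean": means})
        .reset_index(names="probe")
        .sort_values(["gene", "mean", "probe"], ascending=[True, False, True], kind="stable")
        .drop_duplicates(subset="gene", keep="first")
    )
    collapsed = sub.loc[best["probe"]]
    collapsed.index = pd.Index(best["gene"].tolist(), name="gene_id")
    collapsed = collapsed.sort_index()
    report = LoadReport(
        n_retained=collapsed.shape[0],
        n_dropped=n_dropped,
        details={"probes_in": m.shape[0], "genes_out": collapsed.shape[0]},
    )
    return ExpressionMatrix(values=collapsed, scale=m.scale), report


@dataclass
class PCAResult:
    """Per-sample component scores and explained-variance fractions."""

    scores: pd.DataFrame  # samples x components (PC1..PCn)
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x components


def pca_project(m: ExpressionMatrix, n_components: int = 2) -> PCAResult:
    """Project samples onto principal components of gene-space covariance.

    Rows (genes) are mean-centered across samples; no unit-variance
    scaling is applied.  The sign of each component is fixed so its gene
    loading vector has a non-negative sum (first-nonzero-positive when
    the sum is exactly zero), making scores deterministic.
    """
    if m.scale != "log2":
        raise ValidationError("PCA expects a log2-scale matrix")
    n_samples = m.shape[1]
    if n_components > n_samples:
        raise ValidationError(
            f"n_components={n_components} exceeds n_samples={n_samples}"
        )
    X = m.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    # SVD of the centered genes x samples matrix: columns of U are gene
    # loadings, rows of Vt scaled by singular values are sample scores.
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    U, S, Vt = U[:, :k], S[:k], Vt[:k, :]
    for i in range(k):
        total = U[:, i].sum()
        if total < 0 or (total == 0 and _first_nonzero_sign(U[:, i]) < 0):
            U[:, i] = -U[:, i]
            Vt[i, :] = -Vt[i, :]
    scores = (S[:, None] * Vt).T  # samples x components
    var_total = (Xc**2).sum()
    with np.errstate(invalid="ignore"):
        evr = (S**2) / var_total if var_total > 0 else np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.values.columns, columns=comp_names),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(U, index=m.values.index, columns=comp_names),
    )


def _first_nonzero_sign(v: np.ndarray) -> float:
    nz = v[v != 0]
    return float(np.sign(nz[0])) if nz.size else 1.0
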