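"""Binary chromatin-accessibility featurization: TF-IDF and LSI.

A single-cell ATAC experiment is summarized as a binary cell x window matrix
(500-bp genomic windows, 1 = the window is covered by at least one read in
that cell).  The term-frequency / inverse-document-frequency transform

    TFIDF_ij = (X_ij / sum_j X_ij) * ln( N / (1 + sum_i X_ij) )

normalizes each cell by its total number of open windows (TF) and
downweights windows open in many cells while upweighting rare informative
ones (IDF); note the +1 in the denominator makes truly ubiquitous windows
slightly negative rather than zero.  Latent semantic indexing (LSI) is the
rank-d truncated SVD of the TF-IDF matrix, with cells embedded as the left
singular vectors scaled by the singular values; the first 30 components are
the conventional input for downstream archetypal analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

__all__ = ["LsiEmbedding", "tfidf", "lsi"]


@dataclass
class LsiEmbedding:
    """Cells x components LSI embedding with its singular values."""

    components: np.ndarray  # (N, d) = U * S
    singular_values: np.ndarray  # (d,), non-increasing
    provenance: dict = field(default_factory=dict)


def tfidf(
    X: np.ndarray | sp.spmatrix,
    on_zero_cells: str = "error",
) -> np.ndarray:
    """TF-IDF transform of a binary accessibility matrix.

    Evaluates the formula above elementwise with the natural logarithm.
    Columns never open in any cell come out all zero (the TF factor is zero
    there).  Cells with no open window have an undefined TF; by default they
    raise, with ``on_zero_cells="drop"`` they are removed with a warning
    (such cells are upstream QC failures).
    """
    dense = X.toarray() if sp.issparse(X) else np.asarray(X)
    if not np.isin(dense, (0, 1)).all():
        raise ValueError("accessibility matrix must be binary")
    dense = dense.astype(float)
    row_sums = dense.sum(axis=1)
    if (row_sums == 0).any():
        if on_zero_cells == "drop":
            import warnings

            warnings.warn(
                f"dropping {int((row_sums == 0).sum())} cells with zero coverage"
            )
            dense = dense[row_sums > 0]
            row_sums = row_sums[row_sums > 0]
        else:
            raise ValueError("cells with zero open windows; fix QC or pass "
                             "on_zero_cells='drop'")
    N = dense.shape[0]
    col_sums = dense.sum(axis=0)
    tf = dense / row_sums[:, None]
    idf = np.log(N / (1.0 + col_sums))
    return tf * idf[None, :]


def lsi(T: np.ndarray, d: int = 30, seed: int = 0) -> LsiEmbedding:
    """Latent semantic indexing: rank-d truncated SVD of the TF-IDF matrix.

    Returns cells embedded as ``U[:, :d] * S[:d]`` with singular values in
    non-increasing order.  Component signs are fixed deterministically (the
    largest-magnitude loading of each right singular vector is made
    positive), so the embedding is reproducible up to exact arithmetic.
    """
    T = np.asarray(T, dtype=float)
    N, P = T.shape
    if d < 1:
        raise ValueError("d must be at least 1")
    if d > min(N, P):
        raise ValueError(f"d={d} exceeds min(N, P)={min(N, P)}")
    if d < min(N, P):
        rng = np.random.default_rng(seed)
        v0 = rng.normal(size=min(N, P))
        U, S, Vt = svds(T, k=d, v0=v0)
        order = np.argsort(S)[::-1]
        U, S, Vt = U[:, order], S[order], Vt[order]
    else:
        U, S, Vt = np.linalg.svd(T, full_matrices=False)
        U, S, Vt = U[:, :d], S[:d], Vt[:d]
    # deterministic sign convention
    flip = np.sign(Vt[np.arange(d), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip[None, :]
    return LsiEmbedding(
        components=U * S[None, :],
        singular_values=S,
        provenance={"d": d, "n_cells": N, "n_windows": P, "seed": seed},
    )
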