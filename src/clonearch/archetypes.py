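"""Classical and deep archetypal analysis of single-cell feature matrices.

Archetypal analysis (AA) embeds each cell's feature profile as a convex
combination of K extreme profiles (archetypes) that are themselves convex
combinations of cells:

    X  ~  A @ Z,      Z = B @ X,

with A (N x K) and B (K x N) row-stochastic.  The classical fit alternates
exact simplex-constrained least-squares updates of A and B; the deep variant
learns A and B with a feedforward encoder whose latent space is a fixed
standard simplex with K vertices, trained by mini-batch gradient descent on

    || X - dec(A Z*) ||^2  +  || Z* - B A Z* ||^2 .

The module also carries the preprocessing used around AA in barcoded organoid
experiments: per-phase highly-variable-gene intersection with Z-scoring, cell
quality-control filters, out-of-sample projection, and per-group archetype
weight summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls

from ._autodiff import Adam, Tensor

__all__ = [
    "FeatureMatrix",
    "ArchetypeModel",
    "DeepAANetwork",
    "TrainingDivergedError",
    "select_features",
    "fit_archetypes_classical",
    "fit_archetypes_deep",
    "project_onto_archetypes",
    "archetype_group_means",
    "qc_filter_cells",
]


class TrainingDivergedError(RuntimeError):
    """The deep fit produced a non-finite loss."""


@dataclass
class FeatureMatrix:
    """Z-scored cells x features matrix with selection provenance."""

    values: np.ndarray
    feature_names: list[str]
    cell_ids: list[str]
    selection_provenance: dict = field(default_factory=dict)


@dataclass
class ArchetypeModel:
    """Fitted archetype decomposition.

    ``A`` (N x K) gives each cell's convex archetype weights, ``B`` (K x N)
    gives each archetype as a convex combination of cells, and ``Z`` (K x M)
    holds the archetype feature profiles (``Z = B @ X`` for the classical
    variant, decoded simplex vertices for the deep one).
    """

    K: int
    A: np.ndarray
    B: np.ndarray
    Z: np.ndarray
    loss: float
    variant: str
    fit_metadata: dict = field(default_factory=dict)
    feature_names: list[str] | None = None
    network: "DeepAANetwork | None" = None


# ---------------------------------------------------------------------------
# preprocessing


def select_features(
    matrices: Mapping[str, np.ndarray],
    top_counts: Mapping[str, int],
    gene_names: Sequence[str],
    cell_ids: Mapping[str, Sequence[str]] | None = None,
) -> FeatureMatrix:
    """Intersect per-phase most-variable genes and Z-score the result.

    ``matrices`` maps phase name to a (cells x genes) normalized-expression
    matrix over a shared gene universe; ``top_counts`` maps each phase to the
    number of top-variance genes to retain there (e.g. 2000 under drug, 1000
    in regrowth, 500 in the parental sample).  The retained features are the
    intersection of the per-phase sets; cells from all phases are stacked and
    each retained gene is Z-scored across all of them.
    """
    gene_names = list(gene_names)
    phases = list(matrices)
    if set(top_counts) != set(phases):
        raise ValueError("top_counts must provide one entry per phase")
    top_sets: dict[str, set[str]] = {}
    for phase in phases:
        M = np.asarray(matrices[phase], dtype=float)
        if M.shape[1] != len(gene_names):
            raise ValueError(f"phase {phase!r} matrix has wrong gene dimension")
        var = M.var(axis=0)
        order = np.argsort(var, kind="stable")[::-1]
        top_sets[phase] = {gene_names[i] for i in order[: top_counts[phase]]}
    kept = set.intersection(*top_sets.values())
    if not kept:
        raise ValueError(
            "empty intersection of per-phase variable genes; increase top_counts"
        )
    kept_idx = [i for i, g in enumerate(gene_names) if g in kept]
    kept_names = [gene_names[i] for i in kept_idx]

    blocks, ids = [], []
    for phase in phases:
        M = np.asarray(matrices[phase], dtype=float)[:, kept_idx]
        blocks.append(M)
        if cell_ids is not None:
            ids.extend(cell_ids[phase])
        else:
            ids.extend(f"{phase}:{i}" for i in range(M.shape[0]))
    X = np.vstack(blocks)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    provenance = {
        "per_phase_top_counts": dict(top_counts),
        "per_phase_set_sizes": {p: len(s) for p, s in top_sets.items()},
        "intersection_size": len(kept),
    }
    return FeatureMatrix(X, kept_names, ids, provenance)


def qc_filter_cells(
    counts: np.ndarray | sp.spmatrix,
    gene_names: Sequence[str],
    mito_fraction_max: float = 0.30,
    min_genes: int = 1000,
    mito_genes: Sequence[str] | None = None,
    mito_prefix: str = "MT-",
    doublet_flags: Sequence[bool] | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Remove low-quality cells from a raw count matrix.

    Cells with a mitochondrial read fraction strictly greater than
    ``mito_fraction_max`` (dying cells) or strictly fewer than ``min_genes``
    expressed genes are removed; both boundaries are retained.  Mitochondrial
    genes are given explicitly or identified by feature-name prefix.  A
    precomputed boolean doublet flag column may also be supplied.  Returns the
    filtered matrix, the boolean keep mask, and a per-criterion report.
    """
    X = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    gene_names = list(gene_names)
    if mito_genes is not None:
        mito_idx = [i for i, g in enumerate(gene_names) if g in set(mito_genes)]
    else:
        mito_idx = [i for i, g in enumerate(gene_names) if g.startswith(mito_prefix)]
    if not mito_idx and mito_fraction_max is not None:
        raise ValueError(
            f"no mitochondrial genes identifiable (prefix {mito_prefix!r}); "
            "pass mito_genes or disable the filter with mito_fraction_max=None"
        )
    totals = X.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, X[:, mito_idx].sum(axis=1) / totals, 0.0)
    n_genes = (X > 0).sum(axis=1)

    fail_mito = (
        mito_frac > mito_fraction_max
        if mito_fraction_max is not None
        else np.zeros(X.shape[0], dtype=bool)
    )
    fail_genes = n_genes < min_genes
    fail_doublet = (
        np.asarray(doublet_flags, dtype=bool)
        if doublet_flags is not None
        else np.zeros(X.shape[0], dtype=bool)
    )
    keep = ~(fail_mito | fail_genes | fail_doublet)
    report = {
        "n_input": int(X.shape[0]),
        "n_removed_mito": int(fail_mito.sum()),
        "n_removed_min_genes": int(fail_genes.sum()),
        "n_removed_doublet": int(fail_doublet.sum()),
        "n_kept": int(keep.sum()),
    }
    return X[keep], keep, report


# ---------------------------------------------------------------------------
# classical fit


def _simplex_lstsq(D: np.ndarray, y: np.ndarray, penalty: float = 200.0) -> np.ndarray:
    """argmin ||D w - y|| subject to w >= 0, sum(w) = 1.

    Solved as nonnegative least squares with a heavily weighted sum-to-one
    row, then renormalized; the penalty makes the constraint violation of
    order 1/penalty^2 before renormalization.
    """
    k = D.shape[1]
    scale = penalty * max(1.0, float(np.abs(y).max()))
    D_aug = np.vstack([D, np.full((1, k), scale)])
    y_aug = np.concatenate([y, [scale]])
    w, _ = nnls(D_aug, y_aug)
    s = w.sum()
    if s <= 0:
        w = np.full(k, 1.0 / k)
    else:
        w = w / s
    return w


def _furthest_sum_init(X: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Greedy furthest-sum selection of K well-spread cells as seed vertices."""
    rng = np.random.default_rng(seed)
    N = X.shape[0]
    first = int(rng.integers(N))
    chosen = [first]
    dist_sum = np.linalg.norm(X - X[first], axis=1)
    for _ in range(1, K):
        dist_sum[chosen] = -np.inf
        nxt = int(np.argmax(dist_sum))
        chosen.append(nxt)
        d = np.linalg.norm(X - X[nxt], axis=1)
        dist_sum = np.where(np.isinf(dist_sum), dist_sum, dist_sum + d)
    return np.array(chosen)


def _aa_loss(X: np.ndarray, A: np.ndarray, Z: np.ndarray) -> float:
    return float(np.sum((X - A @ Z) ** 2))


def fit_archetypes_classical(
    X: np.ndarray | FeatureMatrix,
    K: int,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
) -> ArchetypeModel:
    """Archetypal analysis by alternating simplex-constrained least squares.

    Each iteration first updates every row of A (cell weights, exact
    per-row constrained least squares against the current archetypes) and then
    each row of B by exact block-coordinate minimization of the full objective
    ``||X - A B X||_F^2``, so the objective is non-increasing across
    iterations.  Initialization places archetypes on furthest-sum-selected
    cells.  Stops when the relative improvement drops below ``tol``.
    """
    feature_names = None
    if isinstance(X, FeatureMatrix):
        feature_names = X.feature_names
        X = X.values
    X = np.asarray(X, dtype=float)
    N, M = X.shape
    if not 1 <= K <= N:
        raise ValueError(f"K must be in [1, {N}]")

    B = np.zeros((K, N))
    B[np.arange(K), _furthest_sum_init(X, K, seed)] = 1.0
    Z = B @ X
    A = np.full((N, K), 1.0 / K)

    history: list[float] = []
    prev: float | None = None
    for it in range(max_iter):
        # A-step: per-cell simplex least squares against fixed Z
        Dt = Z.T  # (M, K)
        A_new = np.empty_like(A)
        for i in range(N):
            A_new[i] = _simplex_lstsq(Dt, X[i])
        A_cand = A_new
        if _aa_loss(X, A_cand, Z) <= _aa_loss(X, A, Z):
            A = A_cand

        # B-step: exact block-coordinate update of each archetype row
        AZ = A @ Z
        for k in range(K):
            a_k = A[:, k]
            d = float(a_k @ a_k)
            if d < 1e-12:
                continue  # archetype currently unused; leave its row as is
            R = X - AZ + np.outer(a_k, Z[k])
            y = R.T @ a_k / d
            w = _simplex_lstsq(X.T, y)
            z_new = w @ X
            # accept only if the global objective does not increase
            old_term = _aa_loss(X, A, Z)
            Z_try = Z.copy()
            Z_try[k] = z_new
            if _aa_loss(X, A, Z_try) <= old_term:
                B[k] = w
                Z = Z_try
                AZ = A @ Z

        loss = _aa_loss(X, A, Z)
        history.append(loss)
        if prev is not None and prev - loss <= tol * max(prev, 1e-30):
            break
        prev = loss

    return ArchetypeModel(
        K=K, A=A, B=B, Z=Z, loss=history[-1], variant="classical",
        fit_metadata={"iterations": len(history), "seed": seed,
                      "loss_history": history, "tol": tol},
        feature_names=list(feature_names) if feature_names else None,
    )


# ---------------------------------------------------------------------------
# deep fit


class DeepAANetwork:
    """Encoder/decoder pair for deep archetypal analysis.

    A shared two-hidden-layer trunk feeds two softmax heads: the A head
    (softmax over archetypes per cell) and the B head (softmax over the cells
    of the batch per archetype).  The latent simplex Z* is fixed to the
    standard simplex (identity vertices), so the latent code of a cell is its
    A row and archetype profiles are the decoded simplex vertices.
    """

    def __init__(self, n_features: int, K: int,
                 hidden_sizes: Sequence[int] = (128, 128), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.K = K
        self.n_features = n_features
        sizes = [n_features, *hidden_sizes]
        self.params: list[Tensor] = []

        def lin(n_in: int, n_out: int) -> tuple[Tensor, Tensor]:
            W = Tensor(rng.normal(0, np.sqrt(1.0 / n_in), (n_in, n_out)),
                       requires_grad=True)
            b = Tensor(np.zeros((1, n_out)), requires_grad=True)
            self.params += [W, b]
            return W, b

        self.enc = [lin(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.head_a = lin(sizes[-1], K)
        self.head_b = lin(sizes[-1], K)
        dec_sizes = [K, *reversed(hidden_sizes), n_features]
        self.dec = [lin(dec_sizes[i], dec_sizes[i + 1])
                    for i in range(len(dec_sizes) - 1)]

    def _trunk(self, X: Tensor) -> Tensor:
        h = X
        for W, b in self.enc:
            h = (h @ W + b).tanh()
        return h

    def encode(self, X: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (A, B): A is (n x K) rows on the simplex, B is (K x n)."""
        h = self._trunk(X)
        Wa, ba = self.head_a
        Wb, bb = self.head_b
        A = (h @ Wa + ba).softmax(axis=1)
        B = (h @ Wb + bb).softmax(axis=0).transpose()
        return A, B

    def decode(self, latent: Tensor) -> Tensor:
        h = latent
        for i, (W, b) in enumerate(self.dec):
            h = h @ W + b
            if i < len(self.dec) - 1:
                h = h.tanh()
        return h

    # -- numpy-level inference helpers -------------------------------------

    def encode_A(self, X: np.ndarray) -> np.ndarray:
        A, _ = self.encode(Tensor(X))
        return A.value

    def archetype_profiles(self) -> np.ndarray:
        return self.decode(Tensor(np.eye(self.K))).value


def fit_archetypes_deep(
    X: np.ndarray | FeatureMatrix,
    K: int,
    hidden_sizes: Sequence[int] = (128, 128),
    epochs: int = 2000,
    batch_size: int | None = None,
    learning_rate: float = 5e-3,
    seed: int = 0,
    n_restarts: int = 3,
    restart_loss_ratio: float = 1e-4,
) -> ArchetypeModel:
    """Deep archetypal analysis with a fixed latent simplex.

    The encoder produces row-stochastic A (cells over archetypes) and B
    (archetypes over cells); the decoder reconstructs X from A Z* with Z* the
    standard K-simplex.  The loss is the sum of the mean-squared
    reconstruction error and the mean-squared archetype-consistency penalty
    ``||Z* - B A Z*||^2`` (with Z* the identity, ``||I - B A|^2``), averaged
    per element and summed with unit weights.  Mini-batches are supported;
    B is recomputed on the full data after training.

    Training is non-convex and can settle in an archetype-collapsed local
    minimum, so up to ``n_restarts`` seeded runs are made and the one with
    the lowest final loss kept; a run whose final loss falls below
    ``restart_loss_ratio`` of its initial loss is accepted immediately.
    Fully deterministic for a given ``seed``.
    """
    feature_names = None
    if isinstance(X, FeatureMatrix):
        feature_names = X.feature_names
        X = X.values
    X = np.asarray(X, dtype=float)
    N, M = X.shape
    if not 1 <= K <= N:
        raise ValueError(f"K must be in [1, {N}]")
    if batch_size is None or batch_size > N:
        batch_size = N

    best: ArchetypeModel | None = None
    for restart in range(max(1, n_restarts)):
        model = _fit_deep_once(
            X, K, hidden_sizes, epochs, batch_size, learning_rate,
            seed=int(np.random.SeedSequence([seed, restart]).generate_state(1)[0]
                     % (2**31 - 1)),
        )
        model.fit_metadata["seed"] = seed
        model.fit_metadata["restart"] = restart
        if best is None or model.loss < best.loss:
            best = model
        if model.loss <= restart_loss_ratio * model.fit_metadata["initial_loss"]:
            break
    assert best is not None
    best.feature_names = list(feature_names) if feature_names else None
    return best


def _fit_deep_once(
    X: np.ndarray,
    K: int,
    hidden_sizes: Sequence[int],
    epochs: int,
    batch_size: int,
    learning_rate: float,
    seed: int,
) -> ArchetypeModel:
    N, M = X.shape
    rng = np.random.default_rng(seed)
    net = DeepAANetwork(M, K, hidden_sizes, seed=seed)
    opt = Adam(net.params, lr=learning_rate)
    eye = np.eye(K)

    first_loss = None
    loss = np.nan
    for epoch in range(epochs):
        order = rng.permutation(N)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, N, batch_size):
            idx = order[start : start + batch_size]
            xb = Tensor(X[idx])
            A, B = net.encode(xb)
            recon = net.decode(A)  # A @ Z* with Z* = I is A itself
            consistency = (B @ A).mse(eye)
            total = recon.mse(X[idx]) + consistency
            if not np.isfinite(total.value):
                raise TrainingDivergedError(
                    f"loss diverged at epoch {epoch} (learning_rate={learning_rate})"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_loss += float(total.value)
            n_batches += 1
        loss = epoch_loss / n_batches
        if first_loss is None:
            first_loss = loss

    A_full = net.encode_A(X)
    B_full = net.encode(Tensor(X))[1].value
    Z = net.archetype_profiles()
    return ArchetypeModel(
        K=K, A=A_full, B=B_full, Z=Z, loss=float(loss), variant="deep",
        fit_metadata={"epochs": epochs, "seed": seed, "initial_loss": first_loss,
                      "learning_rate": learning_rate, "batch_size": batch_size,
                      "hidden_sizes": list(hidden_sizes)},
        network=net,
    )


# ---------------------------------------------------------------------------
# projection and summaries


def project_onto_archetypes(
    model: ArchetypeModel,
    X_new: np.ndarray | pd.DataFrame,
) -> np.ndarray:
    """Archetype weights for new cells under a fitted model.

    Classical models solve the per-row simplex least-squares problem against
    the fixed archetypes; deep models run the encoder forward.  When the model
    records feature names and ``X_new`` is a DataFrame, columns are aligned
    and missing features raise an error listing them.
    """
    if isinstance(X_new, pd.DataFrame):
        if model.feature_names is not None:
            missing = [f for f in model.feature_names if f not in X_new.columns]
            if missing:
                raise ValueError(f"missing features: {missing}")
            X_new = X_new[model.feature_names].to_numpy(dtype=float)
        else:
            X_new = X_new.to_numpy(dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.Z.shape[1]:
        raise ValueError(
            f"feature mismatch: model has {model.Z.shape[1]} features, "
            f"input has {X_new.shape[1]}"
        )
    if model.variant == "deep":
        assert model.network is not None
        return model.network.encode_A(X_new)
    Dt = model.Z.T
    return np.vstack([_simplex_lstsq(Dt, x) for x in X_new])


def archetype_group_means(
    A: np.ndarray,
    grouping: Sequence,
) -> pd.DataFrame:
    """Mean archetype weight per group of cells (rows sum to one).

    ``grouping`` assigns one label per cell (row of A); cells labeled None or
    NaN are treated as unassigned and skipped.  Groups that end up empty are
    omitted with a warning.
    """
    A = np.asarray(A, dtype=float)
    labels = pd.Series(list(grouping))
    if len(labels) != A.shape[0]:
        raise ValueError("grouping must provide one label per cell")
    valid = labels.notna()
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} unassigned cells skipped")
    out = {}
    for label, idx in labels[valid].groupby(labels[valid]).groups.items():
        rows = A[np.asarray(idx)]
        if rows.shape[0] == 0:  # pragma: no cover - groupby never yields empties
            warnings.warn(f"group {label!r} is empty; omitted")
            continue
        out[label] = rows.mean(axis=0)
    df = pd.DataFrame.from_dict(out, orient="index",
                                columns=[f"archetype_{k + 1}" for k in range(A.shape[1])])
    df.index.name = "group"
    return df
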