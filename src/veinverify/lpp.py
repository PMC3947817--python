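"""Locality preserving projections (LPP).

LPP finds a linear map that keeps nearby training samples nearby in the
embedding.  A neighbourhood graph over the m training vectors (kNN with
OR-symmetrization, or an epsilon ball) is weighted either uniformly or by
the heat kernel W_ij = exp(-||x_i - x_j||^2 / t).  With D the diagonal
degree matrix (D_ii = sum_j W_ji) and L = D - W the graph Laplacian, the
projection directions a solve the generalized eigenproblem

    X L X^T a = lambda X D X^T a

and the l eigenvectors of smallest eigenvalue form the map
y = A^T x.  As in the Laplacianfaces lineage, a PCA pre-projection keeps
X D X^T nonsingular; the composite map (centering, PCA, then A) is what
:meth:`LPPModel.transform` applies to new samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.metrics import pairwise_distances

__all__ = ["LPPConfig", "LPPModel", "build_graph", "fit", "transform"]


@dataclass(frozen=True)
class LPPConfig:
    """Graph, weight and embedding settings for LPP.

    t="auto" uses the mean squared pairwise training distance, a
    scale-free default for the heat kernel.
    """

    graph: str = "knn"              # knn | epsilon
    k: int = 5
    epsilon: float | None = None
    weight: str = "heat"            # heat | simple
    t: float | str = "auto"
    out_dim: int | None = None      # default min(100, m - 1), capped by rank
    pca_keep: float = 0.98          # fraction of variance kept by the pre-projection

    def __post_init__(self) -> None:
        if self.graph not in ("knn", "epsilon"):
            raise ValueError("graph must be 'knn' or 'epsilon'")
        if self.weight not in ("heat", "simple"):
            raise ValueError("weight must be 'heat' or 'simple'")
        if self.graph == "knn" and self.k < 1:
            raise ValueError("k must be positive")
        if self.graph == "epsilon" and (self.epsilon is None or self.epsilon <= 0):
            raise ValueError("epsilon graph needs a positive epsilon")
        if not 0 < self.pca_keep <= 1:
            raise ValueError("pca_keep must lie in (0, 1]")


def build_graph(X: np.ndarray, cfg: LPPConfig) -> np.ndarray:
    """Symmetric edge-weight matrix W over the rows of X.

    kNN rule: i and j are connected if i is among the k nearest
    neighbours of j OR j among the k nearest of i.  Epsilon rule:
    connected iff ||x_i - x_j||^2 < epsilon.  Heat weights are
    exp(-||x_i - x_j||^2 / t); simple weights are 1.  Zero diagonal.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples")
    d2 = pairwise_distances(X, metric="sqeuclidean")

    if cfg.graph == "knn":
        if cfg.k >= m:
            raise ValueError(f"k = {cfg.k} must be < number of samples {m}")
        nn = NearestNeighbors(n_neighbors=cfg.k).fit(X)
        idx = nn.kneighbors(return_distance=False)  # self is excluded by sklearn
        adj = np.zeros((m, m), dtype=bool)
        rows = np.repeat(np.arange(m), idx.shape[1])
        adj[rows, idx.ravel()] = True
        adj |= adj.T
    else:
        adj = d2 < cfg.epsilon
        np.fill_diagonal(adj, False)

    if cfg.weight == "simple":
        W = adj.astype(float)
    else:
        t = float(np.mean(d2)) if cfg.t == "auto" else float(cfg.t)
        if t <= 0:
            t = 1.0
        W = np.where(adj, np.exp(-d2 / t), 0.0)
    np.fill_diagonal(W, 0.0)
    return W


@dataclass
class LPPModel:
    """Fitted LPP: centering + PCA pre-projection followed by A.

    Columns of A are generalized eigenvectors ordered by ascending
    eigenvalue, each with its largest-magnitude entry made positive so the
    serialization is reproducible.
    """

    center: np.ndarray              # training mean in input space
    pre: np.ndarray                 # (n_input, n_pre) PCA components
    A: np.ndarray                   # (n_pre, l) eigenvectors
    eigenvalues: np.ndarray         # (l,) ascending
    config: LPPConfig
    n_graph_components: int = 1

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Embed one vector or a (samples, dims) matrix: y = A^T P^T (x - mu)."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.center.shape[0]:
            raise ValueError(f"dimension mismatch: {x.shape[-1]} vs {self.center.shape[0]}")
        return (x - self.center) @ self.pre @ self.A

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "config": {k: getattr(self.config, k) for k in
                       ("graph", "k", "epsilon", "weight", "t", "out_dim", "pca_keep")},
            "n_graph_components": self.n_graph_components,
            "center": self.center.tolist(),
            "pre": self.pre.tolist(),
            "A": self.A.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
        }
        path.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "LPPModel":
        d = json.loads(Path(path).read_text())
        return cls(center=np.array(d["center"]), pre=np.array(d["pre"]),
                   A=np.array(d["A"]), eigenvalues=np.array(d["eigenvalues"]),
                   config=LPPConfig(**d["config"]),
                   n_graph_components=d["n_graph_components"])


def _fix_signs(A: np.ndarray) -> np.ndarray:
    idx = np.abs(A).argmax(axis=0)
    signs = np.sign(A[idx, np.arange(A.shape[1])])
    signs[signs == 0] = 1.0
    return A * signs


def fit(X_train: np.ndarray, cfg: LPPConfig = LPPConfig()) -> LPPModel:
    """Fit LPP on the rows of X_train.

    Raises a numerical error with guidance if the right-hand matrix is
    singular after the PCA pre-projection (lower out_dim or pca_keep).
    """
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X_train must be a (samples >= 2, dims) matrix")
    m = X.shape[0]

    center = X.mean(axis=0)
    n_comp = cfg.pca_keep if cfg.pca_keep < 1 else min(m - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full").fit(X)
    # drop numerically null directions to keep X D X^T well conditioned
    keep = pca.explained_variance_ > 1e-12 * max(pca.explained_variance_[0], 1e-300)
    pre = pca.components_[keep].T                      # (n_input, n_pre)
    Z = (X - center) @ pre                             # (m, n_pre)
    n_pre = Z.shape[1]

    W = build_graph(Z, cfg)
    n_comp_graph, _ = connected_components((W > 0).astype(int), directed=False)
    if n_comp_graph > 1:
        warnings.warn(f"neighbourhood graph has {n_comp_graph} connected components")

    d = W.sum(axis=0)
    D = np.diag(d)
    L = D - W
    Xt = Z.T                                           # (n_pre, m)
    lhs = Xt @ L @ Xt.T
    rhs = Xt @ D @ Xt.T
    lhs = (lhs + lhs.T) / 2
    rhs = (rhs + rhs.T) / 2
    try:
        evals, evecs = scipy.linalg.eigh(lhs, rhs)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "generalized eigenproblem is singular after pre-projection; "
            "lower out_dim or pca_keep"
        ) from exc

    l = cfg.out_dim if cfg.out_dim is not None else min(100, m - 1)
    l = min(l, n_pre)
    A = _fix_signs(evecs[:, :l])
    return LPPModel(center=center, pre=pre, A=A, eigenvalues=evals[:l],
                    config=cfg, n_graph_components=n_comp_graph)


def transform(model: LPPModel, x: np.ndarray) -> np.ndarray:
    """Functional alias of :meth:`LPPModel.transform`."""
    return model.transform(x)
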