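"""Nonmetric 3D multidimensional scaling of population distance matrices.

Initialises with classical (Torgerson) scaling, then minimises stress by
SMACOF with monotone (isotonic) regression on the dissimilarity ranks.
Diagnostics follow Kruskal: stress-1 = sqrt(Σ(d̂ - disparity)² / Σ d̂²) and
RSQ = squared Pearson correlation between disparities and configuration
distances.  Stress-1 is scale-invariant, so the absolute scale of the input
matrix does not matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .errors import DegenerateDataError


@dataclass
class MdsResult:
    labels: list[str]
    coordinates: np.ndarray
    stress: float
    rsq: float
    n_iterations: int
    converged: bool

    def coords_tsv(self) -> str:
        dims = self.coordinates.shape[1]
        lines = ["population\t" + "\t".join(f"dim{i+1}" for i in range(dims))]
        for lab, row in zip(self.labels, self.coordinates):
            lines.append(lab + "\t" + "\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def classical_scaling(D: np.ndarray, n_dim: int = 3) -> np.ndarray:
    """Torgerson principal-coordinates embedding of a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][: min(n_dim, n)]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0.0, None)
    X = V * np.sqrt(w)
    if X.shape[1] < n_dim:
        X = np.hstack([X, np.zeros((n, n_dim - X.shape[1]))])
    return X


def _diagnostics(D: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    iu = np.triu_indices(D.shape[0], 1)
    diss = D[iu]
    dhat = squareform(np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)), checks=False)
    denom = float((dhat**2).sum())
    if denom == 0.0:
        return 0.0, 1.0
    disp = IsotonicRegression().fit_transform(diss, dhat)
    stress = math.sqrt(float(((dhat - disp) ** 2).sum()) / denom)
    sd_disp, sd_dhat = disp.std(), dhat.std()
    if sd_disp == 0.0 or sd_dhat == 0.0:
        rsq = 1.0 if stress < 1e-12 else 0.0
    else:
        rsq = float(np.corrcoef(disp, dhat)[0, 1] ** 2)
    return stress, rsq


def nmds3(
    D: np.ndarray,
    labels: list[str] | None = None,
    n_dim: int = 3,
    n_restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int | None = None,
    method: str = "nmds",
) -> MdsResult:
    """Nonmetric MDS of a symmetric zero-diagonal distance matrix.

    Restart 0 starts from the classical-scaling configuration; the remaining
    ``n_restarts - 1`` use random starts.  The configuration with the lowest
    Kruskal stress-1 is returned, column-centred.  ``method='classical'``
    skips the iterative stage and returns the Torgerson embedding.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if not D[np.triu_indices(n, 1)].any():
        raise DegenerateDataError("all distances are zero")
    labels = labels if labels is not None else [str(i) for i in range(n)]

    # two points embed exactly; the iterative stage has nothing to optimise
    if method == "classical" or n == 2:
        X = classical_scaling(D, n_dim)
        X -= X.mean(axis=0)
        stress, rsq = _diagnostics(D, X)
        return MdsResult(labels, X, stress, rsq, 0, True)

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        init = classical_scaling(D, n_dim) if r == 0 else None
        X, _, n_iter = smacof(
            D,
            metric=False,
            n_components=n_dim,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=False,
            return_n_iter=True,
        )
        stress, rsq = _diagnostics(D, X)
        if best is None or stress < best[0]:
            best = (stress, rsq, X, n_iter)
    stress, rsq, X, n_iter = best
    X = X - X.mean(axis=0)
    return MdsResult(labels, X, stress, rsq, int(n_iter), n_iter < max_iter)


def cluster_readout(result: MdsResult, k: int = 3) -> dict[str, int]:
    """Complete-linkage k-group partition of the embedded coordinates.

    A diagnostic convenience for reading grouped structure off the ordination;
    returns population -> 1-based cluster id.
    """
    n = len(result.labels)
    if k > n:
        raise ValueError("k exceeds number of items")
    if k == n:
        return {lab: i + 1 for i, lab in enumerate(result.labels)}
    if k == 1:
        return {lab: 1 for lab in result.labels}
    Z = linkage(pdist(result.coordinates), method="complete")
    assign = fcluster(Z, t=k, criterion="maxclust")
    return {lab: int(c) for lab, c in zip(result.labels, assign)}
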