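"""Non-metric multidimensional scaling and Gaussian-mixture clustering.

NMDS minimises Kruskal's stress-1,

    stress = sqrt( sum_ij (dhat_ij - d_ij)^2 / sum_ij d_ij^2 ),

alternating a pooled-adjacent-violators isotonic fit of disparities dhat to
the observed dissimilarities with a SMACOF (Guttman-transform) update of the
configuration.  Initialisation is classical (metric) scaling plus jittered
random restarts; the best-stress solution is kept.  The embedded coordinates
feed a full-covariance Gaussian mixture whose K is chosen by BIC — the
model-free cross-check on the admixture clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.mixture import GaussianMixture

from .distances import DistanceMatrix

__all__ = ["NmdsResult", "ClusterAssignment", "nmds", "gaussian_mixture_clusters"]


@dataclass
class NmdsResult:
    labels: list[str]
    coordinates: np.ndarray  # (n, dims)
    stress: float
    n_restarts: int
    stress_trace: np.ndarray  # per-iteration stress of the winning restart

    def __post_init__(self) -> None:
        if not 0 <= self.stress <= 1:
            raise ValueError(f"stress-1 out of [0, 1]: {self.stress}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=self.labels,
            columns=[f"dim{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        df.index.name = "individual_id"
        return df


@dataclass
class ClusterAssignment:
    """Hard cluster labels (contiguous integers from 1) per individual."""

    labels: pd.Series  # index individual_id -> int label
    source: str = "user"

    def __post_init__(self) -> None:
        vals = sorted(self.labels.unique())
        if vals != list(range(1, len(vals) + 1)):
            raise ValueError(f"labels must be contiguous integers from 1, got {vals}")
        self.labels = self.labels.astype(int)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def for_ids(self, ids) -> np.ndarray:
        return self.labels.loc[list(ids)].to_numpy()

    @classmethod
    def from_array(cls, ids, labels, source: str = "user") -> "ClusterAssignment":
        raw = pd.Series(labels, index=list(ids), name="cluster")
        uniq = {v: i + 1 for i, v in enumerate(sorted(raw.unique()))}
        return cls(raw.map(uniq), source)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = (d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - d) ** 2).sum() / denom))


def _config_distances(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _classical_scaling(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    lam, V = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1][:dims]
    lam = np.clip(lam[order], 0, None)
    return V[:, order] * np.sqrt(lam)[None, :]


def nmds(
    D: DistanceMatrix,
    dims: int = 2,
    n_restarts: int = 8,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> NmdsResult:
    """Kruskal non-metric MDS of a distance matrix."""
    n = D.n
    if dims >= n:
        raise ValueError("dims must be smaller than the number of objects")
    if not D.values.any():
        raise ValueError("all-zero distance matrix cannot be embedded")
    iu = np.triu_indices(n, k=1)
    dis = D.values[iu]
    order = np.argsort(dis, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True)

    best = None
    X0 = _classical_scaling(D.values, dims)
    scale = np.abs(X0).max() or 1.0
    for restart in range(n_restarts):
        X = X0 if restart == 0 else X0 + rng.normal(0, 0.1 * scale, X0.shape)
        trace = []
        prev = np.inf
        for _ in range(max_iter):
            d = _config_distances(X)[iu]
            dhat = iso.fit(dis[order], d[order]).predict(dis[order])
            inv = np.empty_like(dhat)
            inv[order] = dhat
            # scale disparities so the Guttman step targets the right norm
            denom = (inv**2).sum()
            if denom > 0:
                inv = inv * np.sqrt((d**2).sum() / denom)
            s = _stress1(d, inv)
            trace.append(s)
            if prev - s < tol:
                break
            prev = s
            # Guttman transform with disparities inv
            W = np.zeros((n, n))
            full_d = _config_distances(X)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.zeros((n, n))
                dh = np.zeros((n, n))
                dh[iu] = inv
                dh += dh.T
                nz = full_d > 0
                ratio[nz] = dh[nz] / full_d[nz]
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = (B @ X) / n
        d = _config_distances(X)[iu]
        dhat = iso.fit(dis[order], d[order]).predict(dis[order])
        inv = np.empty_like(dhat)
        inv[order] = dhat
        s = _stress1(d, inv)
        trace.append(s)
        if best is None or s < best[0]:
            best = (s, X, np.asarray(trace))
    stress, X, trace = best
    return NmdsResult(D.labels, X, min(stress, 1.0), n_restarts, trace)


def gaussian_mixture_clusters(
    coords: NmdsResult,
    K_max: int = 10,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Full-covariance Gaussian mixture over ordination coordinates.

    Fits K = 1..K_max by EM (k-means++-style initialisation, ``n_restarts``
    inits each), picks K by BIC and returns hard argmax-responsibility labels
    plus the BIC table.
    """
    X = np.asarray(coords.coordinates, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite coordinates")
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    rows = []
    models = {}
    for K in range(1, K_max + 1):
        if K > X.shape[0]:
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = GaussianMixture(
                n_components=K,
                covariance_type="full",
                n_init=n_restarts,
                reg_covar=1e-6,
                random_state=seed,
            ).fit(X)
        models[K] = gm
        rows.append({"K": K, "bic": gm.bic(X), "converged": gm.converged_})
    bic_table = pd.DataFrame(rows)
    best_k = int(bic_table.loc[bic_table["bic"].idxmin(), "K"])
    hard = models[best_k].predict(X)
    assignment = ClusterAssignment.from_array(coords.labels, hard + 1, source="gaussian")
    return assignment, bic_table
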