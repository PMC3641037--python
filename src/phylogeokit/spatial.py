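"""Geographic concordance and variance-partitioning statistics.

ANOSIM ranks all n(n-1)/2 pairwise distances (mean ranks for ties) and
contrasts the mean between-group rank with the mean within-group rank,

    R = (rbar_B - rbar_W) / (M / 2),  M = n(n-1)/2,

with significance from permutations of the group labels.  R near 1 means the
groups are maximally separated in the distance space; R near 0 means no
separation.

Distance-based redundancy analysis (dbRDA) regresses a distance matrix on
predictor variables through the Gower-centred inner-product matrix

    G = (I - 11'/n) (-1/2 D.^2) (I - 11'/n)

using the multivariate pseudo-F of McArdle & Anderson:

    F = [tr(H G H) / m] / [tr((I-H) G (I-H)) / (n - m - 1)],

H the hat matrix of the (column-centred) predictors.  With covariates Z the
predictors are first residualised on Z (partial dbRDA) and the denominator
uses the full [Z X] fit; significance comes from Freedman-Lane-style
permutation of the residualised predictors.  Negative eigenvalues of G
(possible for non-Euclidean dissimilarities such as Jaccard) are kept in the
traces, following the McArdle-Anderson convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .distances import DistanceMatrix
from .io import SampleTable
from .ordination import ClusterAssignment

__all__ = [
    "AnosimResult",
    "anosim",
    "anosim_pairwise",
    "DistanceBasedRDA",
    "DbRDAResults",
    "dbrda",
    "ibd_cluster_report",
]


@dataclass
class AnosimResult:
    r: float
    p_value: float
    mean_between_rank: float
    mean_within_rank: float
    n: int
    n_permutations: int
    pairwise: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"R out of range: {self.r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "R": self.r,
                    "p": self.p_value,
                    "mean_between_rank": self.mean_between_rank,
                    "mean_within_rank": self.mean_within_rank,
                    "n": self.n,
                    "n_permutations": self.n_permutations,
                }
            ]
        )

    def summary(self) -> str:
        return (
            f"ANOSIM: R = {self.r:.4f}, p = {self.p_value:.4g} "
            f"({self.n_permutations} permutations, n = {self.n})"
        )


def _labels_for(D: DistanceMatrix, labels) -> np.ndarray:
    if isinstance(labels, ClusterAssignment):
        return labels.for_ids(D.labels)
    arr = np.asarray(labels)
    if arr.shape != (D.n,):
        raise ValueError("labels length does not match distance matrix")
    return arr


def _anosim_r(ranks: np.ndarray, same: np.ndarray, M: int) -> float:
    rw = ranks[same].mean()
    rb = ranks[~same].mean()
    return (rb - rw) / (M / 2.0), rb, rw


def anosim(
    D: DistanceMatrix,
    labels,
    n_permutations: int = 10000,
    seed: int = 0,
) -> AnosimResult:
    """One-way analysis of similarities on a distance matrix."""
    groups = _labels_for(D, labels)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"groups with fewer than 2 members: {list(small)}")
    n = D.n
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(D.values[iu])
    M = len(ranks)
    same = groups[iu[0]] == groups[iu[1]]
    r_obs, rb, rw = _anosim_r(ranks, same, M)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        same_p = perm[iu[0]] == perm[iu[1]]
        r_p, _, _ = _anosim_r(ranks, same_p, M)
        if r_p >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return AnosimResult(float(r_obs), float(p), float(rb), float(rw), n, n_permutations)


def anosim_pairwise(
    D: DistanceMatrix,
    labels,
    n_permutations: int = 10000,
    correction: str = "bonferroni",
    seed: int = 0,
) -> pd.DataFrame:
    """ANOSIM for every unordered group pair, with Bonferroni correction."""
    groups = _labels_for(D, labels)
    uniq = np.unique(groups)
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
    ss = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    usable = []
    for (a, b), child in zip(pairs, ss):
        mask = np.isin(groups, (a, b))
        if (groups[mask] == a).sum() < 2 or (groups[mask] == b).sum() < 2:
            warnings.warn(f"group pair ({a}, {b}) has a singleton group; skipped")
            rows.append(
                {"group_a": a, "group_b": b, "R": np.nan, "p_raw": np.nan}
            )
            continue
        sub_labels = [l for l, m in zip(D.labels, mask) if m]
        sub = D.subset(sub_labels)
        res = anosim(
            sub,
            groups[mask],
            n_permutations=n_permutations,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        rows.append({"group_a": a, "group_b": b, "R": res.r, "p_raw": res.p_value})
        usable.append(len(rows) - 1)
    df = pd.DataFrame(rows)
    n_comp = len(usable)
    if correction == "bonferroni":
        df["p_corrected"] = np.minimum(1.0, df["p_raw"] * n_comp)
    elif correction == "none":
        df["p_corrected"] = df["p_raw"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df


# --- dbRDA -------------------------------------------------------------------


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(M: np.ndarray) -> np.ndarray:
    """Orthogonal-projection (hat) matrix onto the column space of M."""
    if M.size == 0:
        return np.zeros((M.shape[0], M.shape[0]))
    Q, R = np.linalg.qr(M)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    return Q @ Q.T


def _rank(M: np.ndarray) -> int:
    if M.size == 0:
        return 0
    return int(np.linalg.matrix_rank(M, tol=1e-10))


@dataclass
class DbRDAResults:
    pseudo_f: float
    proportion_explained: float
    p_value: float
    m: int
    df_resid: int
    n: int
    n_permutations: int
    trace_total: float
    trace_fitted: float
    negative_eigenvalue_share: float
    predictor_names: list[str]
    covariate_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n": self.n,
                    "pseudo_F": self.pseudo_f,
                    "p": self.p_value,
                    "proportion_explained": self.proportion_explained,
                    "m": self.m,
                    "df_resid": self.df_resid,
                }
            ]
        )

    def summary(self) -> str:
        cov = f", covariates: {self.covariate_names}" if self.covariate_names else ""
        return (
            f"dbRDA: pseudo-F = {self.pseudo_f:.4f}, p = {self.p_value:.4g}, "
            f"proportion explained = {self.proportion_explained:.4f} "
            f"(n = {self.n}, m = {self.m}, predictors: {self.predictor_names}{cov})"
        )


class DistanceBasedRDA:
    """Multivariate regression of a distance matrix on predictors.

    ``X`` (and optional covariates ``Z``) are DataFrames indexed like the
    distance-matrix labels, or plain arrays in label order.
    """

    def __init__(
        self,
        D: DistanceMatrix,
        X,
        Z=None,
    ):
        self.D = D
        self.X, self.predictor_names = self._coerce(X, "x")
        if Z is not None:
            self.Z, self.covariate_names = self._coerce(Z, "z")
        else:
            self.Z, self.covariate_names = None, []
        n = D.n
        Xc = self.X - self.X.mean(axis=0)
        if _rank(Xc) < Xc.shape[1]:
            raise ValueError(
                f"rank-deficient predictors after centering: {self.predictor_names}"
            )

    def _coerce(self, M, prefix: str):
        if isinstance(M, pd.DataFrame):
            arr = M.loc[list(self.D.labels)].to_numpy(dtype=float)
            names = list(M.columns)
        else:
            arr = np.asarray(M, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            names = [f"{prefix}{i + 1}" for i in range(arr.shape[1])]
        if arr.shape[0] != self.D.n:
            raise ValueError("predictor rows do not match distance matrix")
        return arr, names

    def fit(
        self,
        n_permutations: int = 9999,
        seed: int = 0,
        permutation: str = "freedman_lane",
    ) -> DbRDAResults:
        D = self.D.values
        n = self.D.n
        G = _gower_center(D)
        eig = np.linalg.eigvalsh(G)
        neg_share = float(np.abs(eig[eig < 0]).sum() / np.abs(eig).sum()) if np.abs(
            eig
        ).sum() > 0 else 0.0
        trace_total = float(np.trace(G))
        ones = np.ones((n, 1))
        if self.Z is None:
            Xc = self.X - self.X.mean(axis=0)
            m = _rank(Xc)
            H = _hat(Xc)
            H_full = H
            df_resid = n - m - 1
            X_perm = Xc
        else:
            Zc = np.hstack([ones, self.Z])
            HZ = _hat(Zc)
            X_res = (np.eye(n) - HZ) @ self.X
            m = _rank(X_res)
            if m == 0:
                raise ValueError("predictors are collinear with the covariates")
            H = _hat(X_res)
            full = np.hstack([self.Z - self.Z.mean(axis=0), X_res])
            H_full = _hat(full)
            df_resid = n - _rank(full) - 1
            X_perm = X_res
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom")
        tr_fit = float(np.sum(H * G))  # tr(H G H) = tr(H G) for idempotent H
        tr_res = float(trace_total - np.sum(H_full * G))

        def pseudo_f(fit, res):
            # a saturated fit (zero residual trace) maps to an infinite F
            if res <= 1e-12 * max(1.0, abs(trace_total)):
                return np.inf
            return (fit / m) / (res / df_resid)

        f_obs = pseudo_f(tr_fit, tr_res)
        proportion = tr_fit / trace_total if trace_total != 0 else np.nan

        rng = np.random.default_rng(seed)
        if permutation == "raw":
            # permute rows of the raw predictors (and re-residualise)
            pass
        elif permutation != "freedman_lane":
            raise ValueError(f"unknown permutation scheme {permutation!r}")
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if self.Z is None:
                # H under row-permuted X equals P H P'; use index gymnastics
                Gp = G[np.ix_(perm, perm)]
                tr_fit_p = float(np.sum(H * Gp))
                tr_res_p = float(trace_total - np.sum(H_full * Gp))
            else:
                Xp = X_perm[perm]
                if permutation == "raw":
                    Xp = (np.eye(n) - _hat(np.hstack([ones, self.Z]))) @ self.X[perm]
                Hp = _hat(Xp - Xp.mean(axis=0) if self.Z is None else Xp)
                fullp = np.hstack([self.Z - self.Z.mean(axis=0), Xp])
                Hfp = _hat(fullp)
                tr_fit_p = float(np.sum(Hp * G))
                tr_res_p = float(trace_total - np.sum(Hfp * G))
            if pseudo_f(tr_fit_p, tr_res_p) >= f_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        # trace additivity diagnostic (McArdle-Anderson decomposition)
        add = tr_fit + float(
            np.trace((np.eye(n) - H) @ G @ (np.eye(n) - H))
        )
        if self.Z is None and abs(add - trace_total) > 1e-6 * max(1, abs(trace_total)):
            warnings.warn("trace additivity violated beyond tolerance")
        return DbRDAResults(
            float(f_obs),
            float(proportion),
            float(p),
            m,
            df_resid,
            n,
            n_permutations,
            trace_total,
            tr_fit,
            neg_share,
            self.predictor_names,
            self.covariate_names,
        )


def dbrda(
    D: DistanceMatrix,
    X,
    Z=None,
    n_permutations: int = 9999,
    seed: int = 0,
    permutation: str = "freedman_lane",
) -> DbRDAResults:
    """Functional wrapper around :class:`DistanceBasedRDA`."""
    return DistanceBasedRDA(D, X, Z).fit(n_permutations, seed, permutation)


def _cluster_dummies(groups: np.ndarray) -> np.ndarray:
    """n-1 membership indicator columns (last cluster is the reference)."""
    uniq = np.unique(groups)
    return np.column_stack([(groups == g).astype(float) for g in uniq[:-1]])


def ibd_cluster_report(
    D: DistanceMatrix,
    samples: SampleTable,
    labels,
    n_permutations: int = 9999,
    seed: int = 0,
    min_cluster_size: int = 4,
) -> dict:
    """Three-part isolation-by-distance vs cluster-subdivision partition.

    (i) dbRDA of D on latitude+longitude (isolation by distance);
    (ii) dbRDA of D on n-1 cluster dummies with lat+lon as covariates
    (subdivision beyond geography); (iii) per-cluster dbRDA of the restricted
    D on lat+lon (within-cluster IBD).  Clusters smaller than
    ``min_cluster_size`` are skipped (degrees of freedom exhaustion).
    """
    groups = _labels_for(D, labels)
    coords = samples.coordinates(D.labels)  # (lat, lon) degrees
    latlon = pd.DataFrame(
        coords, index=D.labels, columns=["latitude", "longitude"]
    )
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]
    ibd = dbrda(D, latlon, n_permutations=n_permutations, seed=seeds[0])
    uniq = np.unique(groups)
    clusters_part = None
    if len(uniq) >= 2:
        dummies = pd.DataFrame(
            _cluster_dummies(groups),
            index=D.labels,
            columns=[f"cluster_{g}" for g in uniq[:-1]],
        )
        clusters_part = dbrda(
            D, dummies, Z=latlon, n_permutations=n_permutations, seed=seeds[1]
        )
    per_cluster = []
    child = np.random.SeedSequence(seeds[2])
    for g in uniq:
        mask = groups == g
        size = int(mask.sum())
        if size < min_cluster_size:
            warnings.warn(f"cluster {g} has n={size} < {min_cluster_size}; skipped")
            per_cluster.append(
                {"cluster": g, "n": size, "pseudo_F": np.nan, "p": np.nan,
                 "proportion_explained": np.nan}
            )
            continue
        ids = [l for l, m in zip(D.labels, mask) if m]
        sub = D.subset(ids)
        res = dbrda(
            sub,
            latlon.loc[ids],
            n_permutations=n_permutations,
            seed=int(child.spawn(1)[0].generate_state(1)[0] % (2**31 - 1)),
        )
        per_cluster.append(
            {
                "cluster": g,
                "n": size,
                "pseudo_F": res.pseudo_f,
                "p": res.p_value,
                "proportion_explained": res.proportion_explained,
            }
        )
    return {
        "ibd": ibd,
        "clusters_given_space": clusters_part,
        "per_cluster": pd.DataFrame(per_cluster),
    }
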