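"""Bayesian admixture clustering of binary dominant markers, with the
Evanno delta-K criterion for choosing the number of clusters.

Model
-----
Bands are treated as haploid Bernoulli characters.  With K clusters, cluster k
carries a band frequency p_kl at locus l (Beta(1,1) prior) and individual i an
admixture vector q_i (symmetric Dirichlet(alpha) prior).  Each observed call
x_il picks a latent source cluster z_il ~ Categorical(q_i) and then
x_il ~ Bernoulli(p_{z_il, l}).  All full conditionals are conjugate, so the
posterior is explored by plain Gibbs sampling; q and p are reported as
posterior means over the post-burn-in sweeps.  Missing calls are skipped in
both the likelihood and the count updates.

The model-choice score for a run is the standard harmonic-style estimate
``mean(lnL) - var(lnL)/2`` over post-burn-in sweeps, and delta-K at K is the
absolute second difference of the per-K mean score divided by the across-run
standard deviation at K; its maximum over the interior K grid suggests the
number of clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BinaryMarkerMatrix, MISSING

__all__ = ["AdmixtureModel", "AdmixtureResults", "DeltaKTable", "delta_k", "run_k_grid"]


@dataclass
class AdmixtureResults:
    """Posterior summaries of one admixture run."""

    individual_ids: list[str]
    locus_ids: list[str]
    K: int
    q: np.ndarray  # (n, K) posterior-mean admixture proportions
    p: np.ndarray  # (K, L) posterior-mean band frequencies
    alpha: float
    lnl_trace: np.ndarray  # post-burn-in data log-likelihood per sweep
    seed: int

    def __post_init__(self) -> None:
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("admixture proportions must sum to 1 per individual")
        if not np.isfinite(self.lnl_trace).all():
            raise ValueError("non-finite log-likelihood trace")

    @property
    def model_lnp(self) -> float:
        """Model score: mean(lnL) - var(lnL)/2 over the kept sweeps."""
        t = self.lnl_trace
        return float(t.mean() - t.var(ddof=1) / 2 if len(t) > 1 else t.mean())

    def hard_assignment(self) -> "pd.Series":
        """1-based argmax-q cluster labels per individual."""
        return pd.Series(
            self.q.argmax(axis=1) + 1, index=self.individual_ids, name="cluster"
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.q,
            index=self.individual_ids,
            columns=[f"q{k + 1}" for k in range(self.K)],
        )
        df.index.name = "individual_id"
        return df

    def summary(self) -> str:
        sizes = self.hard_assignment().value_counts().sort_index()
        lines = [
            f"Admixture fit: K={self.K}, n={len(self.individual_ids)}, "
            f"L={len(self.locus_ids)}, alpha={self.alpha}",
            f"model lnP estimate: {self.model_lnp:.2f} "
            f"({len(self.lnl_trace)} kept sweeps)",
            "cluster sizes (argmax q): "
            + ", ".join(f"{k}: {v}" for k, v in sizes.items()),
        ]
        return "\n".join(lines)


class AdmixtureModel:
    """Gibbs-sampled admixture model over a binary marker matrix."""

    def __init__(self, markers: BinaryMarkerMatrix):
        self.markers = markers
        self._x = markers.values
        self._obs = markers.observed_mask()

    def fit(
        self,
        K: int,
        burn_in: int = 200,
        sweeps: int = 400,
        alpha: float = 1.0,
        seed: int = 0,
        init: str = "kmeans",
    ) -> AdmixtureResults:
        n, L = self._x.shape
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > n:
            raise ValueError(f"K={K} exceeds the number of individuals ({n})")
        if sweeps < 1:
            raise ValueError("need at least one sweep")
        rng = np.random.default_rng(seed)
        x = self._x
        obs = self._obs
        x1 = (x == 1) & obs
        x0 = (x == 0) & obs
        # sweeps run in float32: the likelihood trace is only used through
        # across-sweep means/variances, where float32 state noise is far below
        # Monte-Carlo noise
        x1f = x1[:, :, None]
        obs_f = obs.astype(np.float32)

        if init == "kmeans" and K > 1:
            # warm start near a K-cluster mode: a k-means hard clustering
            # seeds q and p, which prevents the empty-cluster local modes
            # plain prior draws fall into.  The k-means seed depends only on
            # the data and K, so replicate runs share the same starting mode
            # and their spread reflects Monte-Carlo noise, not init lottery.
            import zlib

            from sklearn.cluster import KMeans

            filled = np.where(obs, x, 0.5).astype(float)
            km_state = zlib.crc32(x.tobytes() + bytes([K % 251])) % (2**31 - 1)
            km = KMeans(n_clusters=K, n_init=10, random_state=km_state).fit(filled)
            hard = km.labels_
            q = np.full((n, K), 0.1 / max(K - 1, 1))
            q[np.arange(n), hard] = 0.9
            p = np.vstack([
                np.where(obs[hard == k].sum(0) > 0,
                         (x1[hard == k].sum(0) + 1) / (obs[hard == k].sum(0) + 2),
                         0.5)
                for k in range(K)
            ])
            p = np.clip(p, 1e-3, 1 - 1e-3)
        elif init == "random" or K == 1:
            q = rng.dirichlet(np.full(K, alpha), size=n)  # (n, K)
            p = rng.beta(1.0, 1.0, size=(K, L))
        else:
            raise ValueError(f"unknown init {init!r}")
        q_sum = np.zeros_like(q)
        p_sum = np.zeros_like(p)
        lnl = []
        kept = 0
        pf = p.astype(np.float32)
        qf = q.astype(np.float32)
        for sweep in range(burn_in + sweeps):
            # z_il | q, p: w_ilk = q_ik * p_kl^x (1-p_kl)^(1-x), observed calls only
            w = np.where(x1f, pf.T[None, :, :], (1.0 - pf.T)[None, :, :])
            w *= qf[:, None, :]
            w_sum = w.sum(axis=2, keepdims=True)
            if sweep >= burn_in:
                # the z normaliser is the mixture likelihood of the current state
                ll = float(
                    np.log(np.clip(w_sum[:, :, 0], 1e-30, None)[obs]).sum()
                )
                if not np.isfinite(ll):
                    raise FloatingPointError("non-finite likelihood during sampling")
                lnl.append(ll)
            w = w.cumsum(axis=2)
            u = rng.random((n, L, 1), dtype=np.float32) * w_sum
            z = (w < u).sum(axis=2)  # (n, L) in 0..K-1
            z = np.minimum(z, K - 1)
            # p | z, x
            n1_kl = np.zeros((K, L))
            n0_kl = np.zeros((K, L))
            for k in range(K):
                sel = z == k
                n1_kl[k] = ((sel & x1).sum(axis=0))
                n0_kl[k] = ((sel & x0).sum(axis=0))
            p = rng.beta(1.0 + n1_kl, 1.0 + n0_kl)
            p = np.clip(p, 1e-9, 1 - 1e-9)
            pf = p.astype(np.float32)
            # q | z
            m = np.vstack([((z == k) & obs).sum(axis=1) for k in range(K)]).T
            q = rng.gamma(alpha + m)
            q /= q.sum(axis=1, keepdims=True)
            qf = q.astype(np.float32)
            if sweep >= burn_in:
                q_sum += q
                p_sum += p
                kept += 1
        qm = q_sum / kept
        qm /= qm.sum(axis=1, keepdims=True)
        return AdmixtureResults(
            self.markers.individual_ids,
            self.markers.locus_ids,
            K,
            qm,
            np.clip(p_sum / kept, 1e-9, 1 - 1e-9),
            alpha,
            np.asarray(lnl),
            seed,
        )


def fit_admixture(
    markers: BinaryMarkerMatrix,
    K: int,
    burn_in: int = 200,
    sweeps: int = 400,
    alpha: float = 1.0,
    seed: int = 0,
) -> AdmixtureResults:
    """Functional wrapper around :class:`AdmixtureModel`."""
    return AdmixtureModel(markers).fit(K, burn_in, sweeps, alpha, seed)


@dataclass
class DeltaKTable:
    """Per-K summary of the Evanno criterion."""

    table: pd.DataFrame  # columns: K, n_runs, mean_lnp, sd_lnp, second_diff, delta_k

    @property
    def best_k(self) -> int:
        t = self.table.dropna(subset=["delta_k"])
        return int(t.loc[t["delta_k"].idxmax(), "K"])

    def to_frame(self) -> pd.DataFrame:
        return self.table


def delta_k(
    runs: Mapping[int, Sequence[float]], numerator: str = "mean_of_runs"
) -> DeltaKTable:
    """Evanno delta-K from per-K lists of model scores.

    delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / s[L(K)], with L the per-K mean
    score and s the across-run sample standard deviation.  With
    ``numerator="per_run"`` the second difference is instead averaged over
    per-run second differences (requires equal run counts).
    """
    ks = sorted(runs)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K grid not consecutive: {ks}")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValueError("need >= 2 runs per K")
    mean = np.array([np.mean(runs[k]) for k in ks])
    sd = np.array([np.std(runs[k], ddof=1) for k in ks])
    second = np.full(len(ks), np.nan)
    if numerator == "mean_of_runs":
        second[1:-1] = np.abs(mean[2:] - 2 * mean[1:-1] + mean[:-2])
    elif numerator == "per_run":
        counts = {len(runs[k]) for k in ks}
        if len(counts) != 1:
            raise ValueError("per_run numerator needs equal run counts at every K")
        arr = np.array([list(runs[k]) for k in ks])  # (nK, R)
        second[1:-1] = np.abs(arr[2:] - 2 * arr[1:-1] + arr[:-2]).mean(axis=1)
    else:
        raise ValueError(f"unknown numerator {numerator!r}")
    dk = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if sd[i] == 0:
            if second[i] == 0:
                dk[i] = 0.0
            else:
                warnings.warn(f"zero run variance at K={ks[i]}: delta-K infinite")
                dk[i] = np.inf
        else:
            dk[i] = second[i] / sd[i]
    df = pd.DataFrame(
        {
            "K": ks,
            "n_runs": [len(runs[k]) for k in ks],
            "mean_lnp": mean,
            "sd_lnp": sd,
            "second_diff": second,
            "delta_k": dk,
        }
    )
    return DeltaKTable(df)


def run_k_grid(
    markers: BinaryMarkerMatrix,
    k_min: int,
    k_max: int,
    n_runs: int = 20,
    burn_in: int = 200,
    sweeps: int = 400,
    alpha: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, list[AdmixtureResults]]]:
    """Replicate admixture runs over a consecutive K grid.

    Returns the run log (K, run, seed, model_lnp) and the fitted results,
    the inputs :func:`delta_k` consumes.
    """
    ss = np.random.SeedSequence(seed)
    log = []
    fits: dict[int, list[AdmixtureResults]] = {}
    model = AdmixtureModel(markers)
    for K in range(k_min, k_max + 1):
        fits[K] = []
        for run in range(n_runs):
            child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            res = model.fit(K, burn_in=burn_in, sweeps=sweeps, alpha=alpha, seed=child)
            fits[K].append(res)
            log.append(
                {"K": K, "run": run, "seed": child, "model_lnp": res.model_lnp}
            )
    return pd.DataFrame(log), fits
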