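"""Pairwise distance matrices: Jaccard (dominant markers), geographic
great-circle / equirectangular (km), and maximum-likelihood GTR+Gamma
(substitutions per site) for a coding alignment.

The GTR+Gamma machinery estimates one substitution model for the whole
alignment (empirical base frequencies; exchangeabilities and gamma shape by
maximising the sum of pairwise log-likelihoods, each pair with its own branch
length) and then re-optimises a single branch length per pair to obtain the
distance, the standard pairwise ML distance of PAUP*-style workflows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammainc

from .io import BinaryMarkerMatrix, CodingAlignment, SampleTable, MISSING

__all__ = [
    "DistanceMatrix",
    "SubstitutionModel",
    "jaccard_matrix",
    "geographic_matrix",
    "fit_gtr_gamma",
    "gtr_gamma_matrix",
]

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEGREE = 111.195


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"
    #: boolean mask of pairs whose distance could not be computed (kept at nan)
    missing_pairs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(np.where(finite, v, 0), np.where(finite.T, v.T, 0)):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal not zero")
        if (v[finite] < 0).any():
            raise ValueError("negative distances")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pair_index(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, k=1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in keep]
        return DistanceMatrix(keep, self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.index.name = "id"
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


def jaccard_matrix(markers: BinaryMarkerMatrix) -> DistanceMatrix:
    """Jaccard distance d = 1 - a/(a+b+c) over shared observed loci.

    ``a`` counts loci where both individuals have the band, ``b``/``c`` loci
    where exactly one does; loci missing in either member of a pair are
    excluded.  A pair with no band in either individual (a+b+c = 0) gets
    distance 0 with a warning.
    """
    if markers.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    obs = markers.observed_mask()
    if not obs.any(axis=1).all():
        bad = [
            i for i, ok in zip(markers.individual_ids, obs.any(axis=1)) if not ok
        ]
        raise ValueError(f"individuals with all loci missing: {bad}")
    x = np.where(obs, markers.values, 0).astype(float)
    o = obs.astype(float)
    both_obs = o @ o.T
    a = x @ x.T
    ones_obs = x @ o.T  # bands of i at loci observed in both
    b = ones_obs - a
    c = ones_obs.T - a
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - a / denom
    empty = (denom == 0) & (both_obs > 0)
    if empty.any():
        warnings.warn(
            f"{int(np.triu(empty, 1).sum())} pairs share no scored band; "
            "their Jaccard distance is defined as 0"
        )
    d[denom == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(markers.individual_ids, d, "jaccard")


def geographic_matrix(
    samples: SampleTable,
    method: Literal["great_circle", "equirectangular"] = "great_circle",
) -> DistanceMatrix:
    """Pairwise geographic distances in km between individuals' localities."""
    coords = np.radians(samples.coordinates())
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    if method == "great_circle":
        dlat = lat - lat.T
        dlon = lon - lon.T
        h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    elif method == "equirectangular":
        deg = samples.coordinates()
        mean_lat = np.radians(deg[:, 0].mean())
        x = deg[:, 1] * np.cos(mean_lat) * KM_PER_DEGREE
        y = deg[:, 0] * KM_PER_DEGREE
        d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(samples.individual_ids, d, "geographic_km")


# --- GTR+Gamma ---------------------------------------------------------------

_BASES = b"ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
# order of the six exchangeabilities
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_PAIR_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class SubstitutionModel:
    """GTR exchangeabilities (r_GT = 1), base frequencies and gamma shape."""

    exchangeabilities: dict = field(
        default_factory=lambda: {p: 1.0 for p in _PAIR_NAMES}
    )
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    gamma_shape: float = 1.0
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        pi = np.asarray(self.base_frequencies, dtype=float)
        if abs(pi.sum() - 1) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if (pi <= 0).any():
            raise ValueError("base frequencies must be positive")
        self.base_frequencies = pi
        if any(v <= 0 for v in self.exchangeabilities.values()):
            raise ValueError("exchangeabilities must be positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """GTR rate matrix scaled to one expected substitution per unit time."""
        r = self.exchangeabilities
        pi = self.base_frequencies
        Q = np.zeros((4, 4))
        for (i, j), name in zip(_PAIRS, _PAIR_NAMES):
            Q[i, j] = r[name] * pi[j]
            Q[j, i] = r[name] * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def gamma_rates(self) -> np.ndarray:
        """Mean rate of each of the equal-probability discrete gamma categories."""
        a = self.gamma_shape
        C = self.n_rate_categories
        edges = _gamma_ppf(np.linspace(0, 1, C + 1), a)
        # mean of a Gamma(a, scale=1/a) on [lo, hi], normalised by category mass 1/C
        upper = gammainc(a + 1, edges[1:] * a)
        lower = gammainc(a + 1, edges[:-1] * a)
        return (upper - lower) * C

    def eigen(self):
        """Symmetric-form eigendecomposition of the rate matrix."""
        pi = self.base_frequencies
        Q = self.rate_matrix()
        s = np.sqrt(pi)
        S = (s[:, None] * Q) / s[None, :]
        S = (S + S.T) / 2
        lam, U = np.linalg.eigh(S)
        left = U.T / s[None, :] * 1.0
        right = s[:, None] * U
        return lam, right, left

    def transition_matrices(self, t: float, eig=None) -> np.ndarray:
        """(C, 4, 4) stack of P(t * rate_c) over the gamma categories."""
        lam, right, left = eig if eig is not None else self.eigen()
        rates = self.gamma_rates()
        out = np.empty((len(rates), 4, 4))
        for c, rc in enumerate(rates):
            out[c] = (right * np.exp(lam * rc * t)[None, :]) @ left
        return np.clip(out, 1e-300, None)


def _gamma_ppf(q, a):
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(q, a, scale=1.0 / a)
    edges[0] = 0.0
    edges[-1] = np.inf
    return edges


def _pattern_counts(alignment: CodingAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair 4x4 site-pattern counts with pairwise deletion of gaps/N."""
    codes = np.full(alignment.sequences.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[alignment.sequences == bytes([b])] = i
    n = alignment.n_sequences
    counts = np.zeros((n, n, 4, 4))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            ci, cj = codes[i][ok], codes[j][ok]
            cnt = np.zeros((4, 4))
            np.add.at(cnt, (ci, cj), 1.0)
            counts[i, j] = cnt
            counts[j, i] = cnt.T
    return codes, counts


def _pair_loglik(t: float, counts: np.ndarray, model: SubstitutionModel, eig) -> float:
    P = model.transition_matrices(t, eig)
    pi = model.base_frequencies
    # site likelihood = mean over categories of pi_x * P_c[x, y]
    site = (pi[None, :, None] * P).mean(axis=0)
    return float((counts * np.log(site)).sum())


def _ml_branch_length(
    counts: np.ndarray,
    model: SubstitutionModel,
    eig,
    t_max: float = 20.0,
    xatol: float = 1e-8,
) -> float:
    total = counts.sum()
    if total == 0:
        return np.nan
    diff = total - np.trace(counts)
    if diff == 0:
        return 0.0
    res = optimize.minimize_scalar(
        lambda t: -_pair_loglik(t, counts, model, eig),
        bounds=(1e-8, t_max),
        method="bounded",
        options={"xatol": xatol},
    )
    t = float(res.x)
    # guard against the boundary beating the interior optimum
    if _pair_loglik(1e-8, counts, model, eig) > _pair_loglik(t, counts, model, eig):
        return 0.0
    return t


def fit_gtr_gamma(
    alignment: CodingAlignment,
    n_rate_categories: int = 4,
    max_iter: int = 600,
    n_outer: int = 4,
) -> SubstitutionModel:
    """Estimate GTR+Gamma parameters by composite pairwise likelihood.

    Base frequencies are set to empirical counts; the five free
    exchangeabilities (r_GT fixed at 1) and the gamma shape maximise the sum
    over pairs of pairwise log-likelihoods, each pair with its own ML branch
    length.  The optimisation alternates bounded Nelder-Mead over the
    (log) model parameters with per-pair branch-length updates, starting from
    the Jukes-Cantor-like point (all r = 1, shape = 1); it is deterministic
    for a given alignment.  Parameters are box-bounded on the log scale —
    the composite likelihood is nearly flat in extreme corners, which the
    bounds simply exclude.
    """
    if alignment.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    codes, counts = _pattern_counts(alignment)
    ungapped = (codes >= 0).all(axis=0).sum()
    if ungapped < 100:
        raise ValueError(f"only {ungapped} ungapped columns; need >= 100")
    base_counts = np.bincount(codes[codes >= 0].ravel(), minlength=4).astype(float)
    pi = base_counts / base_counts.sum()
    if (pi <= 0).any():
        pi = (base_counts + 1) / (base_counts.sum() + 4)
    iu = np.triu_indices(alignment.n_sequences, k=1)
    pair_counts = [counts[i, j] for i, j in zip(*iu)]
    if all(np.trace(c) == c.sum() for c in pair_counts):
        raise ValueError("all sequences identical: no divergence to fit")

    def build(theta: np.ndarray) -> SubstitutionModel:
        r = dict(zip(_PAIR_NAMES[:5], np.exp(theta[:5])))
        r["GT"] = 1.0
        return SubstitutionModel(r, pi, float(np.exp(theta[5])), n_rate_categories)

    x = np.zeros(6)
    model = build(x)
    eig = model.eigen()
    ts = [_ml_branch_length(c, model, eig, xatol=1e-6) for c in pair_counts]
    bounds = [(-3.5, 3.5)] * 5 + [(-2.5, 3.5)]
    converged = False
    prev_ll = -np.inf
    for _ in range(n_outer):

        def objective(theta: np.ndarray) -> float:
            m = build(theta)
            e = m.eigen()
            return -sum(
                _pair_loglik(max(t, 1e-8), c, m, e)
                for t, c in zip(ts, pair_counts)
            )

        res = optimize.minimize(
            objective,
            x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": max_iter, "xatol": 1e-3, "fatol": 1e-4},
        )
        x = res.x
        model = build(x)
        eig = model.eigen()
        ts = [_ml_branch_length(c, model, eig, xatol=1e-6) for c in pair_counts]
        ll = -objective(x)
        if abs(ll - prev_ll) < 1e-3 * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
        converged = res.success or res.nit < max_iter
    if not converged:
        err = RuntimeError("GTR+Gamma optimisation did not converge")
        err.best_model = model  # type: ignore[attr-defined]
        raise err
    return model


def gtr_gamma_matrix(
    alignment: CodingAlignment,
    model: SubstitutionModel | None = None,
    min_sites: int = 50,
) -> DistanceMatrix:
    """Pairwise ML distances (expected substitutions/site) under GTR+Gamma.

    Pairs with fewer than ``min_sites`` jointly resolved sites are flagged as
    missing (NaN) rather than estimated.
    """
    if model is None:
        model = fit_gtr_gamma(alignment)
    _, counts = _pattern_counts(alignment)
    eig = model.eigen()
    n = alignment.n_sequences
    d = np.zeros((n, n))
    missing = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            c = counts[i, j]
            if c.sum() < min_sites:
                d[i, j] = d[j, i] = np.nan
                missing[i, j] = missing[j, i] = True
                continue
            t = _ml_branch_length(c, model, eig)
            d[i, j] = d[j, i] = t
    if missing.any():
        warnings.warn(
            f"{int(np.triu(missing, 1).sum())} pairs have < {min_sites} comparable "
            "sites; distances set to NaN"
        )
    return DistanceMatrix(alignment.sequence_ids, d, "gtr_gamma", missing)
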