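"""Locus-by-environment association scan (SAM-style).

Every (locus, environmental variable) combination gets a univariate logistic
regression of band presence on the variable.  Each model is screened with two
statistics — the likelihood-ratio G = 2(lnL_full - lnL_null) and the Wald
W = (beta/SE)^2, both referred to chi-square(1) — and a locus is called
associated only when BOTH p-values fall below the Bonferroni threshold
(1 - confidence) / n_tests.  Requiring agreement between the two asymptotic
tests guards against the anti-conservative behaviour either one can show in
small or unbalanced samples.

Complete or quasi-complete separation makes the logistic likelihood monotone
(slope diverging); such fits are detected, flagged and excluded from the
significance calls rather than reported with meaningless p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import BinaryMarkerMatrix, EnvTable, SampleTable, MISSING

__all__ = [
    "SamAssociation",
    "EnvScanResults",
    "EnvAssociationScan",
    "logistic_assoc",
    "sam_scan",
]

_MAX_ABS_SLOPE_Z = 12.0  # |beta| on standardised env beyond this flags separation


def _fit_logistic_batch(env: np.ndarray, Y: np.ndarray, obs: np.ndarray,
                        max_iter: int = 60, tol: float = 1e-10):
    """Newton fits of presence ~ 1 + env for a batch of loci.

    ``Y`` is (B, n) with 0/1, ``obs`` a matching observation mask, ``env`` a
    shared (n,) covariate.  Returns arrays (beta0, beta1, se1, lnl_full,
    lnl_null, converged, separated).
    """
    B, n = Y.shape
    x = np.asarray(env, dtype=float)
    scale = x.std()
    if scale == 0:
        raise ValueError("constant environmental variable")
    xs = (x - x.mean()) / scale
    b0 = np.zeros(B)
    b1 = np.zeros(B)
    w_obs = obs.astype(float)
    Yf = np.where(obs, Y, 0).astype(float)
    converged = np.zeros(B, dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * xs[None, :]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        W = mu * (1 - mu) * w_obs
        r = (Yf - mu) * w_obs
        g0 = r.sum(axis=1)
        g1 = (r * xs).sum(axis=1)
        h00 = W.sum(axis=1)
        h01 = (W * xs).sum(axis=1)
        h11 = (W * xs**2).sum(axis=1)
        det = h00 * h11 - h01**2
        det = np.where(np.abs(det) < 1e-30, np.nan, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step_ok = np.isfinite(d0) & np.isfinite(d1)
        d0 = np.where(step_ok, d0, 0.0)
        d1 = np.where(step_ok, d1, 0.0)
        b0 += np.clip(d0, -5, 5)
        b1 += np.clip(d1, -5, 5)
        newly = step_ok & (np.abs(d0) < tol) & (np.abs(d1) < tol)
        converged |= newly
        if converged.all():
            break
    eta = b0[:, None] + b1[:, None] * xs[None, :]
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    lnl_full = (w_obs * (Yf * np.log(mu) + (1 - Yf) * np.log1p(-mu))).sum(axis=1)
    n_obs = w_obs.sum(axis=1)
    n_ones = Yf.sum(axis=1)
    pbar = np.clip(n_ones / n_obs, 1e-12, 1 - 1e-12)
    lnl_null = n_ones * np.log(pbar) + (n_obs - n_ones) * np.log1p(-pbar)
    W = mu * (1 - mu) * w_obs
    h00 = W.sum(axis=1)
    h01 = (W * xs).sum(axis=1)
    h11 = (W * xs**2).sum(axis=1)
    det = h00 * h11 - h01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var1 = h00 / det
    se1 = np.sqrt(np.where(var1 > 0, var1, np.nan))
    separated = (np.abs(b1) > _MAX_ABS_SLOPE_Z) | ~converged | ~np.isfinite(se1)
    # un-standardise the slope back to the original env scale
    beta1 = b1 / scale
    se_orig = se1 / scale
    beta0 = b0 - b1 * x.mean() / scale
    return beta0, beta1, se_orig, lnl_full, lnl_null, converged, separated, b1, se1


@dataclass
class SamAssociation:
    locus_id: str
    variable: str
    slope: float
    se: float
    g_stat: float
    wald: float
    p_g: float
    p_wald: float
    separated: bool
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def logistic_assoc(presence: np.ndarray, env: np.ndarray,
                   locus_id: str = "locus", variable: str = "env") -> SamAssociation:
    """Single-locus, single-variable logistic association test."""
    presence = np.asarray(presence)
    env = np.asarray(env, dtype=float)
    obs = (presence == 0) | (presence == 1)
    if obs.sum() < 10:
        raise ValueError("need at least 10 observations")
    y = presence[obs].astype(float)
    if y.min() == y.max():
        raise ValueError("constant presence vector")
    if env[obs].std() == 0:
        raise ValueError("constant environmental variable")
    out = _fit_logistic_batch(env[obs], y[None, :], np.ones((1, obs.sum()), bool))
    beta0, beta1, se, lnl_full, lnl_null, conv, sep, b1s, se1s = out
    g = max(0.0, 2.0 * (lnl_full[0] - lnl_null[0]))
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (b1s[0] / se1s[0]) ** 2
    if sep[0]:
        return SamAssociation(
            locus_id, variable, float(beta1[0]), np.nan, np.nan, np.nan,
            np.nan, np.nan, True, bool(conv[0]),
        )
    return SamAssociation(
        locus_id, variable, float(beta1[0]), float(se[0]), float(g), float(w),
        float(chi2.sf(g, 1)), float(chi2.sf(w, 1)), False, bool(conv[0]),
    )


@dataclass
class EnvScanResults:
    table: pd.DataFrame  # one row per locus x variable
    n_loci: int
    n_variables: int
    n_tests: int
    n_completed: int
    confidence: float
    threshold: float
    significant_loci: list[str]
    dropped_monomorphic: list[str]
    excluded_individuals: list[str]

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def hits(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        pct = 100.0 * len(self.significant_loci) / max(self.n_loci, 1)
        return (
            f"Association scan: {self.n_loci} loci x {self.n_variables} variables, "
            f"{self.n_tests} tests, Bonferroni threshold {self.threshold:.3g} "
            f"(confidence {self.confidence}); {len(self.significant_loci)} "
            f"significant loci ({pct:.2f}%)"
        )


class EnvAssociationScan:
    """Genome scan of a marker matrix against an environmental table."""

    def __init__(
        self,
        markers: BinaryMarkerMatrix,
        env: EnvTable,
        samples: SampleTable,
    ):
        self.markers = markers
        self.env = env
        self.samples = samples

    def fit(
        self,
        confidence: float = 0.99,
        threshold_on_completed: bool = False,
        variables: list[str] | None = None,
    ) -> EnvScanResults:
        env_rows = self.env.for_samples(
            self.samples.subset(self.markers.individual_ids)
        )
        have_env = env_rows.notna().all(axis=1).to_numpy()
        excluded = [i for i, ok in zip(self.markers.individual_ids, have_env) if not ok]
        keep_idx = np.flatnonzero(have_env)
        if len(keep_idx) < 10:
            raise ValueError("fewer than 10 individuals with environmental data")
        markers = BinaryMarkerMatrix(
            [self.markers.individual_ids[i] for i in keep_idx],
            self.markers.locus_ids,
            self.markers.values[keep_idx],
        )
        markers, dropped = markers.drop_monomorphic()
        env_mat = env_rows.iloc[keep_idx]
        var_names = variables if variables is not None else list(env_mat.columns)
        usable = [v for v in var_names if env_mat[v].std() > 0]
        if not usable:
            raise ValueError("no usable (non-constant) environmental variables")
        Y = markers.values
        obs = markers.observed_mask()
        n_loci = markers.n_loci
        frames = []
        for v in usable:
            x = env_mat[v].to_numpy(dtype=float)
            (beta0, beta1, se, lnl_full, lnl_null,
             conv, sep, b1s, se1s) = _fit_logistic_batch(x, Y.T, obs.T)
            g = np.maximum(0.0, 2.0 * (lnl_full - lnl_null))
            with np.errstate(invalid="ignore", divide="ignore"):
                w = (b1s / se1s) ** 2
            p_g = np.where(sep, np.nan, chi2.sf(g, 1))
            p_w = np.where(sep, np.nan, chi2.sf(w, 1))
            frames.append(
                pd.DataFrame(
                    {
                        "locus_id": markers.locus_ids,
                        "variable": v,
                        "slope": beta1,
                        "se": np.where(sep, np.nan, se),
                        "g_stat": np.where(sep, np.nan, g),
                        "wald": np.where(sep, np.nan, w),
                        "p_g": p_g,
                        "p_wald": p_w,
                        "separated": sep,
                    }
                )
            )
        table = pd.concat(frames, ignore_index=True)
        n_tests = n_loci * len(usable)
        n_completed = int((~table["separated"]).sum())
        denom = n_completed if threshold_on_completed else n_tests
        threshold = (1.0 - confidence) / denom
        table["significant"] = (
            (table["p_g"] < threshold) & (table["p_wald"] < threshold)
        ).fillna(False)
        sig_loci = sorted(table.loc[table["significant"], "locus_id"].unique())
        return EnvScanResults(
            table,
            n_loci,
            len(usable),
            n_tests,
            n_completed,
            confidence,
            threshold,
            sig_loci,
            dropped,
            excluded,
        )


def sam_scan(
    markers: BinaryMarkerMatrix,
    env: EnvTable,
    samples: SampleTable,
    confidence: float = 0.99,
    **kwargs,
) -> EnvScanResults:
    """Functional wrapper around :class:`EnvAssociationScan`."""
    return EnvAssociationScan(markers, env, samples).fit(confidence, **kwargs)
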