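"""Quartile-intersection screen for gene-flow barriers and long-distance
dispersal.

Over all unordered individual pairs, barriers are suggested by pairs in both
the top quartile of genetic distance and the bottom quartile of geographic
distance (high divergence across a short distance); long-distance dispersal by
pairs in the bottom genetic and top geographic quartile (low divergence across
a long distance).  The screen is descriptive: no significance test is
attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Literal

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = ["PairScreenResult", "screen_pairs", "nearest_rank_percentile"]


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank empirical percentile: the ceil(qN)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty value vector")
    rank = max(1, ceil(q * len(v)))
    return float(v[rank - 1])


@dataclass
class PairScreenResult:
    mode: str  # "barrier" | "ldd"
    genetic_threshold: float
    geographic_threshold: float
    pairs: pd.DataFrame  # columns id_a, id_b, d_gen, d_geo
    n_pairs_total: int
    n_ties_genetic: int
    n_ties_geographic: int

    @property
    def n_flagged(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        df = self.pairs.copy()
        df["mode"] = self.mode
        return df

    def summary(self) -> str:
        return (
            f"{self.mode} screen: {self.n_flagged} of {self.n_pairs_total} pairs "
            f"flagged (genetic threshold {self.genetic_threshold:.6g}, "
            f"geographic threshold {self.geographic_threshold:.6g} km)"
        )


def screen_pairs(
    D_gen: DistanceMatrix,
    D_geo: DistanceMatrix,
    mode: Literal["barrier", "ldd"],
    quartile: Literal["nearest-rank", "interpolated"] = "nearest-rank",
    fraction: float = 0.25,
) -> PairScreenResult:
    """Flag pairs jointly extreme in genetic and geographic distance.

    ``fraction`` widens the screen symmetrically (0.25 = quartiles).
    Comparisons are inclusive (>= upper threshold, <= lower threshold), so
    ties at the threshold are flagged; tie counts are reported.
    """
    if D_gen.labels != D_geo.labels:
        if set(D_gen.labels) != set(D_geo.labels):
            raise ValueError("genetic and geographic matrices label mismatch")
        D_geo = D_geo.subset(D_gen.labels)
    n = D_gen.n
    if n < 4:
        raise ValueError("need at least 4 individuals")
    gen = D_gen.condensed()
    geo = D_geo.condensed()
    if np.isnan(gen).any() or np.isnan(geo).any():
        keep = ~(np.isnan(gen) | np.isnan(geo))
        gen, geo = gen[keep], geo[keep]
        index = [p for p, k in zip(D_gen.pair_index(), keep) if k]
    else:
        index = D_gen.pair_index()

    def pct(v, q):
        if quartile == "nearest-rank":
            return nearest_rank_percentile(v, q)
        if quartile == "interpolated":
            return float(np.percentile(v, 100 * q))
        raise ValueError(f"unknown quartile convention {quartile!r}")

    lo, hi = fraction, 1.0 - fraction
    if mode == "barrier":
        g_thr = pct(gen, hi)
        d_thr = pct(geo, lo)
        mask = (gen >= g_thr) & (geo <= d_thr)
    elif mode == "ldd":
        g_thr = pct(gen, lo)
        d_thr = pct(geo, hi)
        mask = (gen <= g_thr) & (geo >= d_thr)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = [
        {"id_a": a, "id_b": b, "d_gen": dg, "d_geo": dd}
        for (a, b), dg, dd, m in zip(index, gen, geo, mask)
        if m
    ]
    return PairScreenResult(
        mode,
        g_thr,
        d_thr,
        pd.DataFrame(rows, columns=["id_a", "id_b", "d_gen", "d_geo"]),
        len(gen),
        int((gen == g_thr).sum()),
        int((geo == d_thr).sum()),
    )
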