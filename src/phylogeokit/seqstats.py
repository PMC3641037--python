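"""Neutrality and demographic tests on a coding alignment.

Fu's Fs
-------
Let ``k_obs`` be the number of distinct haplotypes in a sample of ``n``
sequences and ``theta_pi`` the mean number of pairwise nucleotide differences.
Under the neutral constant-size coalescent the number of distinct alleles K
follows the Ewens sampling formula

    P(K = k | theta, n) = |S_n^k| theta^k / (theta (theta+1) ... (theta+n-1))

with ``|S_n^k|`` the unsigned Stirling numbers of the first kind.  Fu's
statistic is

    S' = P(K >= k_obs | theta = theta_pi),   Fs = ln(S' / (1 - S')).

A star-like genealogy left by a population expansion carries many more
haplotypes than theta_pi predicts, driving S' toward 0 and Fs strongly
negative.  Significance is assessed against neutral constant-size coalescent
simulations at theta = theta_pi (one-tailed, left: p = P(Fs_sim <= Fs_obs)).

McDonald-Kreitman
-----------------
Counts synonymous and nonsynonymous changes among sites polymorphic within the
ingroup and sites fixed between ingroup and outgroup, and tests the 2x2 table
with Fisher's exact test.  Under neutrality the nonsynonymous/synonymous ratio
is the same in both classes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from Bio.Data import CodonTable

from .io import CodingAlignment

__all__ = [
    "EwensDistribution",
    "FuFsResult",
    "MKResult",
    "theta_pi",
    "ewens_k_distribution",
    "fu_fs",
    "fs_from_summary",
    "mcdonald_kreitman",
    "simulate_neutral_fs",
]

#: NCBI translation table for the mitochondrial locus (invertebrate mito code)
DEFAULT_GENETIC_CODE = 5

FS_UNDEFINED = np.nan


def theta_pi(
    alignment: CodingAlignment,
    ingroup_only: bool = True,
    sites: str = "all",
) -> float:
    """Mean pairwise nucleotide differences (pairwise deletion of gaps/N).

    ``sites="third_positions"`` restricts to third codon positions, a common
    proxy for silent variation when a per-site synonymy classification is not
    wanted.
    """
    aln = alignment.ingroup() if ingroup_only else alignment
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    seqs = aln.sequences
    if sites == "third_positions":
        idx = np.arange(aln.frame_offset + 2, aln.length, 3)
        seqs = seqs[:, idx]
    elif sites != "all":
        raise ValueError(f"unknown sites option {sites!r}")
    ok = (seqs != b"-") & (seqs != b"N")
    n = aln.n_sequences
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            total += int(((seqs[i] != seqs[j]) & comp).sum())
            pairs += 1
    return total / pairs


@dataclass
class EwensDistribution:
    """Distribution of the number of distinct alleles under the Ewens formula."""

    n: int
    theta: float
    log_pmf: np.ndarray  # index k-1 -> log P(K = k)

    @property
    def pmf(self) -> np.ndarray:
        return np.exp(self.log_pmf)

    def sf(self, k: int) -> float:
        """P(K >= k)."""
        if k <= 1:
            return 1.0
        if k > self.n:
            return 0.0
        # sum the smaller tail in linear space for accuracy
        return float(np.exp(self.log_pmf[k - 1 :]).sum())


def _log_stirling_first_row(n: int) -> np.ndarray:
    """log |S_n^k| for k = 1..n via |S_{m+1}^k| = m |S_m^k| + |S_m^{k-1}|."""
    row = np.full(n, -np.inf)
    row[0] = 0.0  # |S_1^1| = 1
    for m in range(1, n):
        new = np.full(n, -np.inf)
        new[: m + 1] = np.logaddexp(
            row[: m + 1] + np.log(m),
            np.concatenate([[-np.inf], row[:m]]),
        )
        row = new
    return row


def ewens_k_distribution(n: int, theta: float) -> EwensDistribution:
    """Ewens sampling distribution of the allele count K in a sample of n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if n == 1:
        return EwensDistribution(1, theta, np.zeros(1))
    log_stirling = _log_stirling_first_row(n)
    k = np.arange(1, n + 1)
    log_rising = np.log(theta + np.arange(n)).sum()
    log_pmf = log_stirling + k * np.log(theta) - log_rising
    return EwensDistribution(n, theta, log_pmf)


def _haplotype_count(alignment: CodingAlignment) -> int:
    """Distinct sequences after removing columns containing any gap."""
    seqs = alignment.sequences
    keep = ~(seqs == b"-").any(axis=0)
    stripped = seqs[:, keep]
    return len({row.tobytes() for row in stripped})


def fs_from_summary(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs from sample size, haplotype count and theta (from pi)."""
    if theta <= 0 or k_obs <= 1:
        return FS_UNDEFINED
    dist = ewens_k_distribution(n, theta)
    s_prime = dist.sf(k_obs)
    if s_prime <= 0.0 or s_prime >= 1.0:
        return FS_UNDEFINED
    return float(np.log(s_prime / (1.0 - s_prime)))


@dataclass
class FuFsResult:
    n: int
    k_obs: int
    theta_pi: float
    s_prime: float
    fs: float
    p_value: float
    n_simulations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def summary(self) -> str:
        return (
            f"Fu's Fs: n={self.n}, k={self.k_obs}, theta_pi={self.theta_pi:.4f}, "
            f"Fs={self.fs:.4f}, p={self.p_value:.4g} "
            f"({self.n_simulations} coalescent simulations)"
        )


def simulate_neutral_fs(
    n: int, theta: float, n_simulations: int, seed: int
) -> np.ndarray:
    """Fs values from neutral constant-size infinite-sites coalescent samples.

    Genealogies and mutations come from msprime (haploid samples, N = 1, so
    time is in coalescent units and the per-tree mutation rate theta/2 gives
    E[pairwise differences] = theta).  For each replicate, theta is
    re-estimated from pi and Fs recomputed exactly as for the observed data.
    """
    import msprime

    seed = int(seed) % (2**31 - 2) + 1
    anc = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=1.0,
        sequence_length=1.0,
        num_replicates=n_simulations,
        random_seed=seed,
    )
    rng = np.random.default_rng(seed)
    out = np.empty(n_simulations)
    for r, ts in enumerate(anc):
        mts = msprime.sim_mutations(
            ts,
            rate=theta / 2.0,
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        if mts.num_sites == 0:
            out[r] = FS_UNDEFINED
            continue
        g = mts.genotype_matrix()  # sites x samples
        pi_sim = float(mts.diversity(span_normalise=False))
        k_sim = len({col.tobytes() for col in np.ascontiguousarray(g.T)})
        out[r] = fs_from_summary(n, k_sim, pi_sim)
    return out


def fu_fs(
    alignment: CodingAlignment,
    n_simulations: int = 1000,
    seed: int = 0,
    theta_sites: str = "all",
) -> FuFsResult:
    """Fu's Fs with a coalescent-simulation p-value (one-tailed, left).

    ``theta_sites`` selects the sites used for the theta-from-pi estimate
    ("all" or "third_positions"); haplotypes are always counted on the full
    sequences.
    """
    aln = alignment.ingroup()
    if aln.n_sequences < 3:
        raise ValueError("need at least 3 ingroup sequences")
    n = aln.n_sequences
    pi = theta_pi(alignment, sites=theta_sites)
    k_obs = _haplotype_count(aln)
    if k_obs == 1 or pi == 0:
        warnings.warn("single haplotype: Fu's Fs undefined")
        return FuFsResult(n, k_obs, pi, 1.0, FS_UNDEFINED, 1.0, 0)
    dist = ewens_k_distribution(n, pi)
    s_prime = dist.sf(k_obs)
    fs = fs_from_summary(n, k_obs, pi)
    sims = simulate_neutral_fs(n, pi, n_simulations, seed)
    sims = sims[np.isfinite(sims)]
    p = (1 + int((sims <= fs).sum())) / (1 + len(sims)) if len(sims) else np.nan
    return FuFsResult(n, k_obs, pi, float(s_prime), fs, float(p), n_simulations)


# --- McDonald-Kreitman -------------------------------------------------------


def _codon_change_counts(c1: str, c2: str, table) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) steps over minimal mutational paths.

    Paths passing through stop codons are discarded; returns None if every
    path is blocked.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur = list(c1)
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = list(cur)
            nxt[pos] = c2[pos]
            a, b = "".join(cur), "".join(nxt)
            if b in table.stop_codons and b != c2:
                ok = False
                break
            aa_a = "*" if a in table.stop_codons else table.forward_table.get(a)
            aa_b = "*" if b in table.stop_codons else table.forward_table.get(b)
            if aa_a is None or aa_b is None:
                ok = False
                break
            if aa_a == aa_b:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    if not results:
        return None
    syn = float(np.mean([r[0] for r in results]))
    nonsyn = float(np.mean([r[1] for r in results]))
    return syn, nonsyn


@dataclass
class MKResult:
    syn_poly: float
    nonsyn_poly: float
    syn_fixed: float
    nonsyn_fixed: float
    p_value: float
    excluded_codons: pd.DataFrame = field(default_factory=pd.DataFrame)

    def table(self) -> np.ndarray:
        return np.array(
            [[self.syn_poly, self.nonsyn_poly], [self.syn_fixed, self.nonsyn_fixed]]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "syn_poly": self.syn_poly,
                    "nonsyn_poly": self.nonsyn_poly,
                    "syn_fixed": self.syn_fixed,
                    "nonsyn_fixed": self.nonsyn_fixed,
                    "fisher_p": self.p_value,
                }
            ]
        )

    def summary(self) -> str:
        return (
            f"McDonald-Kreitman: poly S/N = {self.syn_poly:.2f}/{self.nonsyn_poly:.2f}, "
            f"fixed S/N = {self.syn_fixed:.2f}/{self.nonsyn_fixed:.2f}, "
            f"Fisher exact p = {self.p_value:.4g}"
        )


def mcdonald_kreitman(
    alignment: CodingAlignment, genetic_code: int = DEFAULT_GENETIC_CODE
) -> MKResult:
    """McDonald-Kreitman test of neutral evolution of a coding locus.

    Polymorphic = variable within the ingroup; fixed = monomorphic within each
    group but different between them (codons polymorphic in the outgroup are
    excluded from the fixed class).  Codons with gaps/N or more than two states
    in a comparison are excluded and logged.
    """
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    ing = [s for s, o in zip(alignment.as_strings(), alignment.is_outgroup) if not o]
    out = [s for s, o in zip(alignment.as_strings(), alignment.is_outgroup) if o]
    if len(ing) < 2:
        raise ValueError("need >= 2 ingroup sequences")
    if len(out) < 1:
        raise ValueError("need >= 1 outgroup sequence")
    off = alignment.frame_offset
    L = (alignment.length - off) // 3
    syn_poly = nonsyn_poly = syn_fixed = nonsyn_fixed = 0.0
    excluded = []
    for c in range(L):
        s, e = off + 3 * c, off + 3 * c + 3
        cod_in = [seq[s:e] for seq in ing]
        cod_out = [seq[s:e] for seq in out]
        all_cod = cod_in + cod_out
        if any(ch in cod for cod in all_cod for ch in "-N"):
            excluded.append({"codon": c + 1, "reason": "gap_or_ambiguous"})
            continue
        # internal stop in a sequence marks a frame violation
        if any(cod in table.stop_codons for cod in all_cod) and c < L - 1:
            raise ValueError(f"internal stop codon at codon {c + 1}: frame violation")
        states_in = sorted(set(cod_in))
        states_out = sorted(set(cod_out))
        if len(states_in) > 2:
            excluded.append({"codon": c + 1, "reason": "more_than_two_ingroup_states"})
            continue
        if len(states_in) == 2:
            counts = _codon_change_counts(states_in[0], states_in[1], table)
            if counts is None:
                excluded.append({"codon": c + 1, "reason": "all_paths_through_stop"})
                continue
            syn_poly += counts[0]
            nonsyn_poly += counts[1]
            continue
        if len(states_out) > 1:
            excluded.append({"codon": c + 1, "reason": "outgroup_polymorphic"})
            continue
        if states_in[0] != states_out[0]:
            counts = _codon_change_counts(states_in[0], states_out[0], table)
            if counts is None:
                excluded.append({"codon": c + 1, "reason": "all_paths_through_stop"})
                continue
            syn_fixed += counts[0]
            nonsyn_fixed += counts[1]
    # Fisher's exact test needs integer counts; fractional pathway averages are
    # rounded to the nearest integer (they arise only for multi-step codons)
    cont = np.rint(
        [[syn_poly, nonsyn_poly], [syn_fixed, nonsyn_fixed]]
    ).astype(int)
    if cont.sum() == 0:
        p = 1.0
    else:
        _, p = fisher_exact(cont, alternative="two-sided")
    return MKResult(
        syn_poly,
        nonsyn_poly,
        syn_fixed,
        nonsyn_fixed,
        float(p),
        pd.DataFrame(excluded, columns=["codon", "reason"]),
    )
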