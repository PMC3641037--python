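"""Spatially explicit synthetic datasets with the structure the analysis
chain assumes.

The generator emulates a widespread low-dispersal species on an elongated
island: the map is an east-west rectangle partitioned into contiguous cluster
regions by north-south barrier lines.  Within each cluster, latent band
frequencies drift linearly with distance from the cluster centroid (isolation
by distance); individuals near a barrier receive mixed ancestry
(admixture zone); a small fraction of individuals is relocated to a distant
locality with genotype intact (long-distance dispersal by passive transport);
and a handful of loci follow an environmental gradient through a logistic
presence probability (selected loci).  Mitochondrial-style coding sequences
descend from per-cluster coalescent genealogies with exponential growth
(star-like under strong growth), deep between-cluster splits, and two
outgroup sequences on a long external branch.  Nonsynonymous changes are
down-weighted by the same factor on every branch, so the
McDonald-Kreitman null holds by construction.

All randomness flows from ``SimulationConfig.seed`` through a splittable
generator; a fixed config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import BinaryMarkerMatrix, CodingAlignment, EnvTable, SampleTable

__all__ = [
    "SimulationConfig",
    "Landscape",
    "simulate_landscape",
    "simulate_aflp",
    "simulate_sequences",
    "simulate_dataset",
]

# anchor of the synthetic map in WGS84 (an elongated Mediterranean island)
_LAT0, _LON0 = 35.0, 23.5
_KM_PER_DEG = 111.195


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated survey:
    95 individuals at 84 localities in 5 clusters, 1328 dominant loci, a
    633-bp coding locus, strong post-expansion genealogies, rare
    long-distance dispersal, and 4 environment-driven loci among 8 smooth
    environmental surfaces."""

    n_clusters: int = 5
    n_individuals: int = 95
    n_loci: int = 1328
    n_localities: int = 84
    map_extent: tuple[float, float] = (260.0, 60.0)  # km (width, height)
    barrier_segments: list | None = None  # [((x, y0), (x, y1)), ...]; None = even
    ibd_gradient_strength: float = 0.002  # band-frequency drift per km
    admixture_zone_width: float = 15.0  # km
    ldd_rate: float = 0.05  # per-individual relocation probability
    n_env_selected_loci: int = 4
    env_effect_size: float = 2.0  # log-odds per (standardised) env unit
    n_env_variables: int = 8
    seq_length: int = 633  # bp, codon multiple
    theta: float = 40.0  # scaled mutation rate (expected pairwise diffs)
    growth_factor: float = 100.0  # fold population expansion (<= 1 = constant)
    cluster_split_time: float = 0.5  # coalescent units (per ancestral size)
    outgroup_split_time: float = 1.5
    kappa: float = 4.0  # transition/transversion rate bias
    omega: float = 0.2  # nonsynonymous acceptance probability
    genetic_code: int = 5  # NCBI table (invertebrate mitochondrial)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.seq_length % 3 != 0:
            raise ValueError("seq_length must be a codon multiple")
        for name in ("ldd_rate", "missing_rate", "omega"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_localities < self.n_clusters:
            raise ValueError("need at least one locality per cluster")

    def spawn_rngs(self, n: int, stage: str) -> list[np.random.Generator]:
        import zlib

        key = zlib.crc32(stage.encode())  # stable across processes
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return [np.random.default_rng(s) for s in ss.spawn(n)]

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "map_extent" in raw:
            raw["map_extent"] = tuple(raw["map_extent"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["map_extent"] = list(self.map_extent)
        return d


@dataclass
class Landscape:
    """Localities, cluster regions and environmental surfaces on the map."""

    localities: pd.DataFrame  # locality_id, x, y, lat, lon, region
    region_breaks: np.ndarray  # x positions separating regions (sorted)
    env: pd.DataFrame  # locality_id index, one column per env variable
    map_extent: tuple[float, float]

    @property
    def n_regions(self) -> int:
        return len(self.region_breaks) + 1

    def region_of(self, x: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.region_breaks, x)

    def centroids(self) -> np.ndarray:
        """Region centroid x positions."""
        edges = np.concatenate([[0.0], self.region_breaks, [self.map_extent[0]]])
        return (edges[:-1] + edges[1:]) / 2


def _region_breaks(config: SimulationConfig) -> np.ndarray:
    width = config.map_extent[0]
    if config.barrier_segments:
        xs = sorted({float(np.mean([p[0] for p in seg])) for seg in config.barrier_segments})
        if any(not 0 < x < width for x in xs):
            raise ValueError("barrier segment outside the map")
        if len(xs) + 1 != config.n_clusters:
            raise ValueError(
                f"{len(xs)} barriers partition the map into {len(xs) + 1} regions, "
                f"but n_clusters = {config.n_clusters}"
            )
        return np.asarray(xs)
    if config.n_clusters == 1:
        return np.asarray([])
    min_width = 2.0  # km; narrower slabs cannot hold distinct regions
    if width / config.n_clusters < min_width:
        raise ValueError(
            f"cannot tile a {width} km map into {config.n_clusters} regions"
        )
    return np.linspace(0, width, config.n_clusters + 1)[1:-1]


def _to_latlon(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat = _LAT0 + y / _KM_PER_DEG
    lon = _LON0 + x / (_KM_PER_DEG * np.cos(np.radians(_LAT0)))
    return lat, lon


def simulate_landscape(config: SimulationConfig) -> Landscape:
    """Scatter localities in barrier-separated regions and lay env surfaces."""
    rng_loc, rng_env = config.spawn_rngs(2, "landscape")
    breaks = _region_breaks(config)
    width, height = config.map_extent
    edges = np.concatenate([[0.0], breaks, [width]])
    widths = np.diff(edges)
    # at least one locality per region, remainder proportional to area
    counts = np.ones(config.n_clusters, dtype=int)
    extra = config.n_localities - config.n_clusters
    if extra > 0:
        shares = np.floor(extra * widths / widths.sum()).astype(int)
        counts += shares
        for i in range(config.n_localities - counts.sum()):
            counts[i % config.n_clusters] += 1
    xs, ys, regions = [], [], []
    for r, (lo, hi, c) in enumerate(zip(edges[:-1], edges[1:], counts)):
        xs.append(rng_loc.uniform(lo, hi, c))
        ys.append(rng_loc.uniform(0, height, c))
        regions.append(np.full(c, r))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    region = np.concatenate(regions)
    lat, lon = _to_latlon(x, y)
    loc_ids = [f"L{i + 1:03d}" for i in range(len(x))]
    localities = pd.DataFrame(
        {"locality_id": loc_ids, "x": x, "y": y, "lat": lat, "lon": lon,
         "region": region}
    )
    # smooth environmental surfaces: quadratic polynomial in (x, y) + noise,
    # standardised per variable; the first variable is a clean west-east
    # gradient used for the selected loci
    xn = (x - width / 2) / width
    yn = (y - height / 2) / max(height, 1.0)
    env_cols = {}
    for v in range(config.n_env_variables):
        if v == 0:
            surf = xn + rng_env.normal(0, 0.05, len(x))
        else:
            c = rng_env.normal(0, 1, 6)
            surf = (
                c[0] + c[1] * xn + c[2] * yn + c[3] * xn**2 + c[4] * yn**2
                + c[5] * xn * yn + rng_env.normal(0, 0.1, len(x))
            )
        surf = (surf - surf.mean()) / surf.std()
        env_cols[f"env{v + 1}"] = surf
    env = pd.DataFrame(env_cols, index=pd.Index(loc_ids, name="locality_id"))
    if not np.isfinite(env.to_numpy()).all():
        raise RuntimeError("non-finite environmental surface")
    return Landscape(localities, breaks, env, config.map_extent)


def simulate_aflp(
    landscape: Landscape,
    config: SimulationConfig,
    drop_monomorphic: bool = False,
):
    """Binary marker matrix plus ground truth.

    Returns ``(markers, samples, truth)`` where truth carries the latent
    admixture proportions, cluster band frequencies, selected-locus indices
    and relocated (LDD) individuals.
    """
    if config.n_loci < 1 or config.n_individuals < 1:
        raise ValueError("need at least one locus and one individual")
    (rng_assign, rng_freq, rng_geno, rng_sel, rng_ldd,
     rng_miss) = config.spawn_rngs(6, "aflp")
    K, L, n = config.n_clusters, config.n_loci, config.n_individuals
    loc = landscape.localities
    # individuals scattered over localities (several per locality allowed)
    loc_idx = rng_assign.integers(0, len(loc), n)
    x = loc["x"].to_numpy()[loc_idx]
    region = loc["region"].to_numpy()[loc_idx]
    centroids = landscape.centroids()
    edges = np.concatenate([[0.0], landscape.region_breaks,
                            [landscape.map_extent[0]]])

    # latent band frequencies: U-shaped Beta concentrates loci near fixation
    p = rng_freq.beta(0.5, 0.5, size=(K, L))
    ibd_sign = rng_freq.choice([-1.0, 1.0], size=L)

    # admixture proportions: linear decay into the neighbouring region
    q = np.zeros((n, K))
    q[np.arange(n), region] = 1.0
    w = config.admixture_zone_width
    if w > 0 and K > 1:
        for i in range(n):
            r = region[i]
            for b, xb in enumerate(landscape.region_breaks):
                d = abs(x[i] - xb)
                if d < w:
                    other = b + 1 if x[i] <= xb else b
                    if other == r:
                        other = b if x[i] <= xb else b + 1
                    share = 0.5 * (1.0 - d / w)
                    q[i, other] += share
        q /= q.sum(axis=1, keepdims=True)

    # genotypes: per call choose a source cluster, then a band with the
    # IBD-shifted frequency of that cluster
    z = (q.cumsum(axis=1)[:, None, :] < rng_geno.random((n, L, 1))).sum(axis=2)
    z = np.minimum(z, K - 1)
    dx = x[:, None] - centroids[None, :]  # (n, K)
    shift = config.ibd_gradient_strength * dx[np.arange(n)[:, None], z] * ibd_sign[None, :]
    p_eff = np.clip(p[z, np.arange(L)[None, :]] + shift, 0.01, 0.99)
    xmat = (rng_geno.random((n, L)) < p_eff).astype(np.int8)

    # environment-selected loci override the cluster model
    sel = np.sort(rng_sel.choice(L, size=config.n_env_selected_loci, replace=False))
    env1 = landscape.env["env1"].to_numpy()[loc_idx]
    if config.n_env_selected_loci:
        logits = config.env_effect_size * (env1 - env1.mean())
        prob = 1.0 / (1.0 + np.exp(-logits))
        xmat[:, sel] = (rng_sel.random((n, len(sel))) < prob[:, None]).astype(np.int8)

    # long-distance dispersal: genotype travels, locality changes
    ldd = np.flatnonzero(rng_ldd.random(n) < config.ldd_rate)
    min_jump = landscape.map_extent[0] / 2
    for i in ldd:
        far = np.flatnonzero(np.abs(loc["x"].to_numpy() - x[i]) > min_jump)
        if len(far) == 0:
            continue
        loc_idx[i] = rng_ldd.choice(far)

    if config.missing_rate > 0:
        miss = rng_miss.random((n, L)) < config.missing_rate
        xmat[miss] = -1

    ind_ids = [f"ind{i + 1:03d}" for i in range(n)]
    markers = BinaryMarkerMatrix(ind_ids, [f"locus{j + 1:04d}" for j in range(L)], xmat)
    dropped: list[str] = []
    if drop_monomorphic:
        markers, dropped = markers.drop_monomorphic()
    samples = SampleTable(
        pd.DataFrame(
            {
                "individual_id": ind_ids,
                "locality_id": loc["locality_id"].to_numpy()[loc_idx],
                "latitude": loc["lat"].to_numpy()[loc_idx],
                "longitude": loc["lon"].to_numpy()[loc_idx],
                "cluster_label": region + 1,
            }
        )
    )
    truth = {
        "q_true": q,
        "p_true": p,
        "cluster_true": region + 1,
        "selected_loci": sel,
        "selected_locus_ids": [f"locus{j + 1:04d}" for j in sel],
        "ldd_individuals": [ind_ids[i] for i in ldd],
        "dropped_monomorphic": dropped,
    }
    return markers, samples, truth


# --- coding-sequence simulation ---------------------------------------------


def _sense_codons(code_id: int) -> list[str]:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    return sorted(table.forward_table)


def _mutate_sequence(
    seq: np.ndarray,
    branch_length: float,
    rate: float,
    config: SimulationConfig,
    table,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one sequence along a branch with transition bias and the
    nonsynonymous thinning that enforces the neutral MK structure."""
    bases = "ACGT"
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    out = seq.copy()
    n_events = rng.poisson(branch_length * rate)
    L = len(seq)
    for _ in range(n_events):
        pos = int(rng.integers(L))
        cur = out[pos]
        ti = transitions[cur]
        tv = [b for b in bases if b != cur and b != ti]
        weights = np.array([config.kappa, 1.0, 1.0])
        new = rng.choice([ti, tv[0], tv[1]], p=weights / weights.sum())
        c0 = 3 * (pos // 3)
        codon = "".join(out[c0 : c0 + 3])
        newcodon = codon[: pos - c0] + new + codon[pos - c0 + 1 :]
        if newcodon in table.stop_codons:
            continue
        syn = table.forward_table[codon] == table.forward_table[newcodon]
        if not syn and rng.random() >= config.omega:
            continue
        out[pos] = new
    return out


def simulate_sequences(
    landscape: Landscape,
    config: SimulationConfig,
    samples: SampleTable | None = None,
) -> CodingAlignment:
    """Coding alignment from per-cluster expansion genealogies plus outgroups.

    If ``samples`` carries a ``cluster_label`` column, one ingroup sequence is
    generated per individual (grouped by cluster); otherwise individuals are
    split evenly over the clusters.
    """
    import msprime

    if config.theta <= 0:
        raise ValueError("theta must be > 0")
    rng_tree, rng_mut = config.spawn_rngs(2, "sequences")
    K = config.n_clusters
    if samples is not None and "cluster_label" in samples.data.columns:
        ids = samples.individual_ids
        clusters = samples.data["cluster_label"].astype(int).to_numpy()
    else:
        ids = [f"ind{i + 1:03d}" for i in range(config.n_individuals)]
        clusters = np.arange(config.n_individuals) % K + 1
    # growth_factor F is the fold expansion of each cluster population over
    # the recent past: present size F shrinking exponentially back to the
    # ancestral size 1 by half the split time.  Large F concentrates all
    # within-cluster coalescence at the collapse, leaving the long equal tips
    # of a star genealogy; F <= 1 means constant size.
    F = max(config.growth_factor, 1.0)
    t_growth = config.cluster_split_time / 2.0
    growth_rate = np.log(F) / t_growth if F > 1.0 else 0.0
    demography = msprime.Demography()
    for k in range(K):
        demography.add_population(
            name=f"pop{k}", initial_size=F, growth_rate=growth_rate
        )
    demography.add_population(name="anc", initial_size=1.0)
    demography.add_population(name="outg", initial_size=1.0)
    demography.add_population(name="root", initial_size=1.0)
    demography.add_population_split(
        time=config.cluster_split_time,
        derived=[f"pop{k}" for k in range(K)],
        ancestral="anc",
    )
    demography.add_population_split(
        time=config.outgroup_split_time, derived=["anc", "outg"], ancestral="root"
    )
    sample_sets = [
        msprime.SampleSet(int((clusters == k + 1).sum()), population=f"pop{k}", ploidy=1)
        for k in range(K)
    ] + [msprime.SampleSet(2, population="outg", ploidy=1)]
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=demography,
        sequence_length=1.0,
        ploidy=1,
        random_seed=int(rng_tree.integers(1, 2**31 - 1)),
    )
    tree = ts.first()
    table = CodonTable.unambiguous_dna_by_id[config.genetic_code]
    sense = _sense_codons(config.genetic_code)
    n_codons = config.seq_length // 3
    root_seq = np.array(
        list("".join(rng_mut.choice(sense) for _ in range(n_codons)))
    )
    rate = config.theta / 2.0  # per-sequence candidate-event rate per unit time
    seqs: dict[int, np.ndarray] = {}
    order = [tree.root] + [v for v in tree.nodes(order="preorder") if v != tree.root]
    for node in order:
        if node == tree.root:
            seqs[node] = root_seq
            continue
        parent = tree.parent(node)
        seqs[node] = _mutate_sequence(
            seqs[parent], tree.branch_length(node), rate, config, table, rng_mut
        )
    # leaf j in sample order: ingroup ids sorted by cluster, then 2 outgroups
    ordered_ids = [i for k in range(K) for i, c in zip(ids, clusters) if c == k + 1]
    ordered_ids += ["outgroup1", "outgroup2"]
    rows = [seqs[leaf] for leaf in range(len(ordered_ids))]
    mat = np.array(["".join(r) for r in rows], dtype=f"S{config.seq_length}")
    mat = mat.view("S1").reshape(len(ordered_ids), config.seq_length)
    flags = np.zeros(len(ordered_ids), dtype=bool)
    flags[-2:] = True
    return CodingAlignment(ordered_ids, mat, 0, flags)


def simulate_dataset(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    drop_monomorphic: bool = False,
) -> dict:
    """Run the full generator; optionally write the standard input bundle.

    The bundle comprises markers.tsv, samples.tsv, env.tsv, alignment.fasta,
    truth.tsv and config.json.
    """
    landscape = simulate_landscape(config)
    markers, samples, truth = simulate_aflp(landscape, config, drop_monomorphic)
    alignment = simulate_sequences(landscape, config, samples)
    env = EnvTable(landscape.env.copy())
    out = {
        "landscape": landscape,
        "markers": markers,
        "samples": samples,
        "alignment": alignment,
        "env": env,
        "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        markers.to_tsv(outdir / "markers.tsv")
        samples.to_tsv(outdir / "samples.tsv")
        env.to_tsv(outdir / "env.tsv")
        alignment.to_fasta(outdir / "alignment.fasta")
        truth_df = pd.DataFrame(
            {
                "individual_id": markers.individual_ids,
                "cluster_true": truth["cluster_true"],
                "is_ldd": [
                    i in set(truth["ldd_individuals"]) for i in markers.individual_ids
                ],
                **{
                    f"q{k + 1}": truth["q_true"][:, k]
                    for k in range(truth["q_true"].shape[1])
                },
            }
        )
        truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                        float_format="%.6g")
        (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    return out
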