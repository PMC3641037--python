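import numpy as np
import pytest

from phylogeokit.distances import jaccard_matrix
from phylogeokit.envscan import _fit_logistic_batch
from phylogeokit.simulate import (
    SimulationConfig,
    simulate_aflp,
    simulate_dataset,
    simulate_landscape,
    simulate_sequences,
)


class TestLandscape:
    def test_single_cluster_no_barriers(self):
        conf = SimulationConfig(seed=0, n_clusters=1, n_localities=10,
                                n_individuals=10)
        land = simulate_landscape(conf)
        assert land.n_regions == 1
        assert (land.localities["region"] == 0).all()

    def test_determinism(self):
        conf = SimulationConfig(seed=5, n_individuals=20, n_localities=12)
        l1 = simulate_landscape(conf)
        l2 = simulate_landscape(conf)
        assert l1.localities.equals(l2.localities)
        assert l1.env.equals(l2.env)

    def test_five_regions_separated_beyond_admixture_zone(self):
        conf = SimulationConfig(seed=1)
        land = simulate_landscape(conf)
        assert land.n_regions == 5
        c = land.centroids()
        gaps = np.abs(c[:, None] - c[None, :])[np.triu_indices(5, 1)]
        assert gaps.min() > conf.admixture_zone_width

    def test_untileable_map_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            simulate_landscape(
                SimulationConfig(seed=0, n_clusters=200, n_localities=300,
                                 map_extent=(100.0, 10.0))
            )

    def test_explicit_barriers_must_match_clusters(self):
        conf = SimulationConfig(
            seed=0, n_clusters=3,
            barrier_segments=[((100.0, 0.0), (100.0, 60.0))],
        )
        with pytest.raises(ValueError, match="n_clusters"):
            simulate_landscape(conf)


class TestAflp:
    def test_determinism_byte_identical(self, tmp_path):
        conf = SimulationConfig(seed=9, n_individuals=15, n_loci=40,
                                n_localities=10, seq_length=120)
        simulate_dataset(conf, tmp_path / "a")
        simulate_dataset(conf, tmp_path / "b")
        for name in ("markers.tsv", "samples.tsv", "env.tsv",
                     "alignment.fasta", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_cluster_structure_in_jaccard(self):
        # no IBD, no admixture: within-cluster < between-cluster distance
        conf = SimulationConfig(
            seed=3, n_individuals=40, n_loci=150, n_localities=20,
            n_clusters=2, ibd_gradient_strength=0.0, admixture_zone_width=0.0,
            ldd_rate=0.0, n_env_selected_loci=0,
        )
        land = simulate_landscape(conf)
        markers, samples, truth = simulate_aflp(land, conf)
        D = jaccard_matrix(markers).values
        groups = truth["cluster_true"]
        iu = np.triu_indices(len(groups), 1)
        same = groups[iu[0]] == groups[iu[1]]
        assert D[iu][same].mean() < D[iu][~same].mean()

    def test_frequency_recovery_large_sample(self):
        # one cluster, no drift/selection: observed band frequencies within
        # 3 binomial SE of the latent frequencies for >= 95% of loci
        conf = SimulationConfig(
            seed=4, n_clusters=1, n_individuals=600, n_loci=300,
            n_localities=30, ibd_gradient_strength=0.0,
            admixture_zone_width=0.0, ldd_rate=0.0, n_env_selected_loci=0,
        )
        land = simulate_landscape(conf)
        markers, _, truth = simulate_aflp(land, conf)
        p = np.clip(truth["p_true"][0], 0.01, 0.99)
        obs = markers.values.mean(axis=0)
        se = np.sqrt(p * (1 - p) / conf.n_individuals)
        within = np.abs(obs - p) <= 3 * se
        assert within.mean() >= 0.95

    def test_null_effect_size_gives_null_slopes(self):
        # env_effect_size 0: the "selected" loci carry no association; the
        # logistic slope CI covers 0 in nearly all replicates
        cover = 0
        n_rep = 100
        for rep in range(n_rep):
            conf = SimulationConfig(
                seed=1000 + rep, n_clusters=1, n_individuals=90, n_loci=2,
                n_localities=30, n_env_selected_loci=1, env_effect_size=0.0,
                ibd_gradient_strength=0.0, admixture_zone_width=0.0,
                ldd_rate=0.0,
            )
            land = simulate_landscape(conf)
            markers, samples, truth = simulate_aflp(land, conf)
            j = truth["selected_loci"][0]
            y = markers.values[:, j]
            loc_idx = samples.data["locality_id"]
            env = land.env.loc[loc_idx, "env1"].to_numpy()
            if y.min() == y.max():
                cover += 1  # monomorphic: no evidence of association either
                continue
            (_, b1, se, *_rest) = _fit_logistic_batch(
                env, y[None, :], np.ones((1, len(y)), bool)
            )
            if not np.isfinite(se[0]) or abs(b1[0]) <= 1.96 * se[0]:
                cover += 1
        assert cover >= 94

    def test_zero_sizes_rejected(self):
        conf = SimulationConfig(seed=0, n_individuals=10, n_localities=10)
        land = simulate_landscape(conf)
        conf2 = SimulationConfig(seed=0, n_individuals=10, n_loci=0,
                                 n_localities=10)
        with pytest.raises(ValueError):
            simulate_aflp(land, conf2)


class TestSequences:
    def test_no_mutation_limit(self):
        conf = SimulationConfig(
            seed=2, n_clusters=1, n_individuals=8, n_localities=4,
            theta=1e-9, seq_length=90,
        )
        land = simulate_landscape(conf)
        aln = simulate_sequences(land, conf)
        ing = aln.ingroup()
        assert len({s for s in ing.as_strings()}) == 1

    def test_theta_validation(self):
        conf = SimulationConfig(seed=2, n_clusters=1, n_individuals=4,
                                n_localities=4)
        land = simulate_landscape(conf)
        conf.theta = -1.0
        with pytest.raises(ValueError, match="theta"):
            simulate_sequences(land, conf)

    def test_outgroups_on_long_branch(self):
        conf = SimulationConfig(seed=6, n_clusters=2, n_individuals=10,
                                n_localities=6, seq_length=300, theta=10.0)
        land = simulate_landscape(conf)
        aln = simulate_sequences(land, conf)
        assert aln.is_outgroup.sum() == 2
        seqs = aln.sequences
        ing = seqs[~aln.is_outgroup]
        out = seqs[aln.is_outgroup]
        d_in = np.mean([(a != b).mean() for i, a in enumerate(ing)
                        for b in ing[i + 1:]])
        d_out = np.mean([(a != b).mean() for a in ing for b in out])
        assert d_out > d_in

    def test_alignment_is_gap_free_codon_clean(self, small_bundle):
        aln = small_bundle["alignment"]
        assert not (aln.sequences == b"-").any()
        assert aln.length % 3 == 0


def test_config_validation():
    with pytest.raises(ValueError, match="codon"):
        SimulationConfig(seq_length=100)
    with pytest.raises(ValueError, match="ldd_rate"):
        SimulationConfig(ldd_rate=1.5)
    with pytest.raises(ValueError, match="n_clusters"):
        SimulationConfig(n_clusters=0)


def test_config_file_round_trip(tmp_path):
    conf = SimulationConfig(seed=3, n_individuals=10, n_localities=8)
    import json

    (tmp_path / "c.json").write_text(json.dumps(conf.to_dict()))
    back = SimulationConfig.from_file(tmp_path / "c.json")
    assert back == conf
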