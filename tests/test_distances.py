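import numpy as np
import pandas as pd
import pytest

from phylogeokit.distances import (
    DistanceMatrix,
    SubstitutionModel,
    fit_gtr_gamma,
    geographic_matrix,
    gtr_gamma_matrix,
    jaccard_matrix,
)
from phylogeokit.io import BinaryMarkerMatrix, CodingAlignment, SampleTable

from conftest import alignment_from_strings


def brute_force_jaccard(x, y):
    """Set-based oracle with pairwise deletion of missing calls."""
    a = b = c = 0
    for xi, yi in zip(x, y):
        if xi < 0 or yi < 0:
            continue
        if xi == 1 and yi == 1:
            a += 1
        elif xi == 1:
            b += 1
        elif yi == 1:
            c += 1
    return 0.0 if a + b + c == 0 else 1 - a / (a + b + c)


class TestJaccard:
    def test_hand_example(self):
        m = BinaryMarkerMatrix(
            ["x", "y"], [f"l{i}" for i in range(4)],
            np.array([[1, 1, 0, 0], [1, 0, 1, 0]]),
        )
        d = jaccard_matrix(m).values[0, 1]
        assert d == pytest.approx(1 - 1 / 3, abs=1e-12)

    def test_identity_and_disjoint(self):
        m = BinaryMarkerMatrix(
            ["x", "y", "z"], [f"l{i}" for i in range(4)],
            np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]]),
        )
        D = jaccard_matrix(m).values
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.integers(0, 2, size=(10, 20)).astype(np.int8)
            # sprinkle missing calls, keeping every row partly observed
            miss = rng.random((10, 20)) < 0.1
            x[miss] = -1
            x[:, 0] = 1  # guarantee no all-missing individual
            m = BinaryMarkerMatrix(
                [f"i{i}" for i in range(10)], [f"l{j}" for j in range(20)], x
            )
            D = jaccard_matrix(m).values
            for i in range(10):
                for j in range(i + 1, 10):
                    assert D[i, j] == pytest.approx(
                        brute_force_jaccard(x[i], x[j]), abs=1e-12
                    )

    def test_all_missing_individual_rejected(self):
        x = np.array([[1, 0], [-1, -1]], dtype=np.int8)
        m = BinaryMarkerMatrix(["a", "b"], ["l1", "l2"], x)
        with pytest.raises(ValueError, match="missing"):
            jaccard_matrix(m)


class TestGeographic:
    def test_same_point_zero(self):
        s = SampleTable(
            pd.DataFrame(
                {
                    "individual_id": ["a", "b"],
                    "locality_id": ["p", "p"],
                    "latitude": [35.0, 35.0],
                    "longitude": [24.0, 24.0],
                }
            )
        )
        assert geographic_matrix(s).values[0, 1] == 0.0

    def test_one_degree_latitude(self):
        s = SampleTable(
            pd.DataFrame(
                {
                    "individual_id": ["a", "b"],
                    "locality_id": ["p", "q"],
                    "latitude": [35.0, 36.0],
                    "longitude": [24.0, 24.0],
                }
            )
        )
        d = geographic_matrix(s, "great_circle").values[0, 1]
        assert d == pytest.approx(111.195, abs=1e-3)

    def test_methods_agree_within_small_window(self):
        rng = np.random.default_rng(0)
        # elongated ~250 km coastal window (60 km north-south)
        lat = 35.0 + rng.uniform(0, 0.55, 12)
        lon = 24.0 + rng.uniform(0, 2.8, 12)
        s = SampleTable(
            pd.DataFrame(
                {
                    "individual_id": [f"i{i}" for i in range(12)],
                    "locality_id": [f"p{i}" for i in range(12)],
                    "latitude": lat,
                    "longitude": lon,
                }
            )
        )
        gc = geographic_matrix(s, "great_circle").values
        eq = geographic_matrix(s, "equirectangular").values
        iu = np.triu_indices(12, 1)
        rel = np.abs(gc[iu] - eq[iu]) / gc[iu]
        assert rel.max() < 0.005


def _jc_pair(n_diff: int, length: int = 600):
    s1 = "ACGT" * (length // 4)
    s2 = list(s1)
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for i in range(n_diff):
        s2[i] = swap[s2[i]]
    base = {"s1": s1, "s2": "".join(s2), "s3": s1}
    return alignment_from_strings(base)


class TestGtrGamma:
    def test_identical_sequences_zero(self):
        aln = _jc_pair(5)
        model = SubstitutionModel(gamma_shape=100.0)
        D = gtr_gamma_matrix(aln, model)
        assert D.values[0, 2] == 0.0

    def test_jukes_cantor_closed_form_limit(self):
        # equal frequencies, near-infinite shape: ML distance ~ JC formula
        model = SubstitutionModel(gamma_shape=500.0)
        for n_diff in (5, 30, 90):
            aln = _jc_pair(n_diff)
            D = gtr_gamma_matrix(aln, model)
            p_hat = n_diff / 600
            jc = -0.75 * np.log(1 - 4 * p_hat / 3)
            assert D.values[0, 1] == pytest.approx(jc, abs=1e-3)

    def test_monotone_in_mismatches(self):
        model = SubstitutionModel(gamma_shape=500.0)
        prev = -1.0
        for n_diff in (2, 10, 40, 120):
            d = gtr_gamma_matrix(_jc_pair(n_diff), model).values[0, 1]
            assert d > prev
            prev = d

    def test_pair_order_invariance(self, small_bundle):
        aln = small_bundle["alignment"]
        sub_fwd = CodingAlignment(
            aln.sequence_ids[:4], aln.sequences[:4], 0, np.zeros(4, bool)
        )
        rev = [3, 2, 1, 0]
        sub_rev = CodingAlignment(
            [aln.sequence_ids[i] for i in rev], aln.sequences[rev], 0,
            np.zeros(4, bool),
        )
        model = SubstitutionModel(gamma_shape=1.0)
        d1 = gtr_gamma_matrix(sub_fwd, model).values
        d2 = gtr_gamma_matrix(sub_rev, model).values
        assert d1[0, 3] == pytest.approx(d2[3, 0], abs=1e-9)

    def test_fit_rejects_identical_alignment(self):
        s = "ACGT" * 50
        aln = alignment_from_strings({"a": s, "b": s, "c": s})
        with pytest.raises(ValueError, match="identical"):
            fit_gtr_gamma(aln)

    def test_fit_recovers_jc_symmetry(self):
        # sequences evolved with equal rates: exchangeabilities comparable,
        # frequencies near 1/4
        rng = np.random.default_rng(5)
        L = 1200
        root = rng.choice(list("ACGT"), L)
        seqs = {}
        for k in range(6):
            s = root.copy()
            n_mut = rng.poisson(L * 0.12)
            pos = rng.integers(0, L, n_mut)
            for p in pos:
                s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
            seqs[f"t{k}"] = "".join(s)
        aln = alignment_from_strings(seqs)
        model = fit_gtr_gamma(aln)
        r = np.array(list(model.exchangeabilities.values()))
        assert (r.max() / r.min()) < 4.0
        assert np.abs(model.base_frequencies - 0.25).max() < 0.03

    def test_fit_detects_transition_bias(self):
        rng = np.random.default_rng(9)
        L = 1500
        ti = {"A": "G", "G": "A", "C": "T", "T": "C"}
        root = rng.choice(list("ACGT"), L)
        seqs = {}
        for k in range(6):
            s = root.copy()
            for p in rng.integers(0, L, rng.poisson(L * 0.15)):
                if rng.random() < 4 / 6:
                    s[p] = ti[s[p]]
                else:
                    s[p] = rng.choice(
                        [b for b in "ACGT" if b != s[p] and b != ti[s[p]]]
                    )
            seqs[f"t{k}"] = "".join(s)
        model = fit_gtr_gamma(alignment_from_strings(seqs))
        ex = model.exchangeabilities
        transversions = [ex["AC"], ex["AT"], ex["CG"], ex["GT"]]
        assert min(ex["AG"], ex["CT"]) > max(transversions)


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))


def test_distance_matrix_tsv_round_trip(tmp_path, small_bundle):
    D = jaccard_matrix(small_bundle["markers"])
    D.to_tsv(tmp_path / "d.tsv")
    back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
    assert back.labels == D.labels
    assert np.allclose(back.values, D.values, atol=1e-5)
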