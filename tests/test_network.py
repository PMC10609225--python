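import networkx as nx
import numpy as np
import pytest

from conftest import random_small_spectrum
from npderep.network import (
    CosineScore,
    NetworkParams,
    build_network,
    export_edges_tsv,
    export_graphml,
    modified_cosine,
    preprocess_spectrum,
)
from npderep.simulate import SimSpec, simulate_dataset, random_spectrum
from npderep.spectra_io import make_spectrum


def brute_force_modified_cosine(a, b, frag_tol):
    """Exhaustive enumeration over all one-to-one matchings of candidate
    peak pairs; tractable for <=6-peak spectra."""
    na = np.linalg.norm(a.intensity)
    nb = np.linalg.norm(b.intensity)
    if na == 0 or nb == 0:
        return 0.0
    ia, ib = a.intensity / na, b.intensity / nb
    shift = a.precursor_mz - b.precursor_mz
    cand = [
        (i, j)
        for i in range(a.n_peaks)
        for j in range(b.n_peaks)
        if abs(a.mz[i] - b.mz[j]) <= frag_tol or abs(a.mz[i] - b.mz[j] - shift) <= frag_tol
    ]
    cols = sorted({j for _, j in cand})
    by_col = {j: [i for i, jj in cand if jj == j] for j in cols}

    def best_from(k, used_a):
        if k == len(cols):
            return 0.0
        j = cols[k]
        best = best_from(k + 1, used_a)  # leave column j unmatched
        for i in by_col[j]:
            if i not in used_a:
                best = max(best, ia[i] * ib[j] + best_from(k + 1, used_a | {i}))
        return best

    return best_from(0, frozenset())


class TestPreprocess:
    def test_precursor_peak_removed(self):
        s = make_spectrum("p", 500.0, [500.0], [10.0])
        assert preprocess_spectrum(s).n_peaks == 0

    def test_few_far_peaks_unchanged(self):
        s = make_spectrum("p", 500.0, [100.0, 200.0, 300.0], [4.0, 9.0, 16.0])
        out = preprocess_spectrum(s)
        assert list(out.mz) == [100.0, 200.0, 300.0]
        assert np.allclose(out.intensity, [2.0, 3.0, 4.0])  # sqrt transform

    def test_window_keeps_top_k_most_intense(self):
        # 10 equal-spaced peaks in one 50-Da window, k=6
        mz = np.linspace(100.0, 120.0, 10)
        inten = np.arange(1.0, 11.0)
        s = make_spectrum("p", 800.0, mz, inten)
        out = preprocess_spectrum(s, top_k_per_window=6, window=50.0)
        survivors = set(np.round(out.mz, 6))
        expected = set(np.round(mz[np.argsort(inten)[-6:]], 6))
        assert survivors == expected


class TestModifiedCosine:
    def test_self_similarity_is_one(self, rng):
        s = preprocess_spectrum(random_small_spectrum(rng, 12))
        cs = modified_cosine(s, s)
        assert cs.score == pytest.approx(1.0, abs=1e-9)
        assert cs.n_matched == s.n_peaks

    def test_no_candidate_pairs_scores_zero(self):
        a = make_spectrum("a", 500.0, [100.0, 200.0], [1.0, 1.0])
        b = make_spectrum("b", 500.0, [150.0, 250.0], [1.0, 1.0])
        assert modified_cosine(a, b, frag_tol=0.02) == CosineScore(0.0, 0)

    def test_zero_intensity_scores_zero(self):
        a = make_spectrum("a", 500.0, [100.0], [0.0])
        b = make_spectrum("b", 500.0, [100.0], [1.0])
        assert modified_cosine(a, b) == CosineScore(0.0, 0)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = random_small_spectrum(rng, int(rng.integers(2, 7)), "a")
            b = random_small_spectrum(rng, int(rng.integers(2, 7)), "b")
            ab = modified_cosine(a, b, 0.5)
            ba = modified_cosine(b, a, 0.5)
            assert ab.score == ba.score
            assert ab.n_matched == ba.n_matched

    def test_equals_exhaustive_matching_oracle(self, rng):
        """Exact assignment equals brute-force optimum on 100 random pairs
        of <=6-peak spectra."""
        for trial in range(100):
            a = random_small_spectrum(rng, int(rng.integers(1, 7)), f"a{trial}")
            b = random_small_spectrum(rng, int(rng.integers(1, 7)), f"b{trial}")
            frag_tol = float(rng.choice([0.02, 1.0, 20.0]))
            ours = modified_cosine(a, b, frag_tol).score
            oracle = brute_force_modified_cosine(a, b, frag_tol)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_shifted_analog_matches_via_precursor_delta(self):
        # identical fragments shifted by the parent-mass difference
        mz = np.array([110.0, 230.0, 350.0, 470.0])
        a = make_spectrum("a", 500.0, mz, [1.0, 2.0, 3.0, 4.0])
        b = make_spectrum("b", 516.0, mz + 16.0, [1.0, 2.0, 3.0, 4.0])
        cs = modified_cosine(a, b, 0.02)
        assert cs.score == pytest.approx(1.0, abs=1e-9)
        assert cs.n_matched == 4

    def test_matchms_cross_check(self, rng):
        """Independent implementation agreement; exact matching can only
        exceed matchms' greedy matching."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        mc = ModifiedCosine(tolerance=0.02)
        spectra, _ = simulate_dataset(SimSpec(seed=3, n_families=1, analogs_per_family=3))
        pp = [preprocess_spectrum(s) for s in spectra]
        for i in range(len(pp)):
            for j in range(i + 1, len(pp)):
                ref = mc.pair(
                    matchms.Spectrum(mz=pp[i].mz, intensities=pp[i].intensity,
                                     metadata={"precursor_mz": pp[i].precursor_mz},
                                     metadata_harmonization=False),
                    matchms.Spectrum(mz=pp[j].mz, intensities=pp[j].intensity,
                                     metadata={"precursor_mz": pp[j].precursor_mz},
                                     metadata_harmonization=False),
                )
                ours = modified_cosine(pp[i], pp[j], 0.02).score
                assert ours >= float(ref["score"]) - 1e-9
                assert ours == pytest.approx(float(ref["score"]), abs=0.05)


class TestBuildNetwork:
    def test_duplicate_spectrum_pair_forms_edge(self, rng):
        s = random_small_spectrum(rng, 10, "a")
        twin = make_spectrum("b", s.precursor_mz, s.mz, s.intensity)
        net = build_network([s, twin], NetworkParams())
        assert net.number_of_nodes() == 2
        assert net.number_of_edges() == 1
        assert net.edges["a", "b"]["score"] == pytest.approx(1.0, abs=1e-9)

    def test_singleton_dropped_at_min_cluster_size(self, rng):
        s = random_small_spectrum(rng, 10, "only")
        net = build_network([s], NetworkParams())
        assert net.number_of_nodes() == 0

    def test_family_clusters_and_randoms_do_not(self, rng):
        """Analog family forms one component; unrelated random spectra none
        (noise-free generator isolates the clustering mechanics)."""
        spec = SimSpec(seed=7, n_families=1, analogs_per_family=4,
                       n_noise_peaks=0, mz_sigma=0.003)
        spectra, _ = simulate_dataset(spec)
        rand = [random_spectrum(rng, f"r{i}") for i in range(5)]
        net = build_network(spectra + rand, NetworkParams())
        comps = list(nx.connected_components(net))
        assert {s.id for s in spectra} in comps
        assert all(not any(n.startswith("r") for n in c) for c in comps)

    def test_max_component_size_enforced(self, rng):
        s = random_small_spectrum(rng, 10, "a")
        clones = [make_spectrum(f"c{i}", s.precursor_mz, s.mz, s.intensity) for i in range(6)]
        net = build_network(clones, NetworkParams(max_component_size=3))
        assert all(len(c) <= 3 for c in nx.connected_components(net))

    def test_edge_tsv_deterministic_and_counts(self, tmp_path, rng):
        spectra, _ = simulate_dataset(SimSpec(seed=1, n_families=2, analogs_per_family=3,
                                              n_noise_peaks=0, mz_sigma=0.003))
        net = build_network(spectra, NetworkParams())
        p1, p2 = tmp_path / "e1.tsv", tmp_path / "e2.tsv"
        export_edges_tsv(net, p1)
        net2 = build_network(spectra, NetworkParams())
        export_edges_tsv(net2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert len(p1.read_text().splitlines()) - 1 == net.number_of_edges()

    def test_graphml_roundtrip(self, tmp_path, rng):
        s = random_small_spectrum(rng, 10, "a")
        twin = make_spectrum("b", s.precursor_mz, s.mz, s.intensity)
        net = build_network([s, twin], NetworkParams())
        out = tmp_path / "net.graphml"
        export_graphml(net, out)
        back = nx.read_graphml(out)
        assert set(back.nodes) == set(net.nodes)
        assert back.nodes["a"]["precursor_mz"] == pytest.approx(s.precursor_mz)

    def test_empty_graphml(self, tmp_path):
        out = tmp_path / "empty.graphml"
        export_graphml(nx.Graph(), out)
        assert nx.read_graphml(out).number_of_nodes() == 0


def test_params_validation():
    with pytest.raises(ValueError):
        NetworkParams(frag_tol=0.0)
    with pytest.raises(ValueError):
        NetworkParams(min_matched_peaks=0)
    with pytest.raises(ValueError):
        NetworkParams(min_cosine=1.5)
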