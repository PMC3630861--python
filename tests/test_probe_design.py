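import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from kbpbm import (
    DegenerateMotif,
    DesignError,
    InputError,
    ParseError,
    assemble_probes,
    expand_iupac,
    hamming_matrix,
    pcoa,
    read_design,
    select_representatives,
    write_design,
)
from kbpbm.probe_design import DEFAULT_FLANKS, Flank, kmedoids_objective

from oracles import enumerate_consensus, kmedoids_optimum


class TestExpandIupac:
    @pytest.mark.parametrize(
        "consensus,size",
        [("RGGRNNHHYYB", 6912), ("GGRRNNYYCC", 256), ("ACGT", 1)],
    )
    def test_space_size(self, consensus, size):
        space = expand_iupac(consensus)
        assert len(space.kmers) == size
        assert space.motif.space_size == size
        assert len(set(space.kmers)) == size

    def test_matches_brute_force_enumeration(self):
        for consensus in ("ACGT", "RY", "NNB", "HWSK"):
            assert list(expand_iupac(consensus).kmers) == enumerate_consensus(consensus)

    def test_lexicographic_order_and_membership(self):
        space = expand_iupac("GGRRNNYYCC")
        assert list(space.kmers) == sorted(space.kmers)
        assert all(space.motif.matches(k) for k in space.kmers)

    def test_invalid_character_names_position(self):
        with pytest.raises(InputError, match="position 3"):
            DegenerateMotif("GGXAA")
        with pytest.raises(InputError):
            expand_iupac("")

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet=sorted("ACGTRYSWKMBDHVN"), min_size=1, max_size=6))
    def test_count_equals_degeneracy_product(self, consensus):
        space = expand_iupac(consensus)
        expected = enumerate_consensus(consensus)
        assert list(space.kmers) == expected
        assert len(space.kmers) == space.motif.space_size


class TestHammingMatrix:
    def test_closed_form_pairs(self):
        D = hamming_matrix(["AAA", "AAA", "TTT"])
        assert D[0, 1] == 0 and D[0, 2] == 3 and D[1, 2] == 3

    def test_pulldown_core_vs_control_distance(self):
        # the specific kappaB core differs from the scrambled control at all 10 positions
        D = hamming_matrix(["GGGAATTTCC", "AAACCGGGTT"])
        assert D[0, 1] == 10

    def test_symmetric_zero_diagonal(self):
        space = expand_iupac("RYN")
        D = hamming_matrix(space)
        assert (D == D.T).all() and (np.diagonal(D) == 0).all()

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError, match="unequal"):
            hamming_matrix(["AAA", "AAAA"])


class TestPcoa:
    def test_collinear_points(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        emb = pcoa(D)
        assert emb.n_axes == 1
        coords = np.sort(emb.coordinates[:, 0])
        assert np.allclose(coords, [-1.0, 0.0, 1.0], atol=1e-9)

    def test_all_zero_distances_give_no_axes(self):
        emb = pcoa(np.zeros((4, 4)))
        assert emb.n_axes == 0

    def test_equilateral_gives_two_equal_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        emb = pcoa(D, retained_fraction=1.0)
        assert emb.n_axes == 2
        assert np.isclose(emb.eigenvalues[0], emb.eigenvalues[1])

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        D = squareform(pdist(X))
        emb = pcoa(D, retained_fraction=1.0)
        D_hat = squareform(pdist(emb.coordinates))
        assert np.allclose(D_hat, D, rtol=1e-6, atol=1e-9)

    def test_matches_skbio_oracle(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 2))
        D = squareform(pdist(X))
        emb = pcoa(D, retained_fraction=1.0)
        ref = skbio_pcoa(D, number_of_dimensions=2)
        assert np.allclose(
            np.sort(emb.eigenvalues)[::-1], np.sort(ref.eigvals.to_numpy())[::-1][:2],
            atol=1e-8,
        )
        assert np.allclose(
            np.abs(emb.coordinates), np.abs(ref.samples.to_numpy()[:, :2]), atol=1e-6
        )

    def test_axis_norm_equals_eigenvalue(self):
        space = expand_iupac("RYSW")
        emb = pcoa(hamming_matrix(space).astype(float), retained_fraction=1.0)
        norms = (emb.coordinates**2).sum(axis=0)
        assert np.allclose(norms, emb.eigenvalues, rtol=1e-8)

    def test_rejects_bad_matrices(self):
        with pytest.raises(InputError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(InputError):
            pcoa(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestSelectRepresentatives:
    def _embed(self, X):
        return pcoa(squareform(pdist(X)), retained_fraction=1.0)

    def test_k_equals_n_returns_everything(self):
        emb = self._embed(np.random.default_rng(0).normal(size=(5, 2)))
        assert list(select_representatives(emb, 5, seed=0)) == [0, 1, 2, 3, 4]

    def test_k1_is_the_true_medoid(self):
        X = np.random.default_rng(1).normal(size=(5, 2))
        emb = self._embed(X)
        D = squareform(pdist(emb.coordinates))
        chosen = select_representatives(emb, 1, seed=0)
        assert chosen[0] == int(D.sum(axis=1).argmin())

    def test_deterministic(self):
        emb = self._embed(np.random.default_rng(2).normal(size=(20, 3)))
        a = select_representatives(emb, 5, seed=7)
        b = select_representatives(emb, 5, seed=7)
        assert (a == b).all()

    @pytest.mark.parametrize("n,k", [(5, 2), (6, 3), (8, 3), (8, 2), (7, 1)])
    def test_near_optimal_on_small_instances(self, n, k):
        for trial in range(5):
            X = np.random.default_rng(100 * n + 10 * k + trial).normal(size=(n, 2))
            emb = self._embed(X)
            D = squareform(pdist(emb.coordinates))
            chosen = select_representatives(emb, k, seed=trial)
            assert len(set(chosen)) == k
            achieved = kmedoids_objective(D, chosen)
            optimum = kmedoids_optimum(D, k)
            assert achieved <= 1.05 * optimum + 1e-12

    def test_k_out_of_range(self):
        emb = self._embed(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(InputError):
            select_representatives(emb, 0, seed=0)
        with pytest.raises(InputError):
            select_representatives(emb, 5, seed=0)


class TestAssembleProbes:
    def test_full_scale_design_fits_capacity(self):
        cores = list(expand_iupac("RGGRNNHHYYB").kmers[:803])
        design = assemble_probes(cores, DEFAULT_FLANKS, replicates=3, capacity=15_000)
        assert design.n_features == 9636

    def test_capacity_violation_reports_requirements(self):
        cores = list(expand_iupac("RGGRNNHHYYB").kmers[:804])
        with pytest.raises(DesignError, match="9648.*9636"):
            assemble_probes(cores, DEFAULT_FLANKS, replicates=3, capacity=9636)

    def test_pulldown_oligo_assembly(self):
        design = assemble_probes(
            ["GGGAATTTCC"], [Flank("f0", "AGCTGGGCAT", "AACTCT")],
            replicates=1, capacity=10,
        )
        assert design.features[0].full_sequence == "AGCTGGGCATGGGAATTTCCAACTCT"

    def test_empty_core_list_is_allowed(self):
        design = assemble_probes([], DEFAULT_FLANKS, replicates=3)
        assert design.n_features == 0

    def test_selected_cores_are_space_members(self, desk_design):
        space = set(expand_iupac("RGGRNNHHYYB").kmers)
        assert set(desk_design.cores) <= space
        assert len(set(desk_design.cores)) == len(desk_design.cores) == 200


class TestDesignIO:
    def test_round_trip_small(self, tmp_path):
        design = assemble_probes(
            ["GGGAATTTCC", "GGAATTTTCC"], DEFAULT_FLANKS[:1], replicates=1, capacity=100
        )
        path = tmp_path / "design.tsv"
        write_design(design, path)
        assert read_design(path) == design

    def test_round_trip_full_scale(self, tmp_path):
        cores = list(expand_iupac("RGGRNNHHYYB").kmers[:803])
        design = assemble_probes(cores, DEFAULT_FLANKS, replicates=3, capacity=15_000)
        path = tmp_path / "design.tsv"
        write_design(design, path)
        again = read_design(path)
        assert again == design
        assert again.n_features == 9636

    def test_missing_column_is_a_parse_error(self, tmp_path):
        design = assemble_probes(["GGGAATTTCC"], DEFAULT_FLANKS[:1], replicates=1)
        path = tmp_path / "design.tsv"
        write_design(design, path)
        lines = path.read_text().splitlines()
        lines[1] = "\t".join(c for c in lines[1].split("\t") if c != "core_seq")
        bad = tmp_path / "bad.tsv"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="core_seq"):
            read_design(bad)
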