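"""Data model, TSV IO, alignment and harmonization."""

import numpy as np
import pytest
import scipy.sparse as sp

from heterolp import (
    AssociationMatrix,
    Config,
    EntityCatalog,
    NetworkFormatError,
    SimilarityMatrix,
    align_network,
    harmonize_common_entities,
    load_association,
    load_network,
    load_similarity,
    write_association,
    write_network,
    write_similarity,
)

from conftest import association, catalog, similarity


class TestCatalog:
    def test_index_inverts_ids(self):
        cat = catalog("drug", "a", "b", "c")
        assert [cat.index[i] for i in cat.ids] == [0, 1, 2]

    @pytest.mark.parametrize("ids", [("a", "a"), ("a", "")])
    def test_rejects_duplicates_and_empties(self, ids):
        with pytest.raises(NetworkFormatError):
            EntityCatalog("drug", ids)

    def test_rejects_unknown_kind(self):
        with pytest.raises(NetworkFormatError):
            EntityCatalog("protein", ("a",))


class TestMatrixValidation:
    def test_similarity_zeroes_diagonal(self):
        sim = similarity(catalog("drug", "a", "b"), [[0.9, 0.5], [0.5, 0.2]])
        assert sim.toarray()[0, 0] == 0 and sim.toarray()[1, 1] == 0
        assert sim.toarray()[0, 1] == 0.5

    def test_similarity_rejects_asymmetry(self):
        with pytest.raises(NetworkFormatError, match="symmetric"):
            similarity(catalog("drug", "a", "b"), [[0, 0.3], [0.7, 0]])

    def test_rejects_out_of_range(self):
        with pytest.raises(NetworkFormatError, match=r"\[0, 1\]"):
            similarity(catalog("drug", "a", "b"), [[0, 1.5], [1.5, 0]])
        with pytest.raises(NetworkFormatError, match=r"\[0, 1\]"):
            association(catalog("drug", "a"), catalog("disease", "x"), [[-0.1]])

    def test_association_shape_checked(self):
        with pytest.raises(NetworkFormatError, match="shape"):
            AssociationMatrix(
                catalog("drug", "a"), catalog("disease", "x", "y"), sp.csr_array((1, 3))
            )


class TestLoadSimilarity:
    def test_edge_list_symmetrized(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("A\tB\t0.5\n")
        sim = load_similarity(p, "drug")
        assert sim.catalog.ids == ("A", "B")
        np.testing.assert_allclose(sim.toarray(), [[0, 0.5], [0.5, 0]])

    def test_self_edge_dropped(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("A\tA\t0.9\n")
        sim = load_similarity(p, "drug")
        assert sim.catalog.ids == ("A",)
        assert sim.values.nnz == 0

    def test_max_symmetrization_of_conflicting_directions(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("A\tB\t0.3\nB\tA\t0.7\n")
        assert load_similarity(p, "drug").toarray()[0, 1] == 0.7

    def test_conflicting_duplicate_cell_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("A\tB\t0.3\nA\tB\t0.4\n")
        with pytest.raises(NetworkFormatError, match=":2"):
            load_similarity(p, "drug")

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("A\tB\t0.3\nA\tB\n")
        with pytest.raises(NetworkFormatError, match=":2"):
            load_similarity(p, "drug")

    def test_weight_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("A\tB\t1.3\n")
        with pytest.raises(NetworkFormatError, match=r"outside \[0, 1\]"):
            load_similarity(p, "drug")

    def test_labeled_matrix_autodetected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("\tA\tB\tC\nA\t0\t0.2\t0\nB\t0.2\t0\t0.6\nC\t0\t0.6\t0\n")
        sim = load_similarity(p, "drug")
        assert sim.catalog.ids == ("A", "B", "C")
        assert sim.toarray()[1, 2] == 0.6

    def test_header_row_skipped(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("id1\tid2\tweight\nA\tB\t0.5\n")
        assert load_similarity(p, "drug").catalog.ids == ("A", "B")


class TestLoadAssociation:
    def test_two_column_defaults_to_weight_one(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("mitotane\tAdrenocortical carcinoma\n")
        assoc = load_association(p, "drug", "disease")
        np.testing.assert_array_equal(assoc.toarray(), [[1.0]])

    def test_weighted_rows(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("d1\tx1\t0.2\nd1\tx2\t0.8\n")
        assoc = load_association(p, "drug", "disease")
        assert assoc.toarray().sum() == pytest.approx(1.0)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assoc = load_association(p, "drug", "disease")
        assert assoc.shape == (0, 0)


class TestRoundTrip:
    def test_similarity_edge_list_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        S = rng.random((6, 6))
        S = np.round((S + S.T) / 2, 6)
        np.fill_diagonal(S, 0)
        sim = similarity(catalog("drug", *"abcdef"), S)
        p = tmp_path / "s.tsv"
        write_similarity(sim, p)
        again = load_similarity(p, "drug")
        # catalogs may be reordered by file order; compare by identifier
        d1 = sim.toarray()
        d2 = again.toarray()
        pos = [again.catalog.index[i] for i in sim.catalog.ids]
        np.testing.assert_array_equal(d1, d2[np.ix_(pos, pos)])

    def test_association_round_trip_exact(self, tmp_path):
        assoc = association(
            catalog("drug", "a", "b"), catalog("disease", "x", "y"), [[0.25, 0], [0, 1]]
        )
        p = tmp_path / "a.tsv"
        write_association(assoc, p)
        again = load_association(p, "drug", "disease")
        np.testing.assert_array_equal(
            again.toarray()[
                np.ix_(
                    [again.row_catalog.index[i] for i in ("a", "b")],
                    [again.col_catalog.index[i] for i in ("x", "y")],
                )
            ],
            assoc.toarray(),
        )


class TestAlign:
    def _pieces(self):
        s_drug = similarity(catalog("drug", "A", "B"), [[0, 0.5], [0.5, 0]])
        s_dis = similarity(catalog("disease", "x"), [[0]])
        s_tgt = similarity(catalog("target", "t"), [[0]])
        a_dd = association(catalog("drug", "B", "C"), catalog("disease", "x"), [[1], [1]])
        a_dt = association(catalog("drug", "A"), catalog("target", "t"), [[1]])
        a_xt = association(catalog("disease", "x"), catalog("target", "t"), [[1]])
        return s_drug, s_dis, s_tgt, a_dd, a_dt, a_xt

    def test_union_catalog_and_zero_fill(self):
        net = align_network(*self._pieces())
        assert net.drugs.ids == ("A", "B", "C")
        dd = net.A_drug_disease.toarray()
        assert dd[net.drugs.index["A"], 0] == 0  # zero-filled absent row
        assert dd[net.drugs.index["C"], 0] == 1

    def test_identity_when_ids_shared(self, tiny_network):
        net = tiny_network
        again = align_network(
            net.S_drug, net.S_disease, net.S_target,
            net.A_drug_disease, net.A_drug_target, net.A_disease_target,
        )
        assert again.drugs.ids == net.drugs.ids
        np.testing.assert_array_equal(
            again.A_drug_disease.toarray(), net.A_drug_disease.toarray()
        )

    def test_idempotent(self):
        net = align_network(*self._pieces())
        again = align_network(
            net.S_drug, net.S_disease, net.S_target,
            net.A_drug_disease, net.A_drug_target, net.A_disease_target,
        )
        assert again.drugs.ids == net.drugs.ids
        np.testing.assert_array_equal(again.S_drug.toarray(), net.S_drug.toarray())

    def test_kind_namespace_clash_rejected(self):
        s_drug, s_dis, s_tgt, a_dd, a_dt, a_xt = self._pieces()
        bad_tgt = association(catalog("disease", "x"), catalog("target", "A"), [[1]])
        with pytest.raises(NetworkFormatError, match="A"):
            align_network(s_drug, s_dis, s_tgt, a_dd, a_dt, bad_tgt)


class TestHarmonize:
    def _network(self):
        # drug active sets: sim {A,B,C}, drug-dis {B,C,D}, drug-tgt {B,C} -> common {B,C}
        drugs = catalog("drug", "A", "B", "C", "D")
        diseases = catalog("disease", "x", "y")
        targets = catalog("target", "t1", "t2")
        S = np.zeros((4, 4))
        S[0, 1] = S[1, 0] = 0.5
        S[1, 2] = S[2, 1] = 0.5
        S[0, 2] = S[2, 0] = 0.3
        a_dd = np.array([[0, 0], [1, 0], [0, 1], [1, 0]], dtype=float)
        a_dt = np.array([[0, 0], [1, 0], [0, 1], [0, 0]], dtype=float)
        return align_network(
            similarity(drugs, S),
            similarity(diseases, [[0, 0.5], [0.5, 0]]),
            similarity(targets, [[0, 0.5], [0.5, 0]]),
            association(drugs, diseases, a_dd),
            association(drugs, targets, a_dt),
            association(diseases, targets, [[1, 0], [0, 1]]),
        )

    def test_intersection_semantics(self):
        harm = harmonize_common_entities(self._network())
        assert harm.drugs.ids == ("B", "C")

    def test_idempotent_and_no_new_entries(self):
        net = self._network()
        harm = harmonize_common_entities(net)
        again = harmonize_common_entities(harm)
        assert again.drugs.ids == harm.drugs.ids
        np.testing.assert_array_equal(
            again.A_drug_disease.toarray(), harm.A_drug_disease.toarray()
        )
        # subsets of the aligned catalogs; zero entries stay zero
        assert set(harm.drugs.ids) <= set(net.drugs.ids)
        assert harm.A_drug_disease.values.nnz <= net.A_drug_disease.values.nnz

    def test_tiny_network_common_entities(self, tiny_network):
        # only drug A is active in similarity AND both association layers
        harm = harmonize_common_entities(tiny_network)
        assert harm.drugs.ids == ("A",)
        assert harm.diseases.ids == ("x",)
        assert harm.targets.ids == ("t1",)

    def test_empty_intersection_rejected(self):
        drugs = catalog("drug", "A")
        diseases = catalog("disease", "x")
        targets = catalog("target", "t")
        net = align_network(
            similarity(drugs, [[0]]),  # drug has no similarity edge -> inactive
            similarity(diseases, [[0]]),
            similarity(targets, [[0]]),
            association(drugs, diseases, [[1]]),
            association(drugs, targets, [[1]]),
            association(diseases, targets, [[1]]),
        )
        with pytest.raises(NetworkFormatError, match="inapplicable|common"):
            harmonize_common_entities(net)


class TestNetworkIO:
    def test_write_load_network_round_trip(self, tmp_path, tiny_network):
        # edge lists carry only entities with at least one edge, so a second
        # write -> load cycle on the loaded network must be exact
        write_network(tiny_network, tmp_path)
        once = load_network(tmp_path)
        write_network(once, tmp_path)
        twice = load_network(tmp_path)
        for kind in ("drug", "disease", "target"):
            assert once.catalog(kind).ids == twice.catalog(kind).ids
            np.testing.assert_array_equal(
                once.similarity(kind).toarray(), twice.similarity(kind).toarray()
            )
        np.testing.assert_array_equal(
            once.A_drug_disease.toarray(), twice.A_drug_disease.toarray()
        )
        # entities present in the source survive iff they have an edge
        assert set(once.drugs.ids) == {"A", "B"}  # C is edge-free everywhere

    def test_missing_file_named(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="drug_similarity.tsv"):
            load_network(tmp_path)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("alpha: 0.3\ntau: 0.01\n")
        cfg = Config.from_yaml(p)
        assert cfg.alpha == 0.3 and cfg.tau == 0.01 and cfg.max_iter == 1000

    @pytest.mark.parametrize("kwargs", [{"alpha": 0.0}, {"alpha": 1.0}, {"tau": -1}])
    def test_invariants(self, kwargs):
        with pytest.raises(ValueError):
            Config(**kwargs)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("alhpa: 0.3\n")
        with pytest.raises(ValueError, match="alhpa"):
            Config.from_yaml(p)
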