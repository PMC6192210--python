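import numpy as np
import pytest

from bidiffusion import data as dm


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadInteractionTable:
    def test_duplicate_rows_collapse(self, tmp_path):
        p = _write(tmp_path, "net.tsv", "L1\tM1\nL1\tM2\nL2\tM1\nL1\tM1\n")
        net = dm.read_interaction_table(p)
        assert net.n_edges == 3

    def test_hand_enumerated_network(self, tmp_path):
        p = _write(tmp_path, "net.tsv", "L1\tM1\nL1\tM2\nL2\tM1\n")
        net = dm.read_interaction_table(p)
        assert (net.nl, net.nm) == (2, 2)
        assert net.adjacency.sum() == 3
        assert net.lnc_ids == ["L1", "L2"] and net.mir_ids == ["M1", "M2"]
        assert net.adjacency[1, 1] == 0  # (L2, M2) unidentified

    def test_large_file_with_duplicates(self, tmp_path):
        # 5348 distinct pairs written as 8091 rows
        rng = np.random.default_rng(42)
        pairs = set()
        while len(pairs) < 5348:
            pairs.add((int(rng.integers(780)), int(rng.integers(275))))
        pairs = sorted(pairs)
        rows = [f"L{i}\tM{j}" for i, j in pairs]
        extra = rng.integers(0, len(rows), size=8091 - 5348)
        rows += [rows[e] for e in extra]
        rng.shuffle(rows)
        p = _write(tmp_path, "big.tsv", "\n".join(rows) + "\n")
        net = dm.read_interaction_table(p)
        assert net.n_edges == 5348

    def test_empty_file_errors(self, tmp_path):
        p = _write(tmp_path, "empty.tsv", "\n")
        with pytest.raises(ValueError, match="no interactions"):
            dm.read_interaction_table(p)

    def test_malformed_row_reports_line(self, tmp_path):
        p = _write(tmp_path, "bad.tsv", "L1\tM1\nL2\n")
        with pytest.raises(ValueError, match="line 2"):
            dm.read_interaction_table(p)

    def test_comma_delimiter_detected(self, tmp_path):
        p = _write(tmp_path, "net.csv", "L1,M1\nL2,M2\n")
        assert dm.read_interaction_table(p).n_edges == 2

    def test_header_detected_by_non_overlap(self, tmp_path):
        p = _write(tmp_path, "net.tsv", "lncRNA\tmiRNA\nL1\tM1\nL1\tM2\n")
        net = dm.read_interaction_table(p)
        assert net.lnc_ids == ["L1"]
        assert net.n_edges == 2

    def test_roundtrip_preserves_edge_set(self, tmp_path, toy_network):
        p = tmp_path / "rt.tsv"
        dm.write_interaction_table(toy_network, p)
        again = dm.read_interaction_table(p)
        assert set(again.edges()) == set(toy_network.edges())

    def test_unidentified_count_invariant(self, tmp_path):
        p = _write(tmp_path, "net.tsv", "L1\tM1\nL1\tM2\nL2\tM1\n")
        net = dm.read_interaction_table(p)
        assert net.n_unidentified + net.n_edges == net.nl * net.nm


class TestReadExpressionProfiles:
    def test_blank_cell_row_dropped(self, tmp_path):
        text = "id\tc1\tc2\tc3\tc4\tc5\n" \
               "e1\t1\t2\t3\t4\t5\n" \
               "e2\t1\t\t3\t4\t5\n" \
               "e3\t5\t4\t3\t2\t1\n"
        prof = dm.read_expression_profiles(_write(tmp_path, "p.tsv", text))
        assert prof.entity_ids == ["e1", "e3"]

    def test_duplicate_id_errors(self, tmp_path):
        text = "id\tc1\tc2\ne1\t1\t2\ne1\t3\t4\n"
        with pytest.raises(ValueError, match="duplicate"):
            dm.read_expression_profiles(_write(tmp_path, "p.tsv", text))

    def test_too_few_conditions_errors(self, tmp_path):
        text = "id\tc1\ne1\t1\n"
        with pytest.raises(ValueError, match="2 conditions"):
            dm.read_expression_profiles(_write(tmp_path, "p.tsv", text))

    def test_full_scale_table(self, tmp_path):
        rng = np.random.default_rng(0)
        header = "id\t" + "\t".join(f"c{i}" for i in range(172))
        rows = [header]
        for e in range(230):
            rows.append(f"m{e}\t" + "\t".join(
                f"{v:.4f}" for v in rng.random(172)))
        prof = dm.read_expression_profiles(
            _write(tmp_path, "mir.tsv", "\n".join(rows) + "\n"))
        assert prof.values.shape == (230, 172)
        assert prof.n_conditions == 172


class TestReadAnnotationSets:
    def test_terms_deduplicated(self, tmp_path):
        coll = dm.read_annotation_sets(_write(tmp_path, "a.tsv", "m1\tg1,g2,g2\n"))
        assert coll["m1"] == {"g1", "g2"}

    def test_repeated_entity_unions(self, tmp_path):
        coll = dm.read_annotation_sets(
            _write(tmp_path, "a.tsv", "m1\tg1,g2\nm1\tg3\n"))
        assert coll["m1"] == {"g1", "g2", "g3"}

    def test_three_entity_fixture(self, tmp_path):
        text = "m1\tg1,g2\nm2\tg2,g3,g4\nm3\tg5\n"
        coll = dm.read_annotation_sets(_write(tmp_path, "a.tsv", text))
        assert coll.sets == {
            "m1": frozenset({"g1", "g2"}),
            "m2": frozenset({"g2", "g3", "g4"}),
            "m3": frozenset({"g5"}),
        }

    def test_empty_term_list_skipped(self, tmp_path):
        coll = dm.read_annotation_sets(
            _write(tmp_path, "a.tsv", "m1\t\nm2\tg1\n"))
        assert "m1" not in coll and "m2" in coll


class TestReadFasta:
    def test_two_records(self, tmp_path):
        seqs = dm.read_fasta(_write(tmp_path, "s.fa", ">a\nACGT\n>b\nGGGG\n"))
        assert set(seqs.entity_ids) == {"a", "b"}

    def test_header_token_and_u(self, tmp_path):
        seqs = dm.read_fasta(_write(tmp_path, "s.fa", ">x desc here\nACGU\n"))
        assert seqs["x"] == "ACGU"

    def test_mixed_case_uppercased(self, tmp_path):
        seqs = dm.read_fasta(_write(tmp_path, "s.fa", ">x\nacgTt\n"))
        assert seqs["x"] == "ACGTT"

    def test_duplicate_id_errors(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            dm.read_fasta(_write(tmp_path, "s.fa", ">x\nAC\n>x\nGG\n"))

    def test_empty_record_errors(self, tmp_path):
        with pytest.raises(ValueError):
            dm.read_fasta(_write(tmp_path, "s.fa", ">x\n\n>y\nAC\n"))


class TestAlignEntities:
    def test_identity_when_all_covered(self, toy_network):
        out = dm.align_entities(toy_network, lnc_feature_ids=["L1", "L2", "L3"])
        assert out.lnc_ids == toy_network.lnc_ids
        assert (out.adjacency == toy_network.adjacency).all()

    def test_uncovered_lnc_dropped(self, toy_network):
        out = dm.align_entities(toy_network, lnc_feature_ids=["L1", "L3"])
        # L2 gone; its only partner M2 is now isolated and gone too
        assert out.lnc_ids == ["L1", "L3"]
        assert out.mir_ids == ["M1"]
        assert out.n_edges == 2

    def test_no_coverage_errors(self, toy_network):
        with pytest.raises(ValueError, match="no interactions"):
            dm.align_entities(toy_network, lnc_feature_ids=["Z9"])

    def test_never_grows(self, toy_network):
        out = dm.align_entities(toy_network, lnc_feature_ids=["L1", "L2"])
        assert out.nl <= toy_network.nl
        assert out.nm <= toy_network.nm
        assert out.n_edges <= toy_network.n_edges


class TestWriteScoreTable:
    def test_candidate_and_known_row_counts(self, tmp_path):
        net = dm.InteractionNetwork(["L1", "L2"], ["M1", "M2"],
                                    np.array([[1.0, 0.0], [0.0, 0.0]]))
        scores = np.array([[0.9, 0.4], [0.3, 0.2]])
        cand, known = tmp_path / "cand.tsv", tmp_path / "known.tsv"
        dm.write_score_table(scores, net, cand, known)
        assert len(cand.read_text().splitlines()) == 1 + 3
        assert len(known.read_text().splitlines()) == 1 + 1

    def test_tie_order_is_lexicographic(self, tmp_path):
        net = dm.InteractionNetwork(["Lb", "La"], ["M1"],
                                    np.array([[1.0], [0.0]]))
        # add a second lnc pair of candidates with equal scores
        net = dm.InteractionNetwork(["Lb", "La", "Lc"], ["M1"],
                                    np.array([[1.0], [0.0], [0.0]]))
        scores = np.array([[0.5], [0.2], [0.2]])
        cand, known = tmp_path / "c.tsv", tmp_path / "k.tsv"
        dm.write_score_table(scores, net, cand, known)
        lines = cand.read_text().splitlines()[1:]
        assert [l.split("\t")[1] for l in lines] == ["La", "Lc"]

    def test_roundtrip_precision(self, tmp_path, toy_network):
        rng = np.random.default_rng(3)
        scores = rng.random(toy_network.adjacency.shape)
        cand, known = tmp_path / "c.tsv", tmp_path / "k.tsv"
        dm.write_score_table(scores, toy_network, cand, known)
        table = dm.read_score_table(known)
        li = {e: i for i, e in enumerate(toy_network.lnc_ids)}
        mi = {e: i for i, e in enumerate(toy_network.mir_ids)}
        for _, row in table.iterrows():
            expected = scores[li[row["lncRNA"]], mi[row["miRNA"]]]
            assert row["score"] == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_errors(self, tmp_path, toy_network):
        with pytest.raises(ValueError, match="shape"):
            dm.write_score_table(np.zeros((2, 2)), toy_network,
                                 tmp_path / "c", tmp_path / "k")
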