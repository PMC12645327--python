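"""Trait matrix I/O, subsetting, weighting, and taxon matching."""

import numpy as np
import pytest

from traitphylo.errors import (
    DegenerateInputError,
    FormatError,
    MissingReferenceError,
    ValidationError,
)
from traitphylo.likelihood import LikelihoodSpec, total_log_likelihood
from traitphylo.traits import (
    TraitMatrix,
    apply_level_weights,
    match_shared_taxa,
    merge_characters,
    read_trait_matrix,
    subset_characters,
    write_annotations,
    write_trait_matrix,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestReadWrite:
    def test_csv_read_back(self, tmp_path):
        path = _write(tmp_path, "m.csv", "taxon,c1,c2\nA,1,0\nB,0,1\n")
        m = read_trait_matrix(path, format="csv")
        assert m.taxa == ["A", "B"]
        assert m.char_ids == ["c1", "c2"]
        assert np.array_equal(m.states, [[1, 0], [0, 1]])
        assert not (m.states == -1).any()

    def test_nexus_missing_symbol(self, tmp_path):
        path = _write(
            tmp_path,
            "m.nex",
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=3;\n"
            'FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="01";\n'
            "MATRIX\nA 1?0\nB 011\n;\nEND;\n",
        )
        m = read_trait_matrix(path, format="nexus")
        assert m.states[0, 1] == -1
        assert (m.states != -1).sum() == 5

    def test_non_binary_symbol_names_position(self, tmp_path):
        path = _write(tmp_path, "bad.csv", "taxon,c1\nA,2\n")
        with pytest.raises(FormatError, match="c1"):
            read_trait_matrix(path, format="csv")

    def test_duplicate_taxon_rejected(self, tmp_path):
        path = _write(tmp_path, "dup.csv", "taxon,c1\nA,1\nA,0\n")
        with pytest.raises(ValidationError):
            read_trait_matrix(path, format="csv")

    @pytest.mark.parametrize("fmt", ["csv", "nexus"])
    def test_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        states = rng.choice([0, 1, -1], size=(5, 12), p=[0.45, 0.45, 0.1])
        m = TraitMatrix(
            taxa=[f"t{i}" for i in range(5)],
            states=states,
            char_ids=[f"c{j}" for j in range(12)],
        )
        path = str(tmp_path / f"m.{fmt}")
        write_trait_matrix(m, path, format=fmt)
        back = read_trait_matrix(path, format=fmt)
        assert back.taxa == m.taxa
        assert np.array_equal(back.states, m.states)

    def test_annotation_attachment_and_level_counts(self, tmp_path):
        # a fixture with 102 level-2 and 13 level-4 characters, the kind of
        # unbalanced level distribution a real dependency hierarchy produces
        n2, n4 = 102, 13
        chars = [f"c{j}" for j in range(n2 + n4)]
        levels = [2] * n2 + [4] * n4
        states = np.zeros((2, len(chars)), dtype=np.int8)
        states[1, :] = 1
        m = TraitMatrix(taxa=["A", "B"], states=states, char_ids=chars)
        mpath = str(tmp_path / "m.csv")
        write_trait_matrix(m, mpath)
        ann = "char_id,level\n" + "".join(
            f"{c},{l}\n" for c, l in zip(chars, levels)
        )
        apath = _write(tmp_path, "ann.csv", ann)
        loaded = read_trait_matrix(mpath, format="csv", annotations=apath)
        assert (loaded.levels == 2).sum() == n2
        assert (loaded.levels == 4).sum() == n4

    def test_annotation_unknown_char_id(self, tmp_path):
        m = TraitMatrix(taxa=["A", "B"], states=np.eye(2, dtype=np.int8), char_ids=["c1", "c2"])
        mpath = str(tmp_path / "m.csv")
        write_trait_matrix(m, mpath)
        apath = _write(tmp_path, "ann.csv", "char_id,level\nnope,1\n")
        with pytest.raises(MissingReferenceError, match="nope"):
            read_trait_matrix(mpath, format="csv", annotations=apath)

    def test_annotation_round_trip(self, tmp_path):
        m = TraitMatrix(
            taxa=["A", "B"],
            states=np.eye(2, dtype=np.int8),
            char_ids=["c1", "c2"],
            levels=np.array([1, 2]),
            categories=["structure", "patterning"],
            weights=np.array([8.0, 4.0]),
        )
        mpath = str(tmp_path / "m.csv")
        apath = str(tmp_path / "ann.csv")
        write_trait_matrix(m, mpath)
        write_annotations(m, apath)
        back = read_trait_matrix(mpath, annotations=apath)
        assert back == m


class TestSubset:
    def _annotated(self, n1=40, n2=60):
        chars = [f"c{j}" for j in range(n1 + n2)]
        return TraitMatrix(
            taxa=["A", "B"],
            states=np.tile([0, 1], (n1 + n2, 1)).T,
            char_ids=chars,
            levels=np.array([1] * n1 + [2] * n2),
        )

    def test_level_selection_count(self):
        m = self._annotated()
        assert subset_characters(m, level=1).n_characters == 40

    def test_category_selection_structure_count(self):
        # 216-character system: 159 structure + 27 simple + 30 complex patterning
        cats = ["structure"] * 159 + ["simple-patterning"] * 27 + ["complex-patterning"] * 30
        m = TraitMatrix(
            taxa=["A", "B"],
            states=np.zeros((2, 216), dtype=np.int8),
            char_ids=[f"c{j}" for j in range(216)],
            categories=cats,
        )
        assert subset_characters(m, category="structure").n_characters == 159

    def test_empty_selection_is_an_error(self):
        m = self._annotated()
        with pytest.raises(DegenerateInputError):
            subset_characters(m, level=5)

    def test_annotations_preserved(self):
        m = self._annotated()
        m.weights = np.arange(1, m.n_characters + 1, dtype=float)
        sub = subset_characters(m, level=2)
        assert sub.taxa == m.taxa
        assert (sub.levels == 2).all()
        assert np.array_equal(sub.weights, m.weights[40:])


class TestWeights:
    def test_level_weight_mapping(self):
        m = TraitMatrix(
            taxa=["A", "B"],
            states=np.zeros((2, 4), dtype=np.int8),
            char_ids=list("wxyz"),
            levels=np.array([1, 2, 3, 4]),
        )
        w = apply_level_weights(m, {1: 8, 2: 4, 3: 2, 4: 1})
        assert np.array_equal(w.weights, [8, 4, 2, 1])

    def test_missing_level_mapping_is_reference_error(self):
        m = TraitMatrix(
            taxa=["A", "B"],
            states=np.zeros((2, 2), dtype=np.int8),
            char_ids=["c1", "c2"],
            levels=np.array([1, 3]),
        )
        with pytest.raises(MissingReferenceError, match="level 3"):
            apply_level_weights(m, {1: 8, 2: 4})

    def test_identity_weighting_leaves_likelihood_unchanged(
        self, three_tip_tree, default_model, strict_clock, three_taxon_matrix
    ):
        m = three_taxon_matrix.copy()
        m.levels = np.array([1, 1, 2, 2])
        base = total_log_likelihood(
            LikelihoodSpec(matrix=m, tree=three_tip_tree, model=default_model, clock=strict_clock)
        )
        w = apply_level_weights(m, {1: 1, 2: 1})
        weighted = total_log_likelihood(
            LikelihoodSpec(matrix=w, tree=three_tip_tree, model=default_model, clock=strict_clock)
        )
        assert weighted == pytest.approx(base, abs=1e-12)

    def test_integer_weight_equals_character_duplication(
        self, three_tip_tree, default_model, strict_clock
    ):
        m = TraitMatrix(
            taxa=["A", "B", "C"],
            states=np.array([[1], [0], [1]], dtype=np.int8),
            char_ids=["c1"],
            weights=np.array([2.0]),
        )
        dup = TraitMatrix(
            taxa=["A", "B", "C"],
            states=np.array([[1, 1], [0, 0], [1, 1]], dtype=np.int8),
            char_ids=["c1", "c1b"],
        )
        lw = total_log_likelihood(
            LikelihoodSpec(matrix=m, tree=three_tip_tree, model=default_model, clock=strict_clock)
        )
        ld = total_log_likelihood(
            LikelihoodSpec(matrix=dup, tree=three_tip_tree, model=default_model, clock=strict_clock)
        )
        assert lw == pytest.approx(ld, abs=1e-12)


class TestMatchSharedTaxa:
    def _pair(self):
        a = TraitMatrix(
            taxa=[f"lang{i}" for i in range(30)],
            states=np.zeros((30, 3), dtype=np.int8),
            char_ids=["a1", "a2", "a3"],
        )
        b = TraitMatrix(
            taxa=[f"loom{i}" for i in range(25)],
            states=np.ones((25, 2), dtype=np.int8),
            char_ids=["b1", "b2"],
        )
        return a, b

    def test_counts_and_order(self):
        a, b = self._pair()
        pairs = [(f"lang{i}", f"loom{i}") for i in range(20)]
        sa, sb = match_shared_taxa(a, b, pairs)
        assert sa.n_taxa == sb.n_taxa == 20
        assert sa.taxa == [p[0] for p in pairs]
        assert sb.taxa == [p[1] for p in pairs]

    def test_empty_map_rejected(self):
        a, b = self._pair()
        with pytest.raises(ValidationError):
            match_shared_taxa(a, b, [])

    def test_unknown_label_named_in_error(self):
        a, b = self._pair()
        with pytest.raises(MissingReferenceError, match="ghost"):
            match_shared_taxa(a, b, [("lang0", "ghost")])

    def test_duplicate_pairing_rejected(self):
        a, b = self._pair()
        with pytest.raises(ValidationError):
            match_shared_taxa(a, b, [("lang0", "loom0"), ("lang0", "loom1")])


def test_merge_characters_concatenates():
    a = TraitMatrix(taxa=["A", "B"], states=np.eye(2, dtype=np.int8), char_ids=["c1", "c2"])
    b = TraitMatrix(taxa=["A", "B"], states=np.ones((2, 1), dtype=np.int8), char_ids=["c1"])
    merged = merge_characters(a, b)
    assert merged.n_characters == 3
    assert len(set(merged.char_ids)) == 3
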