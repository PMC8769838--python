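"""Binary efficacy matrices, name normalisation, taxa matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethnophylo import (
    EfficacyMatrix,
    default_categories,
    match_taxa,
    normalize_name,
    parse_newick,
    read_efficacy_table,
    simulate_yule_tree,
)

CATS = default_categories()


def write_table(tmp_path, rows, name="eff.csv", header=None):
    header = header or ["species", "family"] + list(CATS)
    path = tmp_path / name
    path.write_text(
        "\n".join([",".join(header)] + [",".join(map(str, r)) for r in rows])
        + "\n"
    )
    return path


def row(species, family="FamA", ones=()):
    return [species, family] + [1 if c in ones else 0 for c in CATS]


class TestCategorySet:
    def test_fifteen_canonical_categories_in_ring_order(self):
        assert len(CATS) == 15
        assert CATS.ids[0] == "poisoning_intoxication"
        assert CATS.ids[-1] == "urinary"

    def test_duplicate_ids_rejected(self):
        from ethnophylo.efficacy_data import CategorySet

        with pytest.raises(ValueError):
            CategorySet(("a", "a"))


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("anemone rivularis var. flore-minore",
             "Anemone_rivularis_var._flore-minore"),
            ("Coptis chinensis Franch.", "Coptis_chinensis"),
            ("Mahonia  eurybracteata ", "Mahonia_eurybracteata"),
            ("AKEBIA TRIFOLIATA subsp AUSTRALIS",
             "Akebia_trifoliata_subsp._australis"),
            ("Clematis_chinensis", "Clematis_chinensis"),
        ],
    )
    def test_rules(self, raw, expected):
        assert normalize_name(raw) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_name("   ")

    @given(
        st.text(alphabet="abcXY .-_", min_size=1).filter(
            lambda s: s.replace("_", " ").strip()
        )
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_idempotent(self, raw):
        once = normalize_name(raw)
        assert normalize_name(once) == once


class TestReadEfficacyTable:
    def test_basic_read_and_shapes(self, tmp_path):
        path = write_table(
            tmp_path,
            [row("Coptis chinensis", ones=("eye", "oral")),
             row("Mahonia eurybracteata", "FamB", ones=tuple(CATS))],
        )
        m = read_efficacy_table(path)
        assert m.n_species == 2
        assert m.row_sums()["Mahonia_eurybracteata"] == 15
        assert m.families["Coptis_chinensis"] == "FamA"

    def test_duplicate_rows_or_merged_with_warning(self, tmp_path):
        path = write_table(
            tmp_path,
            [row("Nigella glandulifera", ones=("eye",)),
             row("Nigella glandulifera", ones=("oral",))],
        )
        with pytest.warns(UserWarning, match="OR-merged"):
            m = read_efficacy_table(path)
        assert m.n_species == 1
        assert m.values.loc["Nigella_glandulifera", "eye"] == 1
        assert m.values.loc["Nigella_glandulifera", "oral"] == 1

    def test_non_binary_cell_located(self, tmp_path):
        r = row("Coptis chinensis", ones=("eye",))
        r[4] = 2
        path = write_table(tmp_path, [r])
        with pytest.raises(ValueError, match="gastrointestinal"):
            read_efficacy_table(path)

    def test_unknown_category_column_rejected(self, tmp_path):
        path = write_table(
            tmp_path,
            [["Coptis chinensis", "FamA"] + [0] * 15 + [1]],
            header=["species", "family"] + list(CATS) + ["bogus"],
        )
        with pytest.raises(ValueError, match="bogus"):
            read_efficacy_table(path)

    def test_truthy_tokens_behind_flag(self, tmp_path):
        r = row("Coptis chinensis")
        r[2] = "TRUE"
        path = write_table(tmp_path, [r])
        with pytest.raises(ValueError):
            read_efficacy_table(path)
        m = read_efficacy_table(
            path, truthy=frozenset({"1", "TRUE"}), falsy=frozenset({"0"})
        )
        assert m.values.iloc[0, 0] == 1

    def test_column_sums_survive_row_permutation_and_roundtrip(self, tmp_path):
        rows = [
            row(f"Genus sp{i}", ones=tuple(np.array(list(CATS))[: i + 1]))
            for i in range(5)
        ]
        a = read_efficacy_table(write_table(tmp_path, rows, "a.csv"))
        b = read_efficacy_table(write_table(tmp_path, rows[::-1], "b.csv"))
        assert (a.column_sums() == b.column_sums()).all()
        out = tmp_path / "round.csv"
        a.to_csv(out)
        c = read_efficacy_table(out)
        assert (a.column_sums() == c.column_sums()).all()
        assert (a.values.sort_index() == c.values.sort_index()).all().all()


class TestEfficacyMatrixInvariants:
    def test_non_binary_entry_rejected(self):
        df = pd.DataFrame({"eye": [2]}, index=["X_y"])
        with pytest.raises(ValueError, match="non-binary"):
            EfficacyMatrix(df)

    def test_all_zero_row_flagged(self):
        df = pd.DataFrame(
            {"eye": [0, 1], "oral": [0, 0]}, index=["X_y", "X_z"]
        )
        with pytest.warns(UserWarning, match="no positive category"):
            EfficacyMatrix(df)


class TestMatchTaxa:
    def make_matrix(self, species):
        values = pd.DataFrame(
            np.ones((len(species), 1), dtype=int),
            index=species,
            columns=["eye"],
        )
        return EfficacyMatrix(values)

    def test_identity_when_subset_of_tips(self):
        tree = parse_newick("((A_b:1,C_d:1):1,E_f:2);")
        matched, rep = match_taxa(self.make_matrix(["A_b", "C_d"]), tree)
        assert rep.n_matched == 2 and rep.n_unmatched == 0
        assert set(matched.species) == {"A_b", "C_d"}

    def test_variety_falls_back_to_binomial(self):
        tree = parse_newick("((X_y:1,C_d:1):1,E_f:2);")
        m = self.make_matrix(["X_y_var._z", "C_d"])
        dropped, rep0 = match_taxa(m, tree, fallback_to_species=False)
        assert rep0.unmatched == ["X_y_var._z"]
        mapped, rep1 = match_taxa(m, tree, fallback_to_species=True)
        assert rep1.n_unmatched == 0
        assert "X_y" in mapped.species

    def test_conservation_counts(self):
        tree = simulate_yule_tree(40, seed=7)
        species = list(tree.tip_labels[:30]) + [f"Absent_sp{i}" for i in range(20)]
        matched, rep = match_taxa(self.make_matrix(species), tree)
        assert rep.n_matched + rep.n_unmatched == 50
        assert rep.n_matched == 30
        assert matched.n_species <= 40

    def test_zero_matches_is_an_error(self):
        tree = parse_newick("((A_b:1,C_d:1):1,E_f:2);")
        with pytest.raises(ValueError, match="no species matched"):
            match_taxa(self.make_matrix(["Q_q", "R_r"]), tree)

    def test_or_merge_order_independent(self):
        tree = parse_newick("((X_y:1,C_d:1):1,E_f:2);")
        values = pd.DataFrame(
            [[1, 0], [0, 1], [1, 1]],
            index=["X_y_var._z", "X_y", "C_d"],
            columns=["eye", "oral"],
        )
        m1, _ = match_taxa(EfficacyMatrix(values), tree, fallback_to_species=True)
        m2, _ = match_taxa(
            EfficacyMatrix(values.iloc[::-1]), tree, fallback_to_species=True
        )
        assert (m1.values.sort_index() == m2.values.sort_index()).all().all()
        assert m1.values.loc["X_y"].tolist() == [1, 1]
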