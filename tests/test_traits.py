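"""Trait table loading, category collapsing, and design encoding."""

import itertools

import numpy as np
import pandas as pd
import pytest

from avibrain.traits import (
    DIET6_LEVELS,
    FORAGING6_LEVELS,
    CategoryMap,
    TraitTable,
    TraitValidationError,
    collapse_categories,
    encode,
    load_traits,
)


def _base_rows():
    return pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(5)],
            "brain_volume": [1.2, 3.4, 0.5, 2.2, 8.0],
            "body_mass": [120.0, 300.0, 25.0, 90.0, 900.0],
            "diet10": ["Omnivore", "fruit", "seeds", "aquatic animals", "nectar"],
            "foraging9": [
                "aquatic plunge",
                "aquatic surface",
                "aquatic dive",
                "ground forage",
                "aerial sally",
            ],
            "migration": ["sedentary", "migratory", "sedentary", "partially migratory", "sedentary"],
            "social_bond": ["solitary", "weakly social", None, "highly social", "solitary"],
            "cooperative": ["non-cooperative"] * 5,
            "territoriality": ["none", "weak", "strong", "none", "weak"],
            "dev_mode": [-1.0, 0.5, 2.0, -0.2, 0.0],
            "group": ["g1", "g1", "g2", "g2", "g2"],
        }
    )


class TestLoad:
    def test_incomplete_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "traits.csv"
        _base_rows().to_csv(p, index=False)
        table = load_traits(p)
        assert len(table) == 4 and table.n_dropped == 1
        assert "sp2" not in table.species

    def test_case_normalised_fine_levels_accepted(self, tmp_path):
        p = tmp_path / "traits.csv"
        _base_rows().to_csv(p, index=False)
        table = load_traits(p)
        collapsed = collapse_categories(table)
        sp0 = collapsed.df.set_index("species").loc["sp0"]
        assert sp0["diet10"] == "omnivore"  # "Omnivore" accepted
        assert sp0["diet6"] == "generalist"

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("species,brain_volume,body_mass\n")
        with pytest.raises(TraitValidationError, match="empty"):
            load_traits(p)

    def test_unknown_level_names_rows(self, tmp_path):
        df = _base_rows().dropna()
        df.loc[0, "diet10"] = "plastic"
        p = tmp_path / "traits.csv"
        df.to_csv(p, index=False)
        with pytest.raises(TraitValidationError, match="plastic"):
            load_traits(p)

    def test_non_positive_mass_rejected(self, tmp_path):
        df = _base_rows().dropna()
        df.loc[1, "body_mass"] = -3.0
        p = tmp_path / "traits.csv"
        df.to_csv(p, index=False)
        with pytest.raises(TraitValidationError, match="body_mass"):
            load_traits(p)

    def test_schema_renames_columns(self, tmp_path):
        df = _base_rows().dropna().rename(columns={"brain_volume": "EndoVol"})
        p = tmp_path / "traits.csv"
        df.to_csv(p, index=False)
        table = load_traits(p, schema={"brain_volume": "EndoVol"})
        assert "brain_volume" in table.df.columns


class TestCollapse:
    def test_aquatic_niches_merge(self, tmp_path):
        p = tmp_path / "traits.csv"
        _base_rows().to_csv(p, index=False)
        collapsed = collapse_categories(load_traits(p))
        sub = collapsed.df.set_index("species")
        assert sub.loc["sp0", "foraging6"] == "aquatic foraging"
        assert sub.loc["sp1", "foraging6"] == "aquatic foraging"

    def test_identity_map_on_coarse_levels(self):
        df = pd.DataFrame(
            {
                "species": ["a", "b"],
                "brain_volume": [1.0, 2.0],
                "body_mass": [10.0, 20.0],
                "diet10": ["generalist", "vertebrates"],
            }
        )
        cmap = CategoryMap(diet={l: l for l in DIET6_LEVELS}, foraging={})
        out = collapse_categories(TraitTable(df=df), cmap)
        assert list(out.df["diet6"]) == ["generalist", "vertebrates"]

    def test_unmapped_level_named(self):
        df = pd.DataFrame(
            {
                "species": ["a"],
                "brain_volume": [1.0],
                "body_mass": [10.0],
                "foraging9": ["bark glean"],
            }
        )
        cmap = CategoryMap(foraging={"ground forage": "ground foraging"})
        with pytest.raises(TraitValidationError, match="bark glean"):
            collapse_categories(TraitTable(df=df), cmap)

    def test_collapse_is_idempotent(self, tmp_path):
        p = tmp_path / "traits.csv"
        _base_rows().to_csv(p, index=False)
        once = collapse_categories(load_traits(p))
        twice = collapse_categories(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


def _full_levels_table(n_repeat=3):
    """Every level of every focal term observed, deterministically."""
    from avibrain import traits as tm

    levels = {
        "cooperative": tm.COOPERATIVE_LEVELS,
        "social_bond": tm.SOCIAL_BOND_LEVELS,
        "territoriality": tm.TERRITORIALITY_LEVELS,
        "migration": tm.MIGRATION_LEVELS,
        "diet6": DIET6_LEVELS,
        "foraging6": FORAGING6_LEVELS,
    }
    n = n_repeat * 6 * 2  # enough rows to cover the 6-level factors
    rows = {"species": [f"sp{i}" for i in range(n)]}
    for t, (term, levs) in enumerate(levels.items()):
        vals = np.array([levs[i % len(levs)] for i in range(n)])
        np.random.default_rng(t).shuffle(vals)  # break inter-term collinearity
        rows[term] = list(vals)
    rows["dev_mode"] = [(-1) ** i * (i / n) for i in range(n)]
    rows["brain_volume"] = [1.0 + i for i in range(n)]
    rows["body_mass"] = [10.0 + i for i in range(n)]
    rows["group"] = ["g1"] * n
    return TraitTable(df=pd.DataFrame(rows))


class TestEncode:
    TERMS = [
        "dev_mode",
        "cooperative",
        "social_bond",
        "territoriality",
        "diet6",
        "foraging6",
        "migration",
    ]

    def test_three_level_factor_gives_two_columns(self):
        table = _full_levels_table()
        dm = encode(table, ["social_bond"])
        assert dm.columns == [
            "intercept",
            "social_bond:highly social",
            "social_bond:weakly social",
        ]

    def test_full_seven_term_model_has_19_columns(self):
        dm = encode(_full_levels_table(), self.TERMS)
        assert dm.p == 19

    def test_reference_levels_omitted(self):
        dm = encode(_full_levels_table(), self.TERMS)
        for ref_col in (
            "cooperative:non-cooperative",
            "social_bond:solitary",
            "territoriality:none",
            "diet6:aquatic animals",
            "foraging6:aerial sallying",
            "migration:sedentary",
        ):
            assert ref_col not in dm.columns

    def test_no_variation_is_an_error(self):
        table = _full_levels_table()
        table.df["cooperative"] = "cooperative"
        with pytest.raises(TraitValidationError, match="no variation"):
            encode(table, ["cooperative"])

    def test_unobserved_reference_is_an_error(self):
        table = _full_levels_table()
        table.df["territoriality"] = np.where(
            np.arange(len(table.df)) % 2, "weak", "strong"
        )
        with pytest.raises(TraitValidationError, match="reference"):
            encode(table, ["territoriality"])

    def test_duplicate_terms_rejected(self):
        with pytest.raises(TraitValidationError, match="duplicated"):
            encode(_full_levels_table(), ["dev_mode", "dev_mode"])

    def test_row_order_follows_taxa_order(self):
        table = _full_levels_table()
        taxa = list(reversed(table.species))
        dm = encode(table, ["dev_mode"], taxa_order=taxa)
        assert dm.taxa == taxa
        expected = table.df.set_index("species")["dev_mode"].reindex(taxa).to_numpy()
        assert np.allclose(dm.X[:, 1], expected)

    def test_shuffled_input_rows_change_nothing(self, rng):
        table = _full_levels_table()
        taxa = table.species
        shuffled = TraitTable(
            df=table.df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        )
        a = encode(table, self.TERMS, taxa_order=taxa)
        b = encode(shuffled, self.TERMS, taxa_order=taxa)
        assert a.columns == b.columns
        assert np.array_equal(a.X, b.X)
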