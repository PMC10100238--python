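"""Species trait tables: loading, category collapsing, and design encoding.

The trait table holds one row per species: brain volume (cm^3), body mass
(g), ecological predictors (diet, foraging niche, migration), social
predictors (social bond, cooperative breeding, territoriality), a
continuous developmental-mode score (altricial species negative,
precocial positive), and a taxonomic group label.

Fine ecological classifications (10 diet categories, 9 foraging niches)
are collapsed into six broader categories each through a configurable
:class:`CategoryMap`; the fine columns are retained so sensitivity
analyses can use the original scheme. Dummy coding uses fixed reference
levels: non-cooperative breeding, solitary social bond, no
territoriality, aquatic-animal diet, aerial-sallying foraging, and
sedentary migration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .pgls import DesignMatrix, PGLSError
from .treeio import normalize_label

__all__ = [
    "TraitTable",
    "CategoryMap",
    "TraitValidationError",
    "load_traits",
    "collapse_categories",
    "encode",
    "DIET10_LEVELS",
    "FORAGING9_LEVELS",
    "DIET6_LEVELS",
    "FORAGING6_LEVELS",
    "LEVEL_SETS",
    "DEFAULT_REFERENCE_LEVELS",
    "FOCAL_COLUMNS",
]

logger = logging.getLogger(__name__)


class TraitValidationError(ValueError):
    """The trait table violates the declared schema."""


DIET10_LEVELS = (
    "aquatic animals",
    "aquatic plants",
    "terrestrial invertebrates",
    "terrestrial vertebrates",
    "terrestrial carrion",
    "nectar",
    "seeds",
    "fruit",
    "other terrestrial plant matter",
    "omnivore",
)
FORAGING9_LEVELS = (
    "aerial screen",
    "bark glean",
    "aerial sally",
    "arboreal glean",
    "ground forage",
    "aquatic plunge",
    "aquatic surface",
    "aquatic dive",
    "generalist",
)
DIET6_LEVELS = (
    "aquatic animals",
    "fruit/nectar",
    "generalist",
    "invertebrates",
    "plants/seeds",
    "vertebrates",
)
FORAGING6_LEVELS = (
    "aerial sallying",
    "aerial screening",
    "aquatic foraging",
    "foraging generalist",
    "gleaning",
    "ground foraging",
)
MIGRATION_LEVELS = ("sedentary", "partially migratory", "migratory")
SOCIAL_BOND_LEVELS = ("solitary", "weakly social", "highly social")
COOPERATIVE_LEVELS = ("non-cooperative", "cooperative")
TERRITORIALITY_LEVELS = ("none", "weak", "strong")

#: Admissible values per categorical column (fine and coarse schemes both pass
#: validation; collapse_categories populates the coarse columns).
LEVEL_SETS: dict[str, frozenset] = {
    "diet10": frozenset(DIET10_LEVELS),
    "foraging9": frozenset(FORAGING9_LEVELS),
    "diet6": frozenset(DIET6_LEVELS),
    "foraging6": frozenset(FORAGING6_LEVELS),
    "migration": frozenset(MIGRATION_LEVELS),
    "social_bond": frozenset(SOCIAL_BOND_LEVELS),
    "cooperative": frozenset(COOPERATIVE_LEVELS),
    "territoriality": frozenset(TERRITORIALITY_LEVELS),
}

DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "cooperative": "non-cooperative",
    "social_bond": "solitary",
    "territoriality": "none",
    "diet6": "aquatic animals",
    "foraging6": "aerial sallying",
    "diet10": "aquatic animals",
    "foraging9": "aerial sally",
    "migration": "sedentary",
}

#: Columns that, when present, must be complete for a row to be retained.
FOCAL_COLUMNS = (
    "brain_volume",
    "body_mass",
    "diet10",
    "foraging9",
    "diet6",
    "foraging6",
    "migration",
    "social_bond",
    "cooperative",
    "territoriality",
    "dev_mode",
    "group",
)

_REQUIRED = ("species", "brain_volume", "body_mass")

# Fine-to-coarse assignments; the exact mapping is configurable because the
# placement of a few fine categories (aquatic plants, carrion) is a judgement
# call users may want to override.
_DEFAULT_DIET_MAP = {
    "aquatic animals": "aquatic animals",
    "fruit": "fruit/nectar",
    "nectar": "fruit/nectar",
    "omnivore": "generalist",
    "terrestrial invertebrates": "invertebrates",
    "seeds": "plants/seeds",
    "other terrestrial plant matter": "plants/seeds",
    "aquatic plants": "plants/seeds",
    "terrestrial vertebrates": "vertebrates",
    "terrestrial carrion": "vertebrates",
}
_DEFAULT_FORAGING_MAP = {
    "aerial sally": "aerial sallying",
    "aerial screen": "aerial screening",
    "aquatic plunge": "aquatic foraging",
    "aquatic surface": "aquatic foraging",
    "aquatic dive": "aquatic foraging",
    "generalist": "foraging generalist",
    "bark glean": "gleaning",
    "arboreal glean": "gleaning",
    "ground forage": "ground foraging",
}


@dataclass
class CategoryMap:
    """Total fine-to-coarse category mapping for diet and foraging niche."""

    diet: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_DIET_MAP))
    foraging: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_FORAGING_MAP)
    )

    def __post_init__(self):
        self.diet = {k.lower(): v.lower() for k, v in self.diet.items()}
        self.foraging = {k.lower(): v.lower() for k, v in self.foraging.items()}

    @classmethod
    def default(cls) -> "CategoryMap":
        return cls()

    @classmethod
    def from_yaml(cls, path: str) -> "CategoryMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(diet=raw.get("diet", {}), foraging=raw.get("foraging", {}))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"diet": self.diet, "foraging": self.foraging}, fh)


@dataclass
class TraitTable:
    """A validated per-species trait table.

    ``df`` has one row per species with a ``species`` column of normalised
    labels matching tree tips; ``n_dropped`` counts input rows removed for
    missing focal fields.
    """

    df: pd.DataFrame
    n_dropped: int = 0

    @property
    def species(self) -> list[str]:
        return list(self.df["species"])

    def __len__(self) -> int:
        return len(self.df)

    def column(self, name: str, taxa=None) -> pd.Series:
        s = self.df.set_index("species")[name]
        if taxa is not None:
            s = s.reindex(list(taxa))
            if s.isna().any():
                missing = list(s[s.isna()].index)
                raise TraitValidationError(f"species missing from table: {missing}")
        return s

    def subset(self, species) -> "TraitTable":
        keep = set(species)
        return TraitTable(
            df=self.df[self.df["species"].isin(keep)].reset_index(drop=True),
            n_dropped=0,
        )


def _validate_levels(df: pd.DataFrame) -> None:
    for col, levels in LEVEL_SETS.items():
        if col not in df.columns:
            continue
        # coarse values are admissible in fine columns too (pre-collapsed input)
        admissible = levels | LEVEL_SETS.get(
            {"diet10": "diet6", "foraging9": "foraging6"}.get(col, col), frozenset()
        )
        bad = df[~df[col].isin(admissible)]
        if len(bad):
            rows = bad[["species", col]].head(10).to_dict("records")
            raise TraitValidationError(f"unknown levels in {col!r}: {rows}")


def load_traits(path, schema: dict[str, str] | None = None) -> TraitTable:
    """Load and validate a species trait CSV.

    ``schema`` maps canonical column names (``species``, ``brain_volume``,
    ``body_mass``, ``diet10`` ...) to the CSV's column names when they
    differ. Rows with any missing focal field are dropped and the count
    logged; unknown category levels and non-positive sizes are errors.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise TraitValidationError(f"empty trait table: {path}")
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise TraitValidationError(f"required columns absent: {missing_cols}")

    df["species"] = df["species"].astype(str).map(normalize_label)
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"].unique())
        raise TraitValidationError(f"duplicate species: {dupes}")
    for col in df.columns:
        if col in LEVEL_SETS or col == "group":
            df[col] = df[col].astype("string").str.strip().str.lower()

    focal = [c for c in FOCAL_COLUMNS if c in df.columns]
    complete = df[focal].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "dropped %d species with incomplete focal data: %s",
            n_dropped,
            list(df.loc[~complete, "species"].head(20)),
        )
    df = df[complete].reset_index(drop=True)
    if len(df) == 0:
        raise TraitValidationError("no species left after dropping incomplete rows")

    for col in ("brain_volume", "body_mass"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            bad = list(df.loc[vals.isna() | (vals <= 0), "species"].head(10))
            raise TraitValidationError(f"non-positive or non-numeric {col}: {bad}")
        df[col] = vals.astype(float)
    if "dev_mode" in df.columns:
        df["dev_mode"] = pd.to_numeric(df["dev_mode"]).astype(float)

    _validate_levels(df)
    return TraitTable(df=df, n_dropped=n_dropped)


def collapse_categories(table: TraitTable, cmap: CategoryMap | None = None) -> TraitTable:
    """Populate the coarse diet/foraging columns from the fine ones.

    The map must cover every observed fine level (an unmapped level is an
    error naming it); fine columns are retained for sensitivity analyses.
    Collapsing is idempotent: coarse values already present map onto
    themselves only if the supplied map says so.
    """
    cmap = cmap or CategoryMap.default()
    df = table.df.copy()
    for fine, coarse, mapping in (
        ("diet10", "diet6", cmap.diet),
        ("foraging9", "foraging6", cmap.foraging),
    ):
        if fine not in df.columns:
            continue
        observed = set(df[fine].dropna().unique())
        unmapped = sorted(observed - set(mapping))
        if unmapped:
            raise TraitValidationError(
                f"category map for {fine!r} does not cover levels: {unmapped}"
            )
        df[coarse] = df[fine].map(mapping)
    _validate_levels(df)
    return TraitTable(df=df, n_dropped=table.n_dropped)


def encode(
    table: TraitTable,
    terms: list[str],
    refs: dict[str, str] | None = None,
    taxa_order=None,
) -> DesignMatrix:
    """Build a dummy-coded design matrix for an ordered list of predictors.

    Categorical terms contribute one indicator per non-reference level
    (columns named ``"term:level"``); numeric terms contribute themselves.
    An intercept column leads. Row order follows ``taxa_order`` when
    given, else the table's own order.
    """
    refs = {**DEFAULT_REFERENCE_LEVELS, **(refs or {})}
    if len(set(terms)) != len(terms):
        dupes = sorted({t for t in terms if terms.count(t) > 1})
        raise TraitValidationError(f"duplicated terms: {dupes}")
    df = table.df
    if taxa_order is not None:
        df = df.set_index("species").reindex(list(taxa_order))
        if df.isna().all(axis=1).any():
            missing = list(df.index[df.isna().all(axis=1)])
            raise TraitValidationError(f"species missing from table: {missing}")
        df = df.reset_index()
    taxa = list(df["species"])

    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for term in terms:
        if term not in df.columns:
            raise TraitValidationError(f"unknown term: {term!r}")
        series = df[term]
        if pd.api.types.is_numeric_dtype(series):
            vals = series.to_numpy(dtype=float)
            if np.ptp(vals) == 0:
                raise TraitValidationError(f"no variation in term {term!r}")
            cols.append(vals)
            names.append(term)
        else:
            levels = sorted(series.dropna().unique())
            if len(levels) < 2:
                raise TraitValidationError(f"no variation in term {term!r}")
            ref = refs.get(term)
            if ref is None:
                ref = levels[0]
            if ref not in levels:
                raise TraitValidationError(
                    f"reference level {ref!r} of {term!r} not observed "
                    f"(levels: {levels})"
                )
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((series == lev).to_numpy(dtype=float))
                names.append(f"{term}:{lev}")
    X = np.column_stack(cols)
    return DesignMatrix(X=X, columns=names, taxa=taxa)


def term_columns(columns: list[str], term: str) -> list[str]:
    """Design columns belonging to one term (numeric or a dummy block)."""
    hits = [c for c in columns if c == term or c.startswith(term + ":")]
    if not hits:
        raise PGLSError(f"term {term!r} has no columns in the design")
    return hits
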