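"""Clade-level re-analysis: eligibility screening and per-clade pipelines.

A taxonomic group is eligible for its own analysis when it is represented
by more than ``min_n`` species (default 30) and shows variation in every
focal variable (at least two observed levels for categorical predictors,
nonzero variance for continuous ones). Within an eligible clade the trees
are pruned to the clade's species, relative brain size is re-estimated
from a clade-specific single-line (global-form) allometric PGLS with
lambda re-optimised, and the drop-one importance analysis is re-run.

Terms that cannot be estimated inside a clade (a level observed in too
few species making the design rank deficient) are dropped with a logged
warning rather than failing the clade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import importance as importance_mod
from .importance import ImportanceReport
from .pgls import PGLSError
from .traits import TraitTable

__all__ = ["CladeSpec", "select_clades", "clade_pipeline", "combined_frame"]

logger = logging.getLogger(__name__)


@dataclass
class CladeSpec:
    name: str
    species: list[str]
    eligible: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.species)


def _has_variation(series: pd.Series) -> bool:
    if pd.api.types.is_numeric_dtype(series):
        return float(series.std(ddof=0)) > 0
    return series.nunique() >= 2


def select_clades(
    table: TraitTable,
    focal: list[str],
    group_col: str = "group",
    min_n: int = 30,
) -> list[CladeSpec]:
    """Assess every group for clade-level analysis eligibility.

    Ineligible groups carry machine-readable reasons: ``"size"`` when the
    group has ``min_n`` or fewer species, and ``"no variation: <term>"``
    per invariant focal variable.
    """
    out = []
    for name, sub in table.df.groupby(group_col, sort=True):
        reasons = []
        if len(sub) <= min_n:
            reasons.append("size")
        for term in focal:
            if term not in sub.columns:
                raise PGLSError(f"focal term {term!r} not in table")
            if not _has_variation(sub[term]):
                reasons.append(f"no variation: {term}")
        out.append(
            CladeSpec(
                name=str(name),
                species=list(sub["species"]),
                eligible=not reasons,
                reasons=reasons,
            )
        )
    return out


def clade_pipeline(
    clade: CladeSpec,
    trees,
    table: TraitTable,
    terms: list[str],
    refs: dict | None = None,
    delta_aic_cutoff: float = 2.0,
    count_lambda_in_reduced: bool = True,
) -> ImportanceReport:
    """Run the residual + importance pipeline within one clade.

    Relative brain size is re-estimated from a clade-specific global-form
    allometric model (lambda re-optimised on the pruned tree) before the
    drop-one analysis; the ensemble runs over all supplied trees.
    """
    if not clade.eligible:
        raise PGLSError(f"clade {clade.name!r} is ineligible: {clade.reasons}")
    sub = table.subset(clade.species)
    usable_terms = []
    dropped = []
    for term in terms:
        if _has_variation(sub.df[term]):
            usable_terms.append(term)
        else:
            dropped.append(term)
            logger.warning(
                "clade %s: term %r has no variation; dropped", clade.name, term
            )
    report = importance_mod.ensemble(
        trees,
        sub,
        usable_terms,
        refs=refs,
        delta_aic_cutoff=delta_aic_cutoff,
        count_lambda_in_reduced=count_lambda_in_reduced,
        allometry_form="global",
    )
    report.dropped_terms = dropped
    # flag levels supported by very few species within the clade
    support = _level_support(sub, usable_terms)
    report.levels = report.levels.merge(support, on=["term", "level"], how="left")
    return report


def _level_support(table: TraitTable, terms: list[str]) -> pd.DataFrame:
    rows = []
    for term in terms:
        series = table.df[term]
        if pd.api.types.is_numeric_dtype(series):
            rows.append({"term": term, "level": "-", "n_species": len(series)})
        else:
            for lev, n in series.value_counts().items():
                rows.append({"term": term, "level": lev, "n_species": int(n)})
    df = pd.DataFrame(rows)
    df["low_support"] = df["n_species"] < 3
    return df


def combined_frame(reports: dict[str, ImportanceReport]) -> pd.DataFrame:
    """Long-format across-clade summary (clade, term, delta_aic, significant)."""
    rows = []
    for clade, rep in reports.items():
        for _, r in rep.summary.iterrows():
            rows.append(
                {
                    "clade": clade,
                    "term": r["term"],
                    "delta_aic": r["delta_aic"],
                    "partial_r2": r["partial_r2"],
                    "significant": bool(r["significant"]),
                }
            )
    return pd.DataFrame(rows)


def plot_clade_importance(combined: pd.DataFrame, path: str, cutoff: float = 2.0):
    """Bar chart of per-clade drop-one deltaAIC values (one panel per clade)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clades = sorted(combined["clade"].unique())
    fig, axes = plt.subplots(
        len(clades), 1, figsize=(7, 2.2 * len(clades)), squeeze=False
    )
    for ax, clade in zip(axes.ravel(), clades):
        sub = combined[combined["clade"] == clade]
        ax.bar(sub["term"], sub["delta_aic"], color="steelblue")
        ax.axhline(cutoff, ls="--", c="grey")
        ax.set_title(clade)
        ax.set_ylabel(r"$\Delta$AIC")
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
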