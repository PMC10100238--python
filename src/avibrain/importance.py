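"""Drop-one predictor importance by deltaAIC, partial R^2, and tree ensembling.

A predictor's importance is judged by refitting the model with all of
that predictor's design columns removed (multi-level categorical terms
are dropped as whole blocks) while holding lambda fixed at the full
model's ML estimate. ``delta_aic = AIC_reduced - AIC_full``: positive
values mean the model worsens when the predictor is dropped, and
``delta_aic > 2`` (by default) flags the predictor as important. The
likelihood partial R^2 is ``1 - exp(-(2/n) * (loglik_full - loglik_reduced))``.

Parameter counting in the comparison is consistent between the two
models by default (the held-fixed lambda is counted in the reduced
model's k, so the AIC penalty difference equals the number of columns
dropped); set ``count_lambda_in_reduced=False`` to leave the fixed
lambda unpenalised, which shifts every delta_aic down by 2.

Phylogenetic uncertainty is handled by running the full pipeline
(allometry -> residuals -> importance) over a posterior sample of trees
and averaging estimates, standard errors, delta_aic and partial R^2
arithmetically across trees; significance is assessed on the across-tree
mean delta_aic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import allometry as allometry_mod
from . import traits as traits_mod
from .pgls import DesignMatrix, PGLSError, PGLSFit, fit_pgls
from .traits import TraitTable, encode, term_columns
from .treeio import Phylogeny, prune_to, vcv

__all__ = [
    "ImportanceReport",
    "partial_r2",
    "drop_one",
    "importance_table",
    "ensemble",
]

logger = logging.getLogger(__name__)


def partial_r2(loglik_full: float, loglik_reduced: float, n: int) -> float:
    """Likelihood partial R^2, ``1 - exp(-(2/n) * delta_loglik)``."""
    return 1.0 - math.exp(-(2.0 / n) * (loglik_full - loglik_reduced))


@dataclass
class ImportanceReport:
    """Per-predictor importance with full-model per-level estimates.

    ``summary`` has one row per term (delta_aic, partial_r2, significant);
    ``levels`` one row per design column of the full model (estimate, SE,
    t/z p-values). For ensembles, values are across-tree means and
    ``per_tree`` holds the long-format per-tree values.
    """

    summary: pd.DataFrame
    levels: pd.DataFrame
    lambda_hat: float
    delta_aic_cutoff: float = 2.0
    n_trees: int = 1
    n_failed: int = 0
    per_tree: pd.DataFrame | None = None
    dropped_terms: list = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.summary.set_index("term").loc[name]


def drop_one(
    design: DesignMatrix,
    y,
    cov,
    full: PGLSFit,
    term: str,
    count_lambda_in_reduced: bool = True,
) -> tuple[float, float]:
    """Refit without one term's columns at the full model's lambda.

    Returns ``(delta_aic, partial_r2)`` where
    ``delta_aic = AIC_reduced - AIC_full``.
    """
    cols = term_columns(design.columns, term)
    reduced_dm = design.drop_columns(cols)
    reduced = fit_pgls(reduced_dm, y, cov, lam=full.lam)
    k_red = reduced.k + (1 if count_lambda_in_reduced else 0)
    aic_red = -2.0 * reduced.loglik + 2.0 * k_red
    delta = aic_red - full.aic
    pr2 = partial_r2(full.loglik, reduced.loglik, full.n)
    return float(delta), float(pr2)


def _levels_frame(fit: PGLSFit) -> pd.DataFrame:
    dof = max(fit.n - len(fit.beta), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = fit.beta / fit.se
    p_t = 2.0 * stats.t.sf(np.abs(tval), dof)
    p_z = 2.0 * stats.norm.sf(np.abs(tval))
    terms, levels = [], []
    for c in fit.columns:
        if ":" in c:
            t, lev = c.split(":", 1)
        else:
            t, lev = c, "-"
        terms.append(t)
        levels.append(lev)
    return pd.DataFrame(
        {
            "term": terms,
            "level": levels,
            "estimate": fit.beta,
            "se": fit.se,
            "p_t": p_t,
            "p_z": p_z,
        }
    )


def importance_table(
    table: TraitTable,
    response: pd.Series,
    terms: list[str],
    cov,
    refs: dict | None = None,
    delta_aic_cutoff: float = 2.0,
    count_lambda_in_reduced: bool = True,
) -> ImportanceReport:
    """Fit the full model (ML lambda) and drop each term in turn.

    ``response`` is a species-indexed series (typically residual relative
    brain size); the design is encoded from the trait table in the
    response's taxon order.
    """
    taxa = list(response.index)
    design = encode(table, terms, refs=refs, taxa_order=taxa)
    y = response.to_numpy(dtype=float)
    full = fit_pgls(design, y, cov, lam="ml")
    rows = []
    for term in terms:
        delta, pr2 = drop_one(
            design, y, cov, full, term, count_lambda_in_reduced=count_lambda_in_reduced
        )
        rows.append(
            {
                "term": term,
                "delta_aic": delta,
                "partial_r2": pr2,
                "significant": delta > delta_aic_cutoff,
            }
        )
    return ImportanceReport(
        summary=pd.DataFrame(rows),
        levels=_levels_frame(full),
        lambda_hat=full.lam,
        delta_aic_cutoff=delta_aic_cutoff,
    )


def ensemble(
    trees: list[Phylogeny],
    table: TraitTable,
    terms: list[str],
    refs: dict | None = None,
    group_col: str = "group",
    min_group_size: int = 10,
    delta_aic_cutoff: float = 2.0,
    count_lambda_in_reduced: bool = True,
    allometry_form: str | None = None,
) -> ImportanceReport:
    """Run allometry -> residuals -> importance per tree and average.

    Each tree is pruned to the table's species; the allometric model is
    selected by AIC per tree (or forced with ``allometry_form``) and
    residuals are recomputed per tree before the drop-one analysis.
    Single-tree failures are logged and skipped.
    """
    if not trees:
        raise PGLSError("empty tree list")
    species = table.species
    sum_rows: list[pd.DataFrame] = []
    lev_rows: list[pd.DataFrame] = []
    lambdas: list[float] = []
    per_tree_records: list[pd.DataFrame] = []
    n_failed = 0
    for i, tree in enumerate(trees):
        try:
            pruned = prune_to(tree, species) if set(tree.tips) != set(species) else tree
            cov = vcv(pruned)
            log_brain = np.log10(table.column("brain_volume", taxa=pruned.tips))
            log_mass = np.log10(table.column("body_mass", taxa=pruned.tips))
            groups = table.column(group_col, taxa=pruned.tips)
            models = allometry_mod.fit_allometry_family(
                log_brain, log_mass, groups, cov, min_group_size=min_group_size
            )
            if allometry_form is not None:
                model = next(m for m in models if m.form == allometry_form)
            else:
                model = allometry_mod.select_allometry(models)
            rel = allometry_mod.relative_brain_size(model)
            rep = importance_table(
                table,
                rel.values,
                terms,
                cov,
                refs=refs,
                delta_aic_cutoff=delta_aic_cutoff,
                count_lambda_in_reduced=count_lambda_in_reduced,
            )
        except Exception as exc:  # single-tree failure: skip, keep count
            logger.warning("tree %d failed: %s", i, exc)
            n_failed += 1
            continue
        sum_rows.append(rep.summary.assign(tree=i))
        lev_rows.append(rep.levels.assign(tree=i))
        lambdas.append(rep.lambda_hat)
        per_tree_records.append(rep.summary.assign(tree=i, lambda_hat=rep.lambda_hat))
    if not sum_rows:
        raise PGLSError(f"all {len(trees)} trees failed")

    long_sum = pd.concat(sum_rows, ignore_index=True)
    mean_sum = (
        long_sum.groupby("term", sort=False)[["delta_aic", "partial_r2"]]
        .mean()
        .reset_index()
    )
    mean_sum["significant"] = mean_sum["delta_aic"] > delta_aic_cutoff
    frac = (
        long_sum.assign(sig=long_sum["delta_aic"] > delta_aic_cutoff)
        .groupby("term", sort=False)["sig"]
        .mean()
        .reset_index(name="significant_fraction")
    )
    mean_sum = mean_sum.merge(frac, on="term")

    long_lev = pd.concat(lev_rows, ignore_index=True)
    mean_lev = (
        long_lev.groupby(["term", "level"], sort=False)[
            ["estimate", "se", "p_t", "p_z"]
        ]
        .mean()
        .reset_index()
    )

    return ImportanceReport(
        summary=mean_sum,
        levels=mean_lev,
        lambda_hat=float(np.mean(lambdas)),
        delta_aic_cutoff=delta_aic_cutoff,
        n_trees=len(sum_rows),
        n_failed=n_failed,
        per_tree=pd.concat(per_tree_records, ignore_index=True),
    )
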