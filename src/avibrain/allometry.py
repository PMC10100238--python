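"""Brain-body allometry: candidate PGLS model family and residual brain size.

Brain volume scales allometrically with body mass (linearly on log-log
axes), but the intercept and slope of that scaling shift among major
clades. Three nested candidate models are fitted by PGLS with ML lambda:

* ``global`` - one intercept and slope for all species;
* ``group_intercepts`` - per-group intercepts, common slope;
* ``group_intercepts_slopes`` - per-group intercepts and slopes.

The lowest-AIC model supplies relative brain size: the per-species raw
residual of log10 brain volume from its (group's) fitted allometric line.
Groups with fewer than ``min_group_size`` species are pooled into an
``"other"`` group rather than dropped, so every species keeps a residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pgls import DesignMatrix, PGLSError, PGLSFit, fit_pgls

__all__ = [
    "FORMS",
    "AllometryModel",
    "RelativeBrainSize",
    "collapse_small_groups",
    "fit_allometry_family",
    "select_allometry",
    "relative_brain_size",
    "comparison_frame",
]

FORMS = ("global", "group_intercepts", "group_intercepts_slopes")
OTHER_GROUP = "other"


@dataclass
class AllometryModel:
    form: str
    groups: pd.Series  # species -> group label (after small-group pooling)
    fit: PGLSFit
    n_groups: int

    @property
    def aic(self) -> float:
        return self.fit.aic


@dataclass
class RelativeBrainSize:
    """Per-species residual log10 brain volume (log10 cm^3 units)."""

    values: pd.Series
    source_model: AllometryModel


def collapse_small_groups(
    groups: pd.Series, min_group_size: int = 10, other_label: str = OTHER_GROUP
) -> pd.Series:
    counts = groups.value_counts()
    small = set(counts[counts < min_group_size].index)
    if not small:
        return groups.copy()
    return groups.map(lambda g: other_label if g in small else g)


def _allometry_design(form: str, log_mass: pd.Series, groups: pd.Series) -> DesignMatrix:
    taxa = list(log_mass.index)
    levels = sorted(groups.unique())
    cols = [np.ones(len(taxa))]
    names = ["intercept"]
    if form in ("group_intercepts", "group_intercepts_slopes"):
        for lev in levels[1:]:
            cols.append((groups == lev).to_numpy(dtype=float))
            names.append(f"group:{lev}")
    cols.append(log_mass.to_numpy(dtype=float))
    names.append("log_mass")
    if form == "group_intercepts_slopes":
        for lev in levels[1:]:
            cols.append(
                (groups == lev).to_numpy(dtype=float) * log_mass.to_numpy(dtype=float)
            )
            names.append(f"log_mass:group:{lev}")
    return DesignMatrix(X=np.column_stack(cols), columns=names, taxa=taxa)


def fit_allometry_family(
    log_brain: pd.Series,
    log_mass: pd.Series,
    groups: pd.Series,
    cov,
    min_group_size: int = 10,
) -> list[AllometryModel]:
    """Fit the three candidate allometric forms with ML lambda.

    Inputs are species-indexed series on a common index; ``cov`` is the
    tree or its covariance. With a single (post-pooling) group all three
    forms collapse to the same design.
    """
    taxa = list(log_brain.index)
    log_mass = log_mass.reindex(taxa)
    groups = collapse_small_groups(groups.reindex(taxa), min_group_size)
    counts = groups.value_counts()
    too_small = sorted(counts[counts < 2].index)
    if too_small:
        raise PGLSError(f"groups with fewer than 2 species after alignment: {too_small}")
    n_groups = groups.nunique()
    y = log_brain.to_numpy(dtype=float)
    out = []
    for form in FORMS:
        use_form = form if n_groups > 1 else "global"
        dm = _allometry_design(use_form, log_mass, groups)
        fit = fit_pgls(dm, y, cov, lam="ml")
        out.append(AllometryModel(form=form, groups=groups, fit=fit, n_groups=n_groups))
    return out


def select_allometry(models: list[AllometryModel]) -> AllometryModel:
    """Lowest-AIC model; ties go to the fewest parameters."""
    if not models:
        raise PGLSError("empty model family")
    return min(models, key=lambda m: (m.aic, m.fit.k))


def relative_brain_size(model: AllometryModel) -> RelativeBrainSize:
    """Raw residuals of log10 brain volume from the fitted allometry."""
    values = pd.Series(model.fit.residuals, index=list(model.fit.taxa))
    return RelativeBrainSize(values=values, source_model=model)


def comparison_frame(models: list[AllometryModel]) -> pd.DataFrame:
    """Model-comparison table: form, k, loglik, AIC, deltaAIC, lambda."""
    rows = [
        {
            "form": m.form,
            "k": m.fit.k,
            "loglik": m.fit.loglik,
            "aic": m.aic,
            "lambda": m.fit.lam,
            "n_groups": m.n_groups,
        }
        for m in models
    ]
    df = pd.DataFrame(rows)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df


def residual_frame(rel: RelativeBrainSize, log_brain: pd.Series) -> pd.DataFrame:
    """Per-species CSV payload: group, fitted value, residual."""
    m = rel.source_model
    return pd.DataFrame(
        {
            "species": list(m.fit.taxa),
            "group": m.groups.reindex(m.fit.taxa).values,
            "log10_brain": log_brain.reindex(m.fit.taxa).values,
            "fitted": m.fit.fitted,
            "residual": rel.values.reindex(m.fit.taxa).values,
        }
    )
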