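"""Soil multifunctionality: averaged 0-1 scaled soil function variables.

Each soil variable is checked for normality (Shapiro-Wilk), transformed
toward normality when needed (log or square root, after shifting variables
with non-positive values so the minimum maps to zero), rescaled to [0, 1]
by (x - min)/(max - min), and the per-plot multifunctionality score is the
arithmetic mean of the scaled variables.  pH is excluded by default because
it is already on a logarithmic scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SOIL_VARIABLES, ValidationError

__all__ = ["normalize_variable", "scale01", "multifunctionality", "MfResult"]

SHAPIRO_ALPHA = 0.05


def normalize_variable(values, alpha: float = SHAPIRO_ALPHA) -> tuple[np.ndarray, str]:
    """Transform a variable toward normality; returns (vector, label).

    If the Shapiro-Wilk test does not reject normality (p >= ``alpha``) the
    vector is returned untouched with label ``"none"``.  Otherwise log and
    square-root candidates are compared and the one with the larger
    Shapiro-Wilk p wins (ties go to log).  Vectors containing values <= 0
    are first shifted by subtracting their minimum; the log candidate then
    uses log1p since the shifted minimum is exactly zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("normality testing needs at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in variable")
    if np.ptp(x) == 0:
        warnings.warn("constant variable: normality test undefined, no transform")
        return x, "none"
    p_raw = stats.shapiro(x).pvalue
    if p_raw >= alpha:
        return x, "none"

    shifted = x.min() <= 0
    base = x - x.min() if shifted else x
    if shifted:
        candidates = {"shift+log": np.log1p(base), "shift+sqrt": np.sqrt(base)}
    else:
        candidates = {"log": np.log(base), "sqrt": np.sqrt(base)}

    best_label, best_vec, best_p = None, None, -1.0
    for label in sorted(candidates, key=lambda s: 0 if "log" in s else 1):
        vec = candidates[label]
        if np.ptp(vec) == 0:
            p = -1.0
        else:
            p = stats.shapiro(vec).pvalue
        if p > best_p:  # strict: tie keeps log (iterated first)
            best_label, best_vec, best_p = label, vec, p
    return best_vec, best_label


def scale01(values) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant vector maps to 0.5 everywhere."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("scaling needs at least 2 values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant variable scaled to 0.5")
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


@dataclass(frozen=True)
class MfResult:
    """Multifunctionality table plus the transform applied per variable."""

    table: pd.DataFrame  # index sample_id; columns mf + scaled variables
    transforms: dict[str, str] = field(default_factory=dict)


def multifunctionality(
    soil: pd.DataFrame,
    excluded: list[str] | tuple[str, ...] = ("pH",),
    variables: list[str] | tuple[str, ...] | None = None,
) -> MfResult:
    """Per-plot multifunctionality over the included soil variables.

    Transform selection and 0-1 scaling use all plots passed in, so call
    per site for within-site scaling (the default pipeline behaviour).
    ``variables`` overrides the default set of 13 measured soil variables
    (before exclusion) for non-standard tables.
    """
    pool = tuple(variables) if variables is not None else SOIL_VARIABLES
    included = [v for v in pool if v not in set(excluded)]
    missing = [v for v in included if v not in soil.columns]
    if missing:
        raise ValidationError(f"soil table missing variables: {missing}")
    if soil.shape[0] < 2:
        raise ValidationError("multifunctionality needs at least 2 plots")

    index = soil["sample_id"] if "sample_id" in soil.columns else soil.index
    scaled = {}
    transforms = {}
    for v in included:
        vec, label = normalize_variable(soil[v].to_numpy())
        scaled[v] = scale01(vec)
        transforms[v] = label
    table = pd.DataFrame(scaled, index=pd.Index(index, name="sample_id"))
    table.insert(0, "mf", table[included].mean(axis=1))
    return MfResult(table=table, transforms=transforms)
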