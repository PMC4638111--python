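"""Agreement metrics and reproducibility comparison designs.

Two configurations are deemed equivalent when they differ only by a
reflection, rotation, translation and rescaling; both metrics here vanish
on that equivalence class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist

from .mds import Configuration3D
from .twostage import procrustes_fit

__all__ = [
    "procrustes_rmsd",
    "distance_error",
    "Condition",
    "ComparisonDesign",
    "comparison_experiment",
    "radius_of_gyration",
]


def _coords(X) -> np.ndarray:
    return X.coords if isinstance(X, Configuration3D) else np.asarray(X, float)


def _check_labels(Xs, Xt) -> None:
    if isinstance(Xs, Configuration3D) and isinstance(Xt, Configuration3D):
        if Xs.labels.shape != Xt.labels.shape or np.any(Xs.labels != Xt.labels):
            s, t = set(np.asarray(Xs.labels).tolist()), set(np.asarray(Xt.labels).tolist())
            raise ValueError(
                f"label mismatch between configurations; unmatched: "
                f"{sorted(s ^ t)[:10]}"
            )


def radius_of_gyration(X) -> float:
    """Root-mean-square distance of points from their centroid."""
    coords = _coords(X)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def _directed_rmsd(source: np.ndarray, target: np.ndarray) -> float:
    tr = procrustes_fit(source, target, allow_scale=True, allow_reflection=True)
    residual = tr.apply(source) - target
    return float(np.sqrt((residual**2).sum(axis=1).mean()))


def procrustes_rmsd(Xs, Xt) -> float:
    """RMSD after optimal reflection/rotation/translation/rescaling.

    Procrustes with rescaling is direction dependent; the reported value is
    the mean of the two directed fits, which makes the metric symmetric.
    """
    _check_labels(Xs, Xt)
    s, t = _coords(Xs), _coords(Xt)
    if s.shape != t.shape:
        raise ValueError(f"configurations differ in shape: {s.shape} vs {t.shape}")
    return 0.5 * (_directed_rmsd(s, t) + _directed_rmsd(t, s))


def distance_error(Xs, Xt, scale_invariant: bool = True) -> float:
    """Compare within-configuration pairwise distances.

    Raw form: ``sqrt(sum_{i<j} (d_s - d_t)**2)``.  The scale-invariant form
    divides each configuration's distances by their own sum over ``i < j``
    before differencing.
    """
    _check_labels(Xs, Xt)
    s, t = _coords(Xs), _coords(Xt)
    if s.shape != t.shape:
        raise ValueError(f"configurations differ in shape: {s.shape} vs {t.shape}")
    if s.shape[0] < 2:
        raise ValueError("need at least 2 points")
    ds, dt = pdist(s), pdist(t)
    if scale_invariant:
        ds = ds / ds.sum()
        dt = dt / dt.sum()
    return float(np.sqrt(((ds - dt) ** 2).sum()))


# ---------------------------------------------------------------------------
# comparison design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """A labeled reconstruction entering a comparison experiment."""

    id: str
    factors: dict[str, str]
    config: Configuration3D


@dataclass(frozen=True)
class ComparisonDesign:
    """All-pairs agreement outcomes with factor contrast annotations.

    ``pairs`` has one row per unordered condition pair with both metrics
    and, per factor, a within/between category label.  ``coefficients``
    maps each outcome metric to an OLS coefficient table (absent in
    referent mode); ``referent_table`` lists each condition's agreement
    with the referent (referent mode only).
    """

    pairs: pd.DataFrame
    coefficients: dict[str, pd.DataFrame] | None = None
    referent_table: pd.DataFrame | None = None


def _pair_category(level_a: str, level_b: str) -> str:
    if level_a == level_b:
        return f"within {level_a}"
    lo, hi = sorted((level_a, level_b))
    return f"between {lo} & {hi}"


def _factor_levels(conditions: list[Condition], factor: str) -> list[str]:
    levels: list[str] = []
    for cond in conditions:
        level = cond.factors[factor]
        if level not in levels:
            levels.append(level)
    return levels


def _contrast_columns(factor: str, levels: list[str]) -> list[str]:
    """All category labels for a factor, baseline (within first level) first."""
    cats = [f"within {levels[0]}"]
    for a, b in combinations(sorted(levels), 2):
        cats.append(f"between {a} & {b}")
    for level in levels[1:]:
        cats.append(f"within {level}")
    return cats


def comparison_experiment(
    conditions: list[Condition], referent: str | None = None
) -> ComparisonDesign:
    """Score all unordered condition pairs and summarize factor effects.

    Without a referent, each factor's pair categories ("within <baseline
    level>" as referent category, "between" and other "within" categories
    as contrasts) enter an ordinary least-squares regression for each
    outcome metric, mirroring a between/within-level comparison design.
    With a referent id, agreement of every other condition with the
    referent is tabulated instead.
    """
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    ids = [c.id for c in conditions]
    if len(set(ids)) != len(ids):
        raise ValueError("condition ids must be unique")
    factors = list(conditions[0].factors)
    for cond in conditions:
        if list(cond.factors) != factors:
            raise ValueError("conditions carry inconsistent factor annotations")

    rows = []
    for ca, cb in combinations(conditions, 2):
        row = {
            "condition_a": ca.id,
            "condition_b": cb.id,
            "rmsd": procrustes_rmsd(ca.config, cb.config),
            "distance_error": distance_error(
                ca.config, cb.config, scale_invariant=True
            ),
        }
        for factor in factors:
            row[factor] = _pair_category(ca.factors[factor], cb.factors[factor])
        rows.append(row)
    pairs = pd.DataFrame(rows)

    if referent is not None:
        by_id = {c.id: c for c in conditions}
        if referent not in by_id:
            raise KeyError(f"unknown referent condition {referent!r}")
        ref = by_id[referent]
        ref_rows = []
        for cond in conditions:
            if cond.id == referent:
                continue
            ref_rows.append(
                {
                    "condition": cond.id,
                    **cond.factors,
                    "rmsd": procrustes_rmsd(ref.config, cond.config),
                    "distance_error": distance_error(
                        ref.config, cond.config, scale_invariant=True
                    ),
                }
            )
        return ComparisonDesign(pairs, referent_table=pd.DataFrame(ref_rows))

    design_cols: dict[str, np.ndarray] = {}
    term_order: list[str] = []
    for factor in factors:
        levels = _factor_levels(conditions, factor)
        cats = _contrast_columns(factor, levels)
        for cat in cats[1:]:  # first category is the baseline
            name = f"{factor}: {cat}"
            design_cols[name] = (pairs[factor] == cat).to_numpy(dtype=float)
            term_order.append(name)
    X = pd.DataFrame(design_cols, index=pairs.index)
    X = sm.add_constant(X, has_constant="add")

    coefficients: dict[str, pd.DataFrame] = {}
    for outcome in ("distance_error", "rmsd"):
        fit = sm.OLS(pairs[outcome].to_numpy(), X).fit()
        coefficients[outcome] = pd.DataFrame(
            {
                "estimate": fit.params,
                "std_error": fit.bse,
                "t_value": fit.tvalues,
                "p_value": fit.pvalues,
            }
        )
    return ComparisonDesign(pairs, coefficients=coefficients)
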