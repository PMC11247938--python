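"""Segment- and sucker-level morphometrics and their factorial statistics.

The measurements mirror how the axial nerve cord (ANC) cell body layer is
quantified along the arm: segments are counted over runs of six suckers on
the anterior and posterior sides, segment widths and nuclei densities are
recorded per position (proximal / intermediate / distal) and ANC territory
(external side ExA / internal side InA), and differences are tested with a
two-way ANOVA followed by Tukey's post-hoc comparisons at α = 0.05.

Tables are tidy :class:`pandas.DataFrame` objects with one measurement per
row; the dataclasses below document the expected columns and their units.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .errors import ParameterError

POSITIONS = ("proximal", "intermediate", "distal")
SIDES = ("anterior", "posterior")
TERRITORIES = ("ExA", "InA")

ALPHA = 0.05


@dataclass
class SegmentRecord:
    """One segment measurement (widths in μm, areas in μm²)."""

    arm_id: str
    position: str  # proximal | intermediate | distal
    side: str  # anterior | posterior
    territory: str  # ExA | InA
    width: float
    height: float | None = None
    nuclei_count: int | None = None
    patch_area: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError(f"width must be positive, got {self.width}")
        if self.nuclei_count is not None and (
            self.patch_area is None or self.patch_area <= 0
        ):
            raise ParameterError(
                "patch_area must be positive when nuclei_count is present"
            )


@dataclass
class SuckerRecord:
    """Per-sucker acetabulum width and segment counts over a six-sucker run."""

    arm_id: str
    position: str
    sucker_index: int
    acetabulum_width: float
    count_anterior: int
    count_posterior: int

    def __post_init__(self) -> None:
        if self.acetabulum_width <= 0:
            raise ParameterError("acetabulum_width must be positive")
        if self.count_anterior < 0 or self.count_posterior < 0:
            raise ParameterError("segment counts must be non-negative")


@dataclass
class AnovaResult:
    """Two-way ANOVA with Tukey HSD post-hoc comparisons."""

    factors: tuple[str, str]
    table: pd.DataFrame  # anova table: sum_sq, df, F, PR(>F)
    f_stats: dict[str, float]
    p_values: dict[str, float]
    significant: dict[str, bool]  # at alpha
    tukey: dict[str, pd.DataFrame]  # per factor: pair, meandiff, p_adj, reject
    interaction_included: bool
    alpha: float = ALPHA


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Tidy DataFrame from a sequence of record dataclasses."""
    return pd.DataFrame([asdict(r) for r in records])


def segments_per_sucker(count_anterior: int, count_posterior: int,
                        n_suckers: int = 6) -> float:
    """Segments per sucker from anterior/posterior counts over a sucker run.

    The two side counts are averaged together, then divided by the number of
    suckers spanned (six in the standard protocol).
    """
    if n_suckers < 1:
        raise ParameterError(f"n_suckers must be >= 1, got {n_suckers}")
    if count_anterior < 0 or count_posterior < 0:
        raise ParameterError("segment counts must be non-negative")
    return ((count_anterior + count_posterior) / 2.0) / n_suckers


def _sem(x: np.ndarray) -> float:
    """Standard error of the mean, n−1 denominator; 0 for a single value."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def summarize_widths(records: pd.DataFrame | Iterable,
                     value: str = "width") -> pd.DataFrame:
    """Two-step width summary per position and territory.

    Anterior and posterior measurements are pooled to give one mean ± sem
    per (position, territory).  The "total" row per position is the mean of
    the ExA and InA means — *not* the pooled grand mean — so an unbalanced
    territory never dominates the total.

    Returns a DataFrame with columns position, territory ("ExA", "InA" or
    "total"), mean, sem, n.  Empty cells are omitted with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    rows = []
    for pos in df["position"].unique():
        sub = df[df["position"] == pos]
        territory_means = {}
        for terr in TERRITORIES:
            vals = sub.loc[sub["territory"] == terr, value].to_numpy(dtype=float)
            if len(vals) == 0:
                warnings.warn(
                    f"no {terr} measurements at position {pos!r}; cell omitted",
                    stacklevel=2,
                )
                continue
            territory_means[terr] = float(np.mean(vals))
            rows.append({
                "position": pos, "territory": terr,
                "mean": territory_means[terr], "sem": _sem(vals),
                "n": len(vals),
            })
        if territory_means:
            rows.append({
                "position": pos, "territory": "total",
                "mean": float(np.mean(list(territory_means.values()))),
                "sem": np.nan,
                "n": int(sub[value].notna().sum()),
            })
    return pd.DataFrame(rows)


def cell_density(nuclei_count: int, patch_area: float) -> float:
    """Cell density as nuclei per μm² of the measured rectangle."""
    if patch_area <= 0:
        raise ParameterError(f"patch_area must be positive, got {patch_area}")
    if nuclei_count < 0:
        raise ParameterError("nuclei_count must be non-negative")
    return nuclei_count / patch_area


def cross_sectional_area(width: float, height: float) -> float:
    """Segment cross-sectional area: width × height (μm²)."""
    if width <= 0 or height <= 0:
        raise ParameterError("width and height must be positive")
    return width * height


def _tukey_pooled(df: pd.DataFrame, response: str, factor: str,
                  mse: float, df_resid: float, alpha: float) -> pd.DataFrame:
    """Tukey HSD over the levels of one factor using the pooled error term.

    The studentized-range statistic for levels i, j is
    q = |m_i − m_j| / sqrt(MSE/2 · (1/n_i + 1/n_j)) with MSE and residual df
    from the full ANOVA model (Tukey–Kramer for unequal n).
    """
    levels = sorted(df[factor].dropna().unique())
    means = {lv: df.loc[df[factor] == lv, response].mean() for lv in levels}
    ns = {lv: int((df[factor] == lv).sum()) for lv in levels}
    rows = []
    k = len(levels)
    for a, b in itertools.combinations(levels, 2):
        diff = means[b] - means[a]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = np.abs(diff) / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append({
            "group1": a, "group2": b, "meandiff": float(diff),
            "q": float(q), "p_adj": p, "reject": p < alpha,
        })
    return pd.DataFrame(rows)


def two_way_anova_tukey(records: pd.DataFrame | Iterable, response: str,
                        factor_a: str, factor_b: str,
                        alpha: float = ALPHA) -> AnovaResult:
    """Two-way ANOVA with interaction and Tukey HSD per main factor.

    Type II sums of squares are used, which coincide with the classical
    two-way decomposition when the design is balanced.  The interaction
    term requires at least two replicates in every factor-level cell and at
    least one observation per cell; otherwise the additive model is fit and
    a warning issued.  Tukey comparisons use the pooled residual mean square
    of the fitted model.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[[response, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ParameterError(f"factor {f!r} needs >= 2 levels")

    cell_sizes = df.groupby([factor_a, factor_b], observed=True).size()
    n_cells = df[factor_a].nunique() * df[factor_b].nunique()
    full_cells = len(cell_sizes) == n_cells
    replicated = full_cells and (cell_sizes >= 2).all()
    include_interaction = bool(replicated)
    if not include_interaction:
        warnings.warn(
            "cells are empty or unreplicated; interaction term refused, "
            "reporting main effects only",
            stacklevel=2,
        )

    op = "*" if include_interaction else "+"
    formula = f"Q('{response}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))"
    model = smf.ols(formula, data=df).fit()
    table = anova_lm(model, typ=2)

    def _term(name: str) -> str:
        return f"C(Q('{name}'))"

    key_map = {factor_a: _term(factor_a), factor_b: _term(factor_b)}
    if include_interaction:
        key_map["interaction"] = f"{_term(factor_a)}:{_term(factor_b)}"

    f_stats, p_values, significant = {}, {}, {}
    for label, key in key_map.items():
        f_stats[label] = float(table.loc[key, "F"])
        p_values[label] = float(table.loc[key, "PR(>F)"])
        significant[label] = p_values[label] < alpha

    mse = float(model.mse_resid)
    df_resid = float(model.df_resid)
    tukey = {
        f: _tukey_pooled(df, response, f, mse, df_resid, alpha)
        for f in (factor_a, factor_b)
    }

    return AnovaResult(
        factors=(factor_a, factor_b),
        table=table,
        f_stats=f_stats,
        p_values=p_values,
        significant=significant,
        tukey=tukey,
        interaction_included=include_interaction,
        alpha=alpha,
    )
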