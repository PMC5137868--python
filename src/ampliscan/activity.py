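"""Acetylcholinesterase (AChE1) activity statistics.

Activity is measured twice per individual: total activity (A_TOT) and the
activity remaining under a carbamate inhibitor (A_R, the insensitive
resistant-enzyme component); the susceptible-enzyme component is the
difference A_S = A_TOT - A_R.  Under strict additivity each gene copy
contributes a fixed per-copy activity, so predicted totals are linear in the
copy counts and the predicted ratio between genotypes is the ratio of their
total copy counts.  The activity index positions an individual between two
control genotypes on a plate-matched scale, and a Gaussian regression of A_R
on the number of resistant copies quantifies the dosage effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecord",
    "CopyActivityModel",
    "RegressionResult",
    "decompose_activity",
    "decompose_table",
    "per_copy_and_additive",
    "activity_index",
    "copy_activity_regression",
]


@dataclass(frozen=True)
class ActivityRecord:
    individual: str
    a_tot: float
    a_r: float
    a_s: float
    sex: str | None = None
    genotype: str | None = None


def decompose_activity(
    a_tot: float,
    a_r: float,
    individual: str = "",
    tolerance: float = 1e-9,
    sex: str | None = None,
    genotype: str | None = None,
) -> ActivityRecord:
    """Split total activity into resistant and susceptible components.

    A_S = A_TOT - A_R, floored at 0 with a warning when the inhibited well
    reads higher than the total beyond measurement tolerance (the inhibited
    well never reads exactly 0 because of spontaneous substrate degradation).
    """
    if np.isnan(a_tot) or np.isnan(a_r):
        raise ValueError(f"missing activity well for individual {individual!r}")
    a_s = a_tot - a_r
    if a_s < -tolerance:
        warnings.warn(
            f"A_R exceeds A_TOT by {-a_s:.3g} for {individual!r}; flooring A_S at 0",
            stacklevel=2,
        )
    return ActivityRecord(individual, a_tot, a_r, max(a_s, 0.0), sex, genotype)


def decompose_table(df: pd.DataFrame, blank: float = 0.0) -> pd.DataFrame:
    """Vectorized decomposition of an activity table.

    Expects columns ``A_TOT`` and ``A_R`` (plus any identifiers); ``blank``
    is an optional per-plate background slope subtracted from both wells
    before decomposition.  Adds an ``A_S`` column.
    """
    out = df.copy()
    out["A_TOT"] = (out["A_TOT"] - blank).clip(lower=0.0)
    out["A_R"] = (out["A_R"] - blank).clip(lower=0.0)
    out["A_S"] = (out["A_TOT"] - out["A_R"]).clip(lower=0.0)
    return out


@dataclass(frozen=True)
class CopyActivityModel:
    """Per-copy activities and additive predictions per genotype."""

    a_r: float  # activity of one resistant copy
    a_s: float  # activity of one susceptible copy
    predictions: Mapping[str, float]  # genotype -> predicted total activity

    def predicted_ratio(self, genotype_a: str, genotype_b: str) -> float:
        return self.predictions[genotype_a] / self.predictions[genotype_b]


def per_copy_and_additive(
    copy_counts: Mapping[str, tuple[int, int]],
    activities: pd.DataFrame,
    r_homozygote: str,
    s_homozygote: str,
) -> CopyActivityModel:
    """Estimate per-copy activities and predict genotype totals additively.

    ``copy_counts`` maps genotype label to (n_R, n_S) copies per diploid
    genome.  The one-R-copy activity is the mean A_R of the resistant
    homozygote divided by its total R copies (e.g. total activity divided by
    six for a three-copies-per-chromosome homozygote); the one-S-copy
    activity likewise from the susceptible homozygote's A_S.  Predicted
    totals are ``n_R * a_r + n_S * a_s``, so the predicted ratio between two
    genotypes is the ratio of their copy-weighted sums.
    """
    for geno in (r_homozygote, s_homozygote):
        if geno not in copy_counts:
            raise ValueError(f"no copy counts for genotype {geno!r}")
    r_rows = activities[activities["genotype"] == r_homozygote]
    s_rows = activities[activities["genotype"] == s_homozygote]
    if r_rows.empty or s_rows.empty:
        raise ValueError("both homozygote genotypes need activity measurements")
    n_r_hom = copy_counts[r_homozygote][0]
    n_s_hom = copy_counts[s_homozygote][1]
    a_r = float(r_rows["A_R"].mean()) / n_r_hom
    a_s_col = "A_S" if "A_S" in s_rows.columns else "A_TOT"
    a_s = float(s_rows[a_s_col].mean()) / n_s_hom
    if n_r_hom == 0 or n_s_hom == 0:
        raise ValueError("homozygote copy counts must be positive")
    predictions = {
        geno: n_r * a_r + n_s * a_s for geno, (n_r, n_s) in copy_counts.items()
    }
    for geno, (n_r, n_s) in copy_counts.items():
        if n_r + n_s == 0 and predictions[geno] > 1e-12:
            warnings.warn(f"genotype {geno!r} has zero copies but nonzero prediction")
    return CopyActivityModel(a_r=a_r, a_s=a_s, predictions=predictions)


def activity_index(a_x: float, a_r3: float, a_r5: float) -> float:
    """Position an individual's activity between two control genotypes.

    A_I = (A_x - A_R3) / (A_R5 - A_R3): 0 at the low-copy control mean, 1 at
    the high-copy control mean, not clipped outside [0, 1].  Controls must be
    measured on the same plate; equal control means leave the index undefined.
    """
    denom = a_r5 - a_r3
    if denom == 0:
        raise ValueError("undefined activity index: control means are equal")
    return (a_x - a_r3) / denom


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    df: int


def copy_activity_regression(table: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares of insensitive activity on resistant copy number.

    ``table`` needs columns ``Nc`` (copies per individual) and ``Ar``.  The
    slope's two-sided t test quantifies the dosage effect.  Requires at least
    three distinct copy numbers.
    """
    import statsmodels.api as sm

    nc = table["Nc"].to_numpy(dtype=float)
    ar = table["Ar"].to_numpy(dtype=float)
    if len(np.unique(nc)) < 3:
        raise ValueError("regression needs >= 3 distinct copy-number values")
    model = sm.OLS(ar, sm.add_constant(nc)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        t_statistic=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        df=int(model.df_resid),
    )
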