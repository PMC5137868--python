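"""Abbott-corrected probit dose-mortality analysis.

Observed mortalities are first corrected for natural (control) mortality with
Abbott's formula m' = (m - c) / (1 - c), then modelled by maximum-likelihood
binomial regression with a probit link on log10 dose.  Lethal concentrations
follow from the inverse link, LC_p = 10 ** ((z_p - intercept) / slope), with
confidence intervals by Fieller's theorem on the intercept/slope ratio (delta
method as fallback for weakly determined slopes).  Strains are compared
through resistance ratios RR_p = LC_p(strain) / LC_p(reference), pairwise
likelihood-ratio tests of equal LC50, and a compact letter display in which
strains sharing a letter are not significantly different.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ProbitFit",
    "StrainComparison",
    "abbott_correct",
    "fit_probit",
    "compare_strains",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ProbitFit:
    strain: str
    intercept: float
    slope: float  # probits per log10 dose; > 0 for a valid fit
    lc50: float
    lc50_ci: tuple[float, float]
    lc95: float
    lc95_ci: tuple[float, float]
    chi2: float
    chi2_df: int
    chi2_p: float
    cov: np.ndarray = field(repr=False, compare=False, default=None)
    log_likelihood: float = float("nan")
    n_obs: int = 0

    def lc(self, p: float) -> float:
        return 10.0 ** ((stats.norm.ppf(p) - self.intercept) / self.slope)

    def var_log10_lc(self, p: float = 0.5) -> float:
        """Delta-method variance of log10 LC_p."""
        z = stats.norm.ppf(p)
        x0 = (z - self.intercept) / self.slope
        grad = np.array([-1.0 / self.slope, -x0 / self.slope])
        return float(grad @ self.cov @ grad)


def abbott_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Correct observed mortality for natural mortality, per strain.

    The control mortality ``c`` is pooled over each strain's dose-0 rows;
    corrected mortality m' = (m - c) / (1 - c), clipped to [0, 1].  Control
    rows are retained with m' = 0 (they are excluded from regression).
    Refuses strains with pooled control mortality >= 0.5.
    """
    required = {"strain", "dose", "n", "dead"}
    if not required <= set(table.columns):
        raise ValueError(f"bioassay table needs columns {sorted(required)}")
    out = []
    for strain, sub in table.groupby("strain", sort=False):
        controls = sub[sub["dose"] == 0]
        c = float(controls["dead"].sum() / controls["n"].sum()) if len(controls) else 0.0
        if c >= 0.5:
            raise ValueError(f"control mortality too high for strain {strain!r} ({c:.0%})")
        sub = sub.copy()
        m = sub["dead"] / sub["n"]
        sub["control_mortality"] = c
        sub["corrected_mortality"] = ((m - c) / (1.0 - c)).clip(0.0, 1.0)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def _probit_nll(params: np.ndarray, x: np.ndarray, n: np.ndarray, m: np.ndarray) -> float:
    a, b = params
    p = stats.norm.cdf(a + b * x)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-(n * (m * np.log(p) + (1.0 - m) * np.log(1.0 - p))).sum())


def fit_probit(corrected: pd.DataFrame, strain: str | None = None) -> ProbitFit:
    """Maximum-likelihood probit regression of corrected mortality on log10 dose.

    Expects the output of :func:`abbott_correct`; control (dose-0) rows are
    excluded.  Requires at least three positive doses including intermediate
    mortalities (complete 0%/100% separation is rejected with advice to widen
    the dose range).  The heterogeneity chi-square sums
    (obs - exp)^2 / (n p (1 - p)) over dose-replicate cells with
    df = cells - 2.
    """
    import statsmodels.api as sm

    df = corrected if strain is None else corrected[corrected["strain"] == strain]
    df = df[df["dose"] > 0]
    if strain is None:
        strains = df["strain"].unique() if "strain" in df.columns else ["?"]
        if len(strains) != 1:
            raise ValueError("multiple strains present; pass `strain=`")
        strain = str(strains[0])
    if df["dose"].nunique() < 3:
        raise ValueError(f"strain {strain!r}: need >= 3 positive doses")
    m = df["corrected_mortality"].to_numpy(dtype=float)
    per_dose = df.groupby("dose")["corrected_mortality"].mean()
    if ((per_dose <= 0.0) | (per_dose >= 1.0)).all():
        raise ValueError(
            f"strain {strain!r}: all doses at 0% or 100% corrected mortality; "
            "the dose range does not bracket the LC50 - add intermediate doses"
        )
    x = np.log10(df["dose"].to_numpy(dtype=float))
    n = df["n"].to_numpy(dtype=float)

    model = sm.GLM(m, sm.add_constant(x), family=sm.families.Binomial(sm.families.links.Probit()), var_weights=n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200, tol=1e-10)
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            raise RuntimeError(f"probit fit failed to converge for {strain!r}: {exc}") from exc
    if not res.converged:
        raise RuntimeError(
            f"probit fit did not converge for {strain!r} after {res.fit_history['iteration']} iterations"
        )
    a, b = float(res.params[0]), float(res.params[1])
    if b <= 0:
        raise ValueError(f"strain {strain!r}: fitted slope is non-positive; mortality must increase with dose")
    cov = np.asarray(res.cov_params())

    # heterogeneity chi-square over dose x replicate cells
    p_hat = stats.norm.cdf(a + b * x)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = p_hat * (1.0 - p_hat)
        cells = var > 0
        chi2 = float((n[cells] * (m[cells] - p_hat[cells]) ** 2 / var[cells]).sum())
    chi2_df = max(int(cells.sum()) - 2, 1)
    chi2_p = float(stats.chi2.sf(chi2, chi2_df))

    lc50, lc50_ci = _lc_with_ci(a, b, cov, 0.5)
    lc95, lc95_ci = _lc_with_ci(a, b, cov, 0.95)
    return ProbitFit(
        strain=strain,
        intercept=a,
        slope=b,
        lc50=lc50,
        lc50_ci=lc50_ci,
        lc95=lc95,
        lc95_ci=lc95_ci,
        chi2=chi2,
        chi2_df=chi2_df,
        chi2_p=chi2_p,
        cov=cov,
        log_likelihood=-_probit_nll(np.array([a, b]), x, n, m),
        n_obs=len(df),
    )


def _lc_with_ci(a: float, b: float, cov: np.ndarray, p: float) -> tuple[float, tuple[float, float]]:
    """LC_p with a 95% CI on the dose scale.

    Fieller's theorem is applied to x0 = (z_p - a) / b when the slope is well
    determined (|t| >= 4 and g < 1); otherwise the delta method is used with
    a logged caveat.
    """
    z = stats.norm.ppf(p)
    x0 = (z - a) / b
    v_aa, v_ab, v_bb = cov[0, 0], cov[0, 1], cov[1, 1]
    t_slope = abs(b) / math.sqrt(v_bb)
    g = (_Z95**2) * v_bb / (b**2)
    if t_slope >= 4.0 and g < 1.0:
        # Fieller interval for the ratio (z - a) / b
        centre = x0 + g / (1.0 - g) * (x0 + v_ab / v_bb)
        disc = (
            v_aa
            + 2.0 * x0 * v_ab
            + x0**2 * v_bb
            - g * (v_aa - v_ab**2 / v_bb)
        )
        half = (_Z95 / (abs(b) * (1.0 - g))) * math.sqrt(max(disc, 0.0))
        lo, hi = centre - half, centre + half
    else:
        warnings.warn(
            "slope weakly determined (|t| < 4 or g >= 1); using delta-method CI",
            stacklevel=3,
        )
        grad = np.array([-1.0 / b, -x0 / b])
        se = math.sqrt(float(grad @ cov @ grad))
        lo, hi = x0 - _Z95 * se, x0 + _Z95 * se
    return 10.0**x0, (10.0**lo, 10.0**hi)


@dataclass(frozen=True)
class PairwiseTest:
    strain_a: str
    strain_b: str
    lr_statistic: float
    p_value: float


@dataclass(frozen=True)
class StrainComparison:
    reference: str
    rr50: dict[str, float]
    rr50_ci: dict[str, tuple[float, float]]
    rr95: dict[str, float]
    pairwise: list[PairwiseTest]
    letters: dict[str, str]
    warnings_: tuple[str, ...] = ()


def _lrt_equal_lc50(
    fit_a: ProbitFit, data_a: pd.DataFrame, fit_b: ProbitFit, data_b: pd.DataFrame
) -> PairwiseTest:
    """Likelihood-ratio test of a common LC50 (slopes free to differ)."""

    def prep(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sub = df[df["dose"] > 0]
        return (
            np.log10(sub["dose"].to_numpy(dtype=float)),
            sub["n"].to_numpy(dtype=float),
            sub["corrected_mortality"].to_numpy(dtype=float),
        )

    xa, na, ma = prep(data_a)
    xb, nb, mb = prep(data_b)

    def nll(params: np.ndarray) -> float:
        mu, ba, bb = params  # shared log10 LC50, strain-specific slopes
        return _probit_nll(np.array([-mu * ba, ba]), xa, na, ma) + _probit_nll(
            np.array([-mu * bb, bb]), xb, nb, mb
        )

    mu0 = 0.5 * (math.log10(fit_a.lc50) + math.log10(fit_b.lc50))
    res = optimize.minimize(
        nll,
        x0=np.array([mu0, fit_a.slope, fit_b.slope]),
        method="Nelder-Mead",
        options=dict(xatol=1e-8, fatol=1e-10, maxiter=4000),
    )
    ll_constrained = -res.fun
    ll_full = fit_a.log_likelihood + fit_b.log_likelihood
    lr = max(0.0, 2.0 * (ll_full - ll_constrained))
    return PairwiseTest(fit_a.strain, fit_b.strain, lr, float(stats.chi2.sf(lr, 1)))


def _letter_groups(order: list[str], significant: set[frozenset[str]]) -> dict[str, str]:
    """Compact letter display: maximal runs of mutually non-different strains
    (in LC50 order) share a letter."""
    intervals: list[tuple[int, int]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and all(
            frozenset((order[a], order[b])) not in significant
            for a in range(i, j + 2)
            for b in range(a + 1, j + 2)
        ):
            j += 1
        intervals.append((i, j))
    # drop intervals contained in another
    maximal = [
        (s, e)
        for s, e in intervals
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in intervals)
    ]
    maximal = sorted(set(maximal))
    letters: dict[str, str] = {name: "" for name in order}
    for k, (s, e) in enumerate(maximal):
        letter = chr(ord("a") + k)
        for idx in range(s, e + 1):
            letters[order[idx]] += letter
    return letters


def compare_strains(
    fits: Sequence[ProbitFit],
    corrected: pd.DataFrame,
    reference: str | None = None,
    alpha: float = 0.05,
) -> StrainComparison:
    """Resistance ratios, pairwise equal-LC50 tests and letter grouping.

    RR50 = LC50(strain) / LC50(reference) with a 95% CI from the summed
    delta-method variances of the two log10 LC50s.  Pairwise significance is
    a likelihood-ratio test of a shared LC50; the compact letter display
    assigns the same letter to strains that are not significantly different
    at ``alpha``.  Non-overlapping dose ranges only attach a warning.
    """
    if len(fits) < 2:
        raise ValueError("need at least two strains to compare")
    by_name = {f.strain: f for f in fits}
    if reference is None:
        reference = min(by_name, key=lambda s: by_name[s].lc50)
    if reference not in by_name:
        raise ValueError(f"reference strain {reference!r} not among the fits")
    ref = by_name[reference]

    notes: list[str] = []
    dose_ranges = {
        s: (
            corrected.loc[(corrected["strain"] == s) & (corrected["dose"] > 0), "dose"].min(),
            corrected.loc[(corrected["strain"] == s) & (corrected["dose"] > 0), "dose"].max(),
        )
        for s in by_name
    }
    ref_lo, ref_hi = dose_ranges[reference]
    for s, (lo, hi) in dose_ranges.items():
        if s != reference and (hi < ref_lo or lo > ref_hi):
            notes.append(f"dose ranges of {s!r} and {reference!r} do not overlap")

    rr50, rr50_ci, rr95 = {}, {}, {}
    for s, fit in by_name.items():
        rr50[s] = fit.lc50 / ref.lc50
        rr95[s] = fit.lc95 / ref.lc95
        if s == reference:
            rr50_ci[s] = (1.0, 1.0)
            continue
        var = fit.var_log10_lc(0.5) + ref.var_log10_lc(0.5)
        half = _Z95 * math.sqrt(var)
        log_rr = math.log10(rr50[s])
        rr50_ci[s] = (10.0 ** (log_rr - half), 10.0 ** (log_rr + half))

    names = sorted(by_name, key=lambda s: by_name[s].lc50)
    pairwise: list[PairwiseTest] = []
    significant: set[frozenset[str]] = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            test = _lrt_equal_lc50(
                by_name[a], corrected[corrected["strain"] == a],
                by_name[b], corrected[corrected["strain"] == b],
            )
            pairwise.append(test)
            if test.p_value < alpha:
                significant.add(frozenset((a, b)))

    letters = _letter_groups(names, significant)
    return StrainComparison(
        reference=reference,
        rr50=rr50,
        rr50_ci=rr50_ci,
        rr95=rr95,
        pairwise=pairwise,
        letters=letters,
        warnings_=tuple(notes),
    )
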