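"""qPCR relative copy-number quantification.

Copy numbers are estimated relative to a single-copy reference locus by the
efficiency-corrected ratio method: with amplification efficiencies fitted
from 10-fold standard-dilution curves, the target/reference concentration
ratio of a sample against a single-copy calibrator genotype is

    ratio = E_t ** (Cq_t(cal) - Cq_t(sample)) / E_r ** (Cq_r(cal) - Cq_r(sample))

calibrated so the single-copy control reads 1.0.  Copies per diploid
individual are then 2 x ratio, and per-chromosome counts follow from zygosity
arithmetic.  Flanking loci just outside an amplified region act as
single-copy controls delimiting the amplicon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "CopyRatioEstimate",
    "fit_standard_curve",
    "relative_quantity",
    "flanking_single_copy_check",
    "copies_per_chromosome",
    "CopyDistribution",
]

WELL_COLUMNS = ("sample", "locus", "role", "dilution_log10", "Cq")


@dataclass(frozen=True)
class StandardCurve:
    locus: str
    slope: float  # Cq per log10 quantity; negative for a valid curve
    efficiency: float  # E = 10 ** (-1 / slope), in (1, 2.2]
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class CopyRatioEstimate:
    sample: str
    locus: str
    ratio: float  # relative to the single-copy reference, calibrator == 1
    se: float
    replicates: int
    copies_per_individual: float  # = 2 * ratio (diploid)
    low_replication: bool = False  # flagged when < 2 replicates


def fit_standard_curve(wells: pd.DataFrame, locus: str | None = None) -> StandardCurve:
    """Least-squares fit of Cq on log10 relative quantity for one locus.

    Expects standard wells with ``dilution_log10`` (0, -1, -2, ... for a
    10-fold series) and ``Cq``.  Requires at least three dilution points; a
    positive fitted slope (more template, later Cq) raises a ``ValueError``.
    """
    df = wells
    if locus is not None:
        df = df[df["locus"] == locus]
    df = df[df["role"] == "standard"] if "role" in df.columns else df
    df = df.dropna(subset=["dilution_log10", "Cq"])
    points = df["dilution_log10"].nunique()
    if points < 3:
        raise ValueError(f"standard curve needs >= 3 dilution points, got {points}")
    fit = stats.linregress(df["dilution_log10"].to_numpy(), df["Cq"].to_numpy())
    if fit.slope >= 0:
        raise ValueError("inverted dilution series: fitted slope is non-negative")
    efficiency = 10.0 ** (-1.0 / fit.slope)
    return StandardCurve(
        locus=locus or (df["locus"].iloc[0] if "locus" in df.columns else ""),
        slope=float(fit.slope),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
        n_points=int(points),
    )


def _replicate_cq(wells: pd.DataFrame, sample: str, locus: str) -> np.ndarray:
    sub = wells[(wells["sample"] == sample) & (wells["locus"] == locus)]
    cq = sub["Cq"].to_numpy(dtype=float)
    if len(cq) == 0:
        raise ValueError(f"no wells for sample {sample!r}, locus {locus!r}")
    if len(cq) >= 3:
        med = np.median(cq)
        keep = np.abs(cq - med) <= 1.0
        if not keep.all():
            warnings.warn(
                f"dropped {int((~keep).sum())} outlier well(s) for {sample!r}/{locus!r}",
                stacklevel=3,
            )
            cq = cq[keep]
    return cq


def relative_quantity(
    wells: pd.DataFrame,
    sample: str,
    target_locus: str,
    reference_locus: str,
    calibrator: str,
    efficiencies: dict[str, float] | None = None,
) -> CopyRatioEstimate:
    """Efficiency-corrected target/reference ratio of a sample vs calibrator.

    Replicate wells are averaged per (sample, locus) after dropping wells
    more than 1 Cq from the replicate median; the standard error is
    propagated from the replicate scatter of all four Cq means.
    """
    if efficiencies is None:
        efficiencies = {
            locus: fit_standard_curve(wells, locus).efficiency
            for locus in (target_locus, reference_locus)
        }
    e_t = efficiencies[target_locus]
    e_r = efficiencies[reference_locus]

    groups = {
        key: _replicate_cq(wells, s, l)
        for key, (s, l) in {
            "ts": (sample, target_locus),
            "tc": (calibrator, target_locus),
            "rs": (sample, reference_locus),
            "rc": (calibrator, reference_locus),
        }.items()
    }
    means = {k: float(v.mean()) for k, v in groups.items()}
    variances = {k: float(v.var(ddof=1) / len(v)) if len(v) > 1 else 0.0 for k, v in groups.items()}

    log_ratio = (means["tc"] - means["ts"]) * math.log(e_t) - (
        means["rc"] - means["rs"]
    ) * math.log(e_r)
    ratio = math.exp(log_ratio)
    var_log = (math.log(e_t) ** 2) * (variances["tc"] + variances["ts"]) + (
        math.log(e_r) ** 2
    ) * (variances["rc"] + variances["rs"])
    se = ratio * math.sqrt(var_log)
    n_rep = min(len(v) for v in groups.values())
    return CopyRatioEstimate(
        sample=sample,
        locus=target_locus,
        ratio=ratio,
        se=se,
        replicates=n_rep,
        copies_per_individual=2.0 * ratio,
        low_replication=n_rep < 2,
    )


def flanking_single_copy_check(
    estimates: dict[str, CopyRatioEstimate],
    tolerance: float = 0.3,
) -> tuple[bool, dict[str, bool]]:
    """Check that loci flanking the amplicon are present as single copies.

    ``estimates`` maps locus label (e.g. ``5'out``, ``3'out``) to its ratio
    estimate; a locus passes when its ratio lies in [1 - tol, 1 + tol].
    Returns (all passed, per-locus verdicts).
    """
    verdicts = {
        locus: (1.0 - tolerance) <= est.ratio <= (1.0 + tolerance)
        for locus, est in estimates.items()
    }
    return all(verdicts.values()), verdicts


@dataclass(frozen=True)
class CopyDistribution:
    total_copies: float
    per_chromosome: tuple[int, int] | None  # resolved counts, else None
    resolved: bool
    note: str = ""


def copies_per_chromosome(
    total_copies: float,
    ploidy: int = 2,
    known_haplotype_copies: int | None = None,
    homozygous: bool = False,
) -> CopyDistribution:
    """Distribute a measured total copy number over homologous chromosomes.

    Homozygotes split evenly; with one haplotype of known copy count the
    other is the remainder; otherwise the distribution cannot be resolved
    from a total alone and is flagged unknown.
    """
    if total_copies <= 0:
        raise ValueError("total copies must be positive")
    if ploidy != 2:
        raise ValueError("only diploid arithmetic is supported")
    if known_haplotype_copies is not None:
        other = int(round(total_copies)) - known_haplotype_copies
        if other < 0:
            raise ValueError(
                f"known haplotype carries {known_haplotype_copies} copies but the "
                f"total is only {total_copies}"
            )
        return CopyDistribution(total_copies, (known_haplotype_copies, other), True)
    if homozygous:
        per = int(round(total_copies / 2.0))
        return CopyDistribution(total_copies, (per, per), True)
    return CopyDistribution(
        total_copies, None, False,
        note="distribution unknown: total copies alone cannot be split across chromosomes",
    )
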