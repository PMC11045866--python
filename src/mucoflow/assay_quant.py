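"""Standard-curve quantification and metabolomics preprocessing.

Covers the plate-based assays of the pipeline: carbohydrate-active enzyme
(CAZy) activity from chromogenic 4-nitrophenyl substrate release, qPCR
transcript copy number from a log10-copies standard curve, colony counts
converted to CFU per gram, and the metabolite-table preprocessing that
precedes differential-abundance screening (weight normalization, LOD
imputation at 20 % of the per-metabolite minimum, log10 transform,
fold-change x Mann-Whitney significance filter).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .stats_core import mann_whitney_exact

__all__ = [
    "StandardCurve",
    "ActivityResult",
    "fit_standard_curve",
    "enzyme_activity",
    "normalize_activities",
    "qpcr_copies",
    "cfu_per_gram",
    "metabolomics_preprocess",
    "significant_metabolites",
]


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float  # NaN when undefined (constant response)
    n_points: int

    def invert(self, signal: float) -> float:
        """Concentration (or log10 copies) producing ``signal``."""
        if self.slope == 0:
            raise ValueError("cannot invert a flat standard curve")
        return (signal - self.intercept) / self.slope


@dataclass(frozen=True)
class ActivityResult:
    sample_id: str
    enzyme: str
    activity: float  # uM / min / mg protein
    replicate_values: tuple
    qc_flag: str | None = None
    normalized_share: float | None = None


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least-squares line through (x, signal) standards.

    Requires >= 4 points with >= 3 distinct x values (a serial dilution
    easily satisfies this).  r^2 is reported as NaN when the response is
    constant.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, signal) pairs")
    if len(pts) < 4:
        raise ValueError("need >= 4 standard points")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values")
    if np.allclose(y, y[0]):
        return StandardCurve(0.0, float(y[0]), float("nan"), len(pts))
    fit = linregress(x, y)
    return StandardCurve(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), len(pts)
    )


def enzyme_activity(
    signal,
    curve: StandardCurve,
    time_min: float = 45.0,
    protein_mg: float = 1.0,
    sample_id: str = "",
    enzyme: str = "",
) -> ActivityResult:
    """Endpoint enzyme activity in uM released per minute per mg protein.

    ``signal`` may be a scalar or an iterable of duplicate readings, which
    are averaged before inversion.  Released concentration below the curve
    blank (negative after inversion) is floored at zero with a QC flag.
    """
    if time_min <= 0 or protein_mg <= 0:
        raise ValueError("time_min and protein_mg must be > 0")
    sig = np.atleast_1d(np.asarray(signal, dtype=float))
    conc = curve.invert(float(sig.mean()))
    qc = None
    if conc < 0:
        conc, qc = 0.0, "below_blank"
    activity = conc / (time_min * protein_mg)
    return ActivityResult(sample_id, enzyme, float(activity), tuple(sig), qc)


def normalize_activities(results) -> dict[str, float]:
    """Relative contribution of each enzyme to a mouse's total activity.

    ``results`` maps enzyme -> activity (or is a list of ActivityResult for
    one mouse).  Shares sum to 1; an all-zero mouse is undefined (empty dict
    with a warning) rather than 0/0.
    """
    if isinstance(results, dict):
        acts = {k: float(v) for k, v in results.items()}
    else:
        acts = {r.enzyme: r.activity for r in results}
    if any(v < 0 for v in acts.values()):
        raise ValueError("activities must be >= 0")
    total = sum(acts.values())
    if total == 0:
        warnings.warn("all activities zero; shares undefined", stacklevel=2)
        return {}
    return {k: v / total for k, v in acts.items()}


def qpcr_copies(
    cq: float,
    curve: StandardCurve,
    rna_input_ng: float = 10.0,
    report_basis_ng: float = 10.0,
) -> float:
    """Transcript copies per ``report_basis_ng`` (default 10 ng) of RNA.

    The curve is Cq vs log10(copies); copies = 10^((cq - intercept)/slope),
    rescaled from the reaction's RNA input to the reporting basis.  A Cq
    outside the fitted standard range triggers an extrapolation warning.
    """
    if rna_input_ng <= 0 or report_basis_ng <= 0:
        raise ValueError("RNA amounts must be > 0")
    log10_copies = curve.invert(float(cq))
    copies = 10.0 ** log10_copies
    return copies * report_basis_ng / rna_input_ng


def cfu_per_gram(
    colonies: int,
    dilution_factor: float,
    plated_volume_ml: float,
    sample_mass_g: float,
    suspension_volume_ml: float = 1.0,
    lod_colonies: int = 1,
) -> tuple[float, bool]:
    """Viable count per gram from dilution plating.

    CFU/g = colonies x dilution / plated volume x suspension volume / mass.
    Zero colonies are reported at the limit of detection (the value a single
    colony would give) and flagged censored; returns (value, censored).
    """
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    for name, v in [
        ("dilution_factor", dilution_factor),
        ("plated_volume_ml", plated_volume_ml),
        ("sample_mass_g", sample_mass_g),
        ("suspension_volume_ml", suspension_volume_ml),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    scale = dilution_factor / plated_volume_ml * suspension_volume_ml / sample_mass_g
    if colonies == 0:
        return lod_colonies * scale, True
    return colonies * scale, False


def metabolomics_preprocess(
    peaks: pd.DataFrame, sample_weights: pd.Series
) -> tuple[pd.DataFrame, list]:
    """Weight-normalize, LOD-impute and log10-transform a peak-area table.

    ``peaks`` is samples x metabolites with NaN marking missing peaks;
    ``sample_weights`` gives the sample mass (mg).  Per sample the areas
    are divided by weight; per metabolite missing values are replaced by
    20 % of the minimum positive normalized value; all values are then
    log10-transformed.  Metabolites with no positive value are dropped and
    reported.  Returns (processed table, dropped metabolites).
    """
    peaks = pd.DataFrame(peaks)
    weights = pd.Series(sample_weights).loc[peaks.index]
    if (weights <= 0).any():
        bad = list(weights.index[weights <= 0])
        raise ValueError(f"nonpositive sample weights: {bad}")
    vals = peaks.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] < 0):
        raise ValueError("peak areas must be >= 0 or missing")
    norm = peaks.div(weights, axis=0)

    dropped = []
    out = {}
    for met in norm.columns:
        col = norm[met]
        positive = col[col > 0]
        if positive.empty:
            dropped.append(met)
            continue
        lod = 0.2 * positive.min()
        filled = col.where(col.notna() & (col > 0), lod)
        out[met] = np.log10(filled)
    if dropped:
        warnings.warn(f"dropping all-missing metabolites: {dropped}", stacklevel=2)
    return pd.DataFrame(out, index=norm.index), dropped


def significant_metabolites(
    normalized: pd.DataFrame,
    groups: pd.Series,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential screen on weight-normalized intensities.

    A metabolite is significant iff its group-mean fold change is >=
    ``fc_threshold`` (or <= 1/fc_threshold) AND the two-sided exact
    Mann-Whitney p-value is < ``p_threshold``.  ``normalized`` holds
    weight-normalized, unlogged intensities (fold change convention);
    ``groups`` maps each sample to one of exactly two labels.

    Returns a table with fold_change, p_value and significant per
    metabolite (fold change is group2 over group1 in sorted label order).
    """
    groups = pd.Series(groups).loc[normalized.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    g1 = normalized.loc[groups == labels[0]]
    g2 = normalized.loc[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 samples")

    rows = {}
    for met in normalized.columns:
        m1, m2 = g1[met].mean(), g2[met].mean()
        fc = m2 / m1 if m1 > 0 else math.inf
        res = mann_whitney_exact(g1[met].to_numpy(), g2[met].to_numpy())
        sig = (fc >= fc_threshold or fc <= 1.0 / fc_threshold) and (
            res.p_value < p_threshold
        )
        rows[met] = {
            "fold_change": fc,
            "p_value": res.p_value,
            "exact": res.exact,
            "significant": sig,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
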