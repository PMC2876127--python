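"""Quality control, background correction, M/A computation and loess
normalization for two-color genomic hybridizations.

The normalization step is the scientifically loaded one: in a
cross-species hybridization a large share of features carry genuinely
depressed ratios (divergence, not dye bias), so fitting the loess curve on
all features drags the baseline down and manufactures false "excess"
calls.  :func:`loess_normalize` therefore supports fitting the curve on a
conserved-gene subset only, while applying the correction to every
feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import QC_LOW_SIGNAL, QC_OK, QC_TECHNICAL_ERROR, ValidationError

__all__ = [
    "apply_qc",
    "filter_min_arrays",
    "background_correct_minimum",
    "compute_ma",
    "loess_normalize",
    "NORMALIZATION_SETS",
]

NORMALIZATION_SETS = ("all", "conserved_1000", "conserved_100")


def apply_qc(scan: pd.DataFrame, n_sd: float = 2.0) -> pd.DataFrame:
    """Flag poor-quality features: foreground < ``n_sd`` SDs above background.

    A feature passes on an array only if, in *both* channels,
    ``fg - bg >= n_sd * bg_sd`` holds strictly... more precisely the flag is
    raised when ``fg - bg < n_sd * bg_sd`` in either channel (a foreground
    exactly at the threshold is flagged).  Pre-existing ``technical_error``
    flags are preserved.
    """
    out = scan.copy()
    # boundary is flagged: passing requires strictly more than n_sd SDs
    low1 = (out["fg1"] - out["bg1"]) <= n_sd * out["bg1_sd"]
    low2 = (out["fg2"] - out["bg2"]) <= n_sd * out["bg2_sd"]
    keep_tech = out["qc_flag"] == QC_TECHNICAL_ERROR
    out["qc_flag"] = np.where(
        keep_tech, QC_TECHNICAL_ERROR, np.where(low1 | low2, QC_LOW_SIGNAL, QC_OK)
    )
    return out


def filter_min_arrays(scan: pd.DataFrame, min_arrays: int = 2) -> set[str]:
    """Feature ids that pass QC on at least ``min_arrays`` arrays."""
    n_arrays = scan["array_id"].nunique()
    if min_arrays > n_arrays:
        raise ValidationError(
            f"min_arrays={min_arrays} exceeds the number of arrays ({n_arrays})"
        )
    ok = scan[scan["qc_flag"] == QC_OK]
    counts = ok.groupby("feature_id").size()
    return set(counts.index[counts >= min_arrays])


def background_correct_minimum(scan: pd.DataFrame) -> pd.DataFrame:
    """Subtract background; rescue nonpositive values to half the minimum
    positive corrected value of that array/channel ("minimum" correction).
    """
    out = scan.copy()
    for ch in ("1", "2"):
        corrected = out[f"fg{ch}"] - out[f"bg{ch}"]
        out[f"corrected{ch}"] = corrected
        for array_id, idx in out.groupby("array_id").groups.items():
            vals = out.loc[idx, f"corrected{ch}"]
            positive = vals[vals > 0]
            if len(positive) == 0:
                raise ValidationError(
                    f"array {array_id} channel {ch}: no positive corrected intensity"
                )
            floor = positive.min() / 2.0
            out.loc[idx, f"corrected{ch}"] = vals.where(vals > 0, floor)
    return out


def compute_ma(corrected: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """M/A transform with dye-swap sign resolution.

    With ``t`` the test-channel and ``r`` the reference-channel corrected
    intensity (channel roles taken from the design's dye orientation):
    ``M = log2(t/r)``, ``A = (log2 t + log2 r)/2``.  Positive M always
    means excess in the test sample, regardless of dye orientation.
    ``included`` records whether the (array, feature) passed QC.
    """
    orient = design.set_index("array_id")["dye_orientation"]
    missing = set(corrected["array_id"]) - set(orient.index)
    if missing:
        raise ValidationError(f"arrays absent from design: {sorted(missing)}")
    o = corrected["array_id"].map(orient).to_numpy()
    c1 = corrected["corrected1"].to_numpy(dtype=float)
    c2 = corrected["corrected2"].to_numpy(dtype=float)
    if np.any(c1 <= 0) or np.any(c2 <= 0):
        raise ValidationError("corrected intensities must be positive")
    t = np.where(o == 1, c1, c2)
    r = np.where(o == 1, c2, c1)
    return pd.DataFrame({
        "array_id": corrected["array_id"],
        "feature_id": corrected["feature_id"],
        "M": np.log2(t / r),
        "A": (np.log2(t) + np.log2(r)) / 2.0,
        "included": (corrected["qc_flag"] == QC_OK).to_numpy(),
    })


def _fit_set_ids(normalization_set: str, annotation: pd.DataFrame) -> set[str]:
    if normalization_set == "all":
        return set(annotation["feature_id"])
    if normalization_set in ("conserved_1000", "conserved_100"):
        return set(annotation.loc[annotation[normalization_set], "feature_id"])
    raise ValueError(
        f"unknown normalization set {normalization_set!r}; "
        f"expected one of {NORMALIZATION_SETS}"
    )


def loess_normalize(
    ma: pd.DataFrame,
    normalization_set: str,
    annotation: pd.DataFrame,
    span: float = 0.4,
    iterations: int = 0,
    min_subset: int = 30,
) -> pd.DataFrame:
    """Within-array loess normalization of M on A, fit on a gene subset.

    Per array, a locally weighted regression (degree 1, ``span`` fraction,
    ``iterations`` robustness iterations — default none, because bisquare
    reweighting mistakes the tails of a strong smooth dye trend for
    outliers and leaves a residual tilt) of M on A is fitted using only
    the included features of ``normalization_set`` ("all",
    "conserved_1000" or "conserved_100"), then the fitted curve is
    evaluated at every feature's A and subtracted from every feature's M.
    Evaluation beyond the subset's A-range clamps to the boundary fitted
    value, avoiding runaway extrapolation.
    """
    fit_ids = _fit_set_ids(normalization_set, annotation)
    out = ma.copy()
    for array_id, idx in out.groupby("array_id").groups.items():
        sub = out.loc[idx]
        fit_mask = (
            sub["included"]
            & sub["feature_id"].isin(fit_ids)
            & np.isfinite(sub["M"])
            & np.isfinite(sub["A"])
        )
        n_fit = int(fit_mask.sum())
        if n_fit < min_subset:
            raise ValidationError(
                f"array {array_id}: normalization set {normalization_set!r} has "
                f"only {n_fit} usable features (< {min_subset})"
            )
        a_fit = sub.loc[fit_mask, "A"].to_numpy(dtype=float)
        m_fit = sub.loc[fit_mask, "M"].to_numpy(dtype=float)
        delta = 0.005 * (a_fit.max() - a_fit.min())
        curve = lowess(
            m_fit, a_fit, frac=span, it=iterations, delta=delta, return_sorted=True
        )
        # np.interp clamps to the boundary fitted values outside the range
        correction = np.interp(
            sub["A"].to_numpy(dtype=float), curve[:, 0], curve[:, 1]
        )
        out.loc[idx, "M"] = sub["M"].to_numpy(dtype=float) - correction
    return out
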