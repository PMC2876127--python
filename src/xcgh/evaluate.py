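"""Ground-truth evaluation of genomic-excess calls.

Rate conventions (fixed throughout):

- true positives: X-linked features called in excess;
- false negatives: X-linked features not called; ``tp + fn`` equals the
  number of analyzable X features and the TP/FN rates share that
  denominator;
- false positives: autosomal features called in excess; the FP *rate* is
  the fraction of all excess calls that map to autosomes,
  ``fp / (tp + fp)`` (0 when nothing is called).  A secondary column
  reports the fraction of analyzable autosomal features called, which is a
  different quantity and is never used as "the" FP rate.

Percentages are rounded half-up to whole percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = [
    "EvaluationSummary",
    "ConfounderBreakdown",
    "rates_from_counts",
    "percent",
    "summarize_calls",
    "detection_by_divergence",
    "pooled_detection",
    "classify_error_confounders",
    "explained_fraction",
    "fn_copy_ratio_correlation",
    "build_report",
    "FN_CATEGORIES",
    "FP_CATEGORIES",
]

FN_CATEGORIES = ("no_hit", "autosomal_only", "tel_het", "ref_not_found",
                 "ref_hits_gt_het")
FP_CATEGORIES = ("het_x_hit", "tel_het", "het_hits_gt_ref")


def percent(x: float) -> int:
    """Round a fraction to whole percent, half-up (0.165 -> 17)."""
    return int(math.floor(100.0 * x + 0.5))


@dataclass
class EvaluationSummary:
    species: str
    normalization: str
    n_x_analyzed: int
    tp: int
    fp: int
    fn: int
    tp_rate: float
    fp_rate: float
    fn_rate: float
    #: fraction of analyzable autosomal features called (secondary measure)
    fp_rate_autosomal: float = float("nan")

    @property
    def tp_pct(self) -> int:
        return percent(self.tp_rate)

    @property
    def fp_pct(self) -> int:
        return percent(self.fp_rate)

    @property
    def fn_pct(self) -> int:
        return percent(self.fn_rate)

    def as_row(self) -> dict:
        return {
            "species": self.species,
            "normalization": self.normalization,
            "n_x_analyzed": self.n_x_analyzed,
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "tp_rate": self.tp_rate, "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
            "tp_pct": self.tp_pct, "fp_pct": self.fp_pct, "fn_pct": self.fn_pct,
            "fp_rate_autosomal": self.fp_rate_autosomal,
        }


def rates_from_counts(
    tp: int, fp: int, fn: int, species: str = "", normalization: str = ""
) -> EvaluationSummary:
    """Rates from raw counts: TP/FN share the X denominator, FP uses calls."""
    n_x = tp + fn
    tp_rate = tp / n_x if n_x else 0.0
    fn_rate = fn / n_x if n_x else 0.0
    fp_rate = fp / (tp + fp) if (tp + fp) else 0.0
    return EvaluationSummary(
        species=species, normalization=normalization, n_x_analyzed=n_x,
        tp=tp, fp=fp, fn=fn,
        tp_rate=tp_rate, fp_rate=fp_rate, fn_rate=fn_rate,
    )


def summarize_calls(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    analyzable_ids=None,
    species: str = "",
    normalization: str = "",
) -> EvaluationSummary:
    """Score excess calls against X-linkage (the planted duplication)."""
    ann = annotation.set_index("feature_id")
    missing = set(results["feature_id"]) - set(ann.index)
    if missing:
        raise ValidationError(
            f"results contain unannotated features: {sorted(missing)[:10]}"
        )
    res = results
    if analyzable_ids is not None:
        res = res[res["feature_id"].isin(set(analyzable_ids))]
    is_x = res["feature_id"].map(ann["is_x"]).to_numpy(dtype=bool)
    called = res["called_excess"].to_numpy(dtype=bool)
    tp = int((is_x & called).sum())
    fn = int((is_x & ~called).sum())
    fp = int((~is_x & called).sum())
    n_auto = int((~is_x).sum())
    summary = rates_from_counts(tp, fp, fn, species, normalization)
    summary.fp_rate_autosomal = fp / n_auto if n_auto else float("nan")
    return summary


def detection_by_divergence(
    results: pd.DataFrame,
    profile: pd.DataFrame,
    annotation: pd.DataFrame,
    bin_width_pct: float = 1.0,
    exclude_below_pct: float = 1.0,
    low_support_n: int = 5,
) -> pd.DataFrame:
    """Per-divergence-bin detection proportion for X-linked features.

    Divergence is ``100 - top_hit_pid`` percent; features without a
    qualifying heterologous hit are excluded, as are bins below
    ``exclude_below_pct`` (near-identical features carry no information
    about divergence effects).  Bins are ``[k, k + width)``; bins with
    fewer than ``low_support_n`` features are flagged.
    """
    ann = annotation.set_index("feature_id")
    merged = results.merge(
        profile[["feature_id", "top_hit_pid"]], on="feature_id", how="left"
    )
    merged["is_x"] = merged["feature_id"].map(ann["is_x"]).astype(bool)
    use = merged[merged["is_x"] & merged["top_hit_pid"].notna()].copy()
    use["divergence_pct"] = 100.0 - use["top_hit_pid"]
    use = use[use["divergence_pct"] >= exclude_below_pct]
    if len(use) == 0:
        return pd.DataFrame(
            columns=["bin_low", "bin_high", "n", "n_called", "proportion",
                     "low_support"]
        )
    k = np.floor(use["divergence_pct"] / bin_width_pct).astype(int)
    rows = []
    for bin_idx, grp in use.groupby(k):
        rows.append({
            "bin_low": bin_idx * bin_width_pct,
            "bin_high": (bin_idx + 1) * bin_width_pct,
            "n": len(grp),
            "n_called": int(grp["called_excess"].sum()),
            "proportion": float(grp["called_excess"].mean()),
            "low_support": len(grp) < low_support_n,
        })
    return pd.DataFrame(rows).sort_values("bin_low").reset_index(drop=True)


def pooled_detection(
    results: pd.DataFrame,
    profile: pd.DataFrame,
    annotation: pd.DataFrame,
    lo_pct: float,
    hi_pct: float,
) -> tuple[float, int]:
    """Detection proportion of X features pooled over a divergence window
    ``[lo_pct, hi_pct)``; returns (proportion, n)."""
    ann = annotation.set_index("feature_id")
    merged = results.merge(
        profile[["feature_id", "top_hit_pid"]], on="feature_id", how="left"
    )
    is_x = merged["feature_id"].map(ann["is_x"]).astype(bool)
    div = 100.0 - merged["top_hit_pid"]
    use = merged[is_x & div.notna() & (div >= lo_pct) & (div < hi_pct)]
    if len(use) == 0:
        return float("nan"), 0
    return float(use["called_excess"].mean()), len(use)


@dataclass
class ConfounderBreakdown:
    direction: str  # "false_negative" or "false_positive"
    categories: dict[str, set] = field(default_factory=dict)
    union_count: int = 0
    total_errors: int = 0

    @property
    def explained_fraction(self) -> float:
        if self.total_errors == 0:
            return float("nan")
        return self.union_count / self.total_errors


def classify_error_confounders(
    error_ids,
    direction: str,
    annotation: pd.DataFrame,
    profile: pd.DataFrame,
) -> ConfounderBreakdown:
    """Assign erroneous calls to chromosomal confounder categories.

    False negatives (X features not called): ``no_hit`` (no heterologous
    hit at all — candidate deletion), ``autosomal_only`` (hits only on
    heterologous autosomes — movement off the X), ``tel_het``
    (heterochromatin/telomere hits), ``ref_not_found`` (no qualifying hit
    to the platform genome), ``ref_hits_gt_het`` (more similar regions in
    the platform genome than the heterologous one, hit ratio < 1).

    False positives (autosomal features called): ``het_x_hit`` (hit on the
    heterologous X — movement onto the X), ``tel_het``,
    ``het_hits_gt_ref`` (hit ratio > 1 — candidate real duplication).

    A feature may fall in several categories; the total explained is the
    size of the union, not the column sum.
    """
    error_ids = set(error_ids)
    if direction not in ("false_negative", "false_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    ann = annotation.set_index("feature_id")
    prof = profile[profile["feature_id"].isin(error_ids)].copy()
    missing = error_ids - set(prof["feature_id"])
    if missing:
        raise ValidationError(
            f"no divergence profile for error features: {sorted(missing)[:10]}"
        )
    is_x = prof["feature_id"].map(ann["is_x"]).astype(bool)
    if direction == "false_negative":
        if not is_x.all():
            raise ValueError("false negatives must be X-linked features")
        cats = {
            "no_hit": prof["no_hit"],
            "autosomal_only": prof["autosomal_only"],
            "tel_het": prof["tel_or_het"],
            "ref_not_found": prof["ref_not_found"],
            "ref_hits_gt_het": prof["hit_ratio"] < 1,
        }
    else:
        if is_x.any():
            raise ValueError("false positives must be autosomal features")
        cats = {
            "het_x_hit": prof["het_x_hit"],
            "tel_het": prof["tel_or_het"],
            "het_hits_gt_ref": prof["hit_ratio"] > 1,
        }
    sets = {
        name: set(prof.loc[mask.fillna(False).astype(bool), "feature_id"])
        for name, mask in cats.items()
    }
    union = set().union(*sets.values()) if sets else set()
    return ConfounderBreakdown(
        direction=direction,
        categories=sets,
        union_count=len(union),
        total_errors=len(error_ids),
    )


def explained_fraction(breakdown: ConfounderBreakdown):
    """Whole-percent (half-up) fraction of errors explained by the union of
    confounder categories; ``None`` when there are no errors."""
    if breakdown.total_errors == 0:
        return None
    return percent(breakdown.union_count / breakdown.total_errors)


def fn_copy_ratio_correlation(
    results: pd.DataFrame, fn_ids, copy_ratio: pd.Series, min_n: int = 10
):
    """Pearson correlation of false-negative coefficients with the log2
    copy-ratio proxy (hit-count ratio, or the true copy ratio in
    simulation).  Returns (r, p), or (nan, nan) when undefined.
    """
    fn_ids = set(fn_ids)
    res = results[results["feature_id"].isin(fn_ids)]
    proxy = res["feature_id"].map(copy_ratio)
    ok = proxy.notna() & (proxy > 0) & np.isfinite(res["coef"])
    x = np.log2(proxy[ok].to_numpy(dtype=float))
    y = res.loc[ok, "coef"].to_numpy(dtype=float)
    if len(x) < min_n:
        raise ValueError(
            f"only {len(x)} false negatives with a copy-ratio proxy (< {min_n})"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def identity_variance_explained(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    analyzable,
    species: str,
) -> float:
    """R-squared of a linear regression of per-feature mean log ratio on
    sequence identity, over analyzable single-copy, unconfounded autosomal
    features — the share of hybridization-ratio variation attributable to
    divergence alone."""
    t = truth.set_index("feature_id")
    clean = ~(t["deleted"] | t["paralog_family"] | t["heterochromatic"]
              | t["moved_off_x"] | t["moved_onto_x"]) & ~t["is_x"]
    ids = set(t.index[clean]) & set(analyzable)
    res = results[results["feature_id"].isin(ids)]
    ident = res["feature_id"].map(t[f"identity_{species}"])
    fit = stats.linregress(ident, res["coef"])
    return float(fit.rvalue**2)


def build_report(
    summaries: list[EvaluationSummary],
    out_dir,
    fn_breakdowns: dict[str, ConfounderBreakdown] | None = None,
    fp_breakdowns: dict[str, ConfounderBreakdown] | None = None,
    divergence_curves: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Write rate, confounder and divergence-curve tables to ``out_dir``.

    Idempotent: regenerating from the same inputs reproduces the files
    byte-identically.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([s.as_row() for s in summaries]).to_csv(
        out_dir / "evaluation_summary.tsv", sep="\t", index=False
    )
    for label, breakdowns, cats in (
        ("confounders_fn.tsv", fn_breakdowns, FN_CATEGORIES),
        ("confounders_fp.tsv", fp_breakdowns, FP_CATEGORIES),
    ):
        if not breakdowns:
            continue
        rows = []
        for name, b in breakdowns.items():
            row = {"label": name, "total_errors": b.total_errors}
            for cat in cats:
                row[cat] = len(b.categories.get(cat, set()))
            row["total_explained"] = b.union_count
            row["explained_pct"] = explained_fraction(b)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / label, sep="\t", index=False)
    if divergence_curves:
        frames = []
        for name, curve in divergence_curves.items():
            c = curve.copy()
            c.insert(0, "label", name)
            frames.append(c)
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / "divergence_curve.tsv", sep="\t", index=False
        )
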