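"""Genomic-excess calling: per-feature means, empirical-Bayes variance
moderation, FDR control, and the GEL50 power summary.

Each feature's normalized, sign-resolved log ratios across replicate
arrays are reduced to a one-sample problem (the dye swap is resolved
upstream, and the design carries no other covariates): ``coef`` is the
mean M, ``s2`` the sample variance with ``df = n - 1``.  Per-feature
variances are then shrunk toward a prior (d0, s0^2) estimated across all
features from the scaled-F behaviour of sample variances, yielding a
moderated t with ``d0 + df`` degrees of freedom — the standard
empirical-Bayes treatment for few-replicate two-color arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModerationPrior",
    "fit_feature_means",
    "estimate_moderation_prior",
    "moderate",
    "bh_adjust",
    "call_excess",
    "gel50",
    "run_tests",
]


@dataclass
class ModerationPrior:
    """Prior degrees of freedom and variance for moderation.

    ``d0`` may be ``inf`` when the observed spread of log sample variances
    does not exceed its theoretical sampling spread (no evidence of
    variance heterogeneity); moderation then replaces every variance by
    ``s0_sq`` and the moderated t reduces to a z-statistic.
    """

    d0: float
    s0_sq: float


def fit_feature_means(ma: pd.DataFrame, feature_ids=None) -> pd.DataFrame:
    """Per-feature mean, unbiased variance and residual df of included M.

    ``ma`` is a normalized M/A table across arrays with an ``included``
    flag; ``feature_ids`` optionally restricts to the analyzable set.
    Every feature reaching this stage must be included on >= 2 arrays.
    """
    use = ma[ma["included"]]
    if feature_ids is not None:
        use = use[use["feature_id"].isin(set(feature_ids))]
    g = use.groupby("feature_id")["M"]
    res = pd.DataFrame({
        "coef": g.mean(),
        "s2": g.var(ddof=1),
        "n_included": g.size(),
    })
    if (res["n_included"] < 2).any():
        bad = res.index[res["n_included"] < 2][:5].tolist()
        raise ValueError(
            f"features with < 2 included arrays reached fitting: {bad}"
        )
    res["df"] = res["n_included"] - 1
    return res.reset_index()


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    # method-of-moments style start: trigamma(x) ~ 1/x + 1/(2x^2)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def estimate_moderation_prior(s2, df) -> ModerationPrior:
    """Estimate (d0, s0^2) by moment matching on log sample variances.

    Under the hierarchical model ``s2 ~ s0^2 * F(df, d0)``, the log sample
    variance has closed-form mean and variance in terms of digamma and
    trigamma functions.  Matching the empirical variance of
    ``log s2 - digamma(df/2) + log(df/2)`` against
    ``trigamma(df/2) + trigamma(d0/2)`` gives d0 (by trigamma inversion,
    Newton, tol 1e-8); the mean then gives s0^2.  When the empirical
    spread does not exceed the theoretical sampling spread, d0 = +inf.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if not ok.any() or np.all(s2[ok] == 0):
        raise ValueError("cannot estimate a variance prior: no positive s2")
    if ok.sum() < 50:
        raise ValueError(
            f"cannot estimate a variance prior from {int(ok.sum())} features (< 50)"
        )
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return ModerationPrior(d0=float(d0), s0_sq=float(s0_sq))


def moderate(
    results: pd.DataFrame, prior: ModerationPrior, one_sided: bool = False
) -> pd.DataFrame:
    """Shrink variances toward the prior and compute moderated t and p.

    ``s2_moderated = (d0 s0^2 + df s2) / (d0 + df)`` (``s0^2`` when d0 is
    infinite), ``t = coef / sqrt(s2_moderated / n_included)``, p from the t
    distribution with ``d0 + df`` degrees of freedom (normal tail when d0
    is infinite).  Two-sided by default; directionality is enforced at the
    call stage, or set ``one_sided`` for an upper-tail p.
    """
    out = results.copy()
    df = out["df"].to_numpy(dtype=float)
    s2 = out["s2"].to_numpy(dtype=float)
    n = out["n_included"].to_numpy(dtype=float)
    if np.isinf(prior.d0):
        s2_mod = np.full_like(s2, prior.s0_sq)
    else:
        s2_mod = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
    t = out["coef"].to_numpy(dtype=float) / np.sqrt(s2_mod / n)
    df_total = df + prior.d0
    if np.isinf(prior.d0):
        upper = stats.norm.sf(t)
        two = 2.0 * stats.norm.sf(np.abs(t))
    else:
        upper = stats.t.sf(t, df_total)
        two = 2.0 * stats.t.sf(np.abs(t), df_total)
    out["s2_moderated"] = s2_mod
    out["t_moderated"] = t
    out["p"] = upper if one_sided else two
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_excess(results: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """Call genomic excess: FDR-adjusted q below alpha AND positive coef."""
    out = results.copy()
    out["called_excess"] = (out["q"] < alpha) & (out["coef"] > 0)
    return out


def run_tests(
    ma: pd.DataFrame,
    feature_ids=None,
    alpha: float = 0.1,
    one_sided: bool = False,
) -> tuple[pd.DataFrame, ModerationPrior]:
    """Full testing stage: fit, estimate prior, moderate, adjust, call."""
    res = fit_feature_means(ma, feature_ids)
    prior = estimate_moderation_prior(res["s2"], res["df"])
    res = moderate(res, prior, one_sided=one_sided)
    res["q"] = bh_adjust(res["p"])
    res = call_excess(res, alpha=alpha)
    return res, prior


def gel50(
    prior: ModerationPrior,
    df_typical: int,
    n_arrays: int,
    alpha: float = 0.1,
    n_sim: int = 2000,
    seed: int = 0,
    mu_grid=None,
    alt_fraction: float = 0.1,
) -> float:
    """Monte-Carlo log2-ratio level at which detection power reaches 50%.

    For each true level mu on the grid, features are simulated with true
    variances drawn from the fitted prior (point mass at ``s0_sq`` when d0
    is infinite), sample means and variances drawn at ``n_arrays``
    replicates, then pushed through moderation, BH adjustment and excess
    calling inside a background of null features.  Returns the mu at which
    the detection proportion crosses 0.5 (linear interpolation between
    grid points); ``inf`` with a warning if it never does.  Deterministic
    given ``seed``.
    """
    if mu_grid is None:
        mu_grid = np.arange(0.0, 1.5001, 0.05)
    mu_grid = np.asarray(mu_grid, dtype=float)
    rng = np.random.default_rng(seed)
    n_alt = max(1, int(round(alt_fraction * n_sim)))
    n_null = n_sim - n_alt
    power = np.empty_like(mu_grid)
    for k, mu in enumerate(mu_grid):
        means = np.concatenate([np.full(n_alt, mu), np.zeros(n_null)])
        if np.isinf(prior.d0):
            v = np.full(n_sim, prior.s0_sq)
        else:
            v = prior.s0_sq * prior.d0 / rng.chisquare(prior.d0, size=n_sim)
        coef = rng.normal(means, np.sqrt(v / n_arrays))
        s2 = v * rng.chisquare(df_typical, size=n_sim) / df_typical
        res = pd.DataFrame({
            "coef": coef,
            "s2": s2,
            "df": df_typical,
            "n_included": n_arrays,
        })
        res = moderate(res, prior)
        res["q"] = bh_adjust(res["p"])
        res = call_excess(res, alpha=alpha)
        power[k] = res["called_excess"].to_numpy()[:n_alt].mean()
    above = np.flatnonzero(power >= 0.5)
    if len(above) == 0:
        warnings.warn("detection power never reaches 0.5 on the mu grid")
        return float("inf")
    i = above[0]
    if i == 0:
        return float(mu_grid[0])
    x0, x1 = mu_grid[i - 1], mu_grid[i]
    y0, y1 = power[i - 1], power[i]
    return float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0))
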