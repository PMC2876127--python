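"""Synthetic cross-species genomic hybridization data with ground truth.

The generator emulates a female-test versus male-reference two-color aCGH
experiment on a platform built from the reference species.  X-linked
features are the planted "duplicates": a female test sample carries two X
copies against the male reference's one, so every X feature has a true
copy ratio of 2:1 (log2 ratio +1) while autosomes sit at 2:2 (log2 ratio 0).

Cross-species divergence enters through a per-feature sequence identity of
the test-species ortholog to the platform probe, drawn from a per-species
truncated normal.  Identity maps to hybridization efficiency through a
linear-with-clamp curve ``h(id) = max(0, 1 - beta_div * (1 - id))``, so the
expected log ratio of a diverged X ortholog is ``1 + log2 h(id)`` — the
duplication signal is progressively masked and eventually erased as
divergence grows.

On top of the copy/divergence signal the generator layers: a per-feature
probe effect shared across arrays (sequence characteristics such as GC and
indels), per-array measurement noise with feature-to-feature variance
heterogeneity (inverse-chi-square distributed true variances, which is what
makes variance moderation worthwhile downstream), a smooth intensity-
dependent dye-bias curve whose sign flips with dye orientation, and
chromosomal confounders (deletions, X movement, paralog families,
heterochromatic suppression) mirrored consistently into fabricated BLAST
hit tables so the confounder classifier can be validated against the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    QC_OK,
    QC_TECHNICAL_ERROR,
    ValidationError,
)

__all__ = [
    "IdentityModel",
    "DyeBias",
    "ConfounderProbs",
    "SimulationConfig",
    "ConfigurationError",
    "PLATFORM",
    "simulate_truth",
    "hybridization_efficiency",
    "expected_log_ratio",
    "expected_observed_log_ratio",
    "make_design",
    "simulate_arrays",
    "simulate_hit_tables",
    "dye_bias_curve",
]


class ConfigurationError(ValueError):
    """Simulation configuration violates a validity constraint."""


PLATFORM = "platform"

# Euchromatic chromosome arms of a Drosophila-like genome plus one
# heterochromatic scaffold.  Same naming in both genomes so an ortholog's
# hit lands on the like-named chromosome unless a movement confounder says
# otherwise.
_CHROMOSOMES = [
    # name, length_bp, is_x, is_heterochromatin
    ("X", 23_500_000, True, False),
    ("2L", 23_000_000, False, False),
    ("2R", 21_100_000, False, False),
    ("3L", 24_500_000, False, False),
    ("3R", 27_900_000, False, False),
    ("het_scaffold", 8_000_000, False, True),
]
_AUTOSOME_ARMS = ["2L", "2R", "3L", "3R"]


@dataclass
class IdentityModel:
    """Truncated-normal model of per-feature sequence identity (0..1)."""

    mean_identity: float
    sd_identity: float
    min_identity: float = 0.75


@dataclass
class DyeBias:
    """Smooth intensity-dependent dye bias, an odd cubic in centered A.

    ``d(A) = amplitude * (z**3 - 3 z) / 2`` with ``z = (A - a_mean)/a_sd``
    (a scaled third Hermite polynomial: mean zero under the A distribution,
    so the bias tilts the M-A cloud without shifting its center).
    """

    amplitude: float = 0.15


@dataclass
class ConfounderProbs:
    """Independent per-feature probabilities of chromosomal confounders."""

    paralog_family: float = 0.02
    move_off_x: float = 0.01
    move_onto_x: float = 0.01
    deletion: float = 0.01
    heterochromatic: float = 0.007


def _default_divergence_model() -> dict[str, IdentityModel]:
    return {
        PLATFORM: IdentityModel(1.0, 0.0, 1.0),
        "simulans_like": IdentityModel(0.96, 0.02, 0.75),
        "yakuba_like": IdentityModel(0.92, 0.025, 0.75),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults reproduce the structure of the motivating cross-species
    hybridization design: ~18.8k features of which 16.7% are X-linked, six
    dye-swapped arrays, a simulans-like identity distribution around 96%
    and a yakuba-like one around 92%, and an identity->efficiency slope
    calibrated (see ``analysis/00_calibrate.py``) so that detection of the
    planted X excess is ~93% within species, ~50% at 2-4% divergence and
    near zero at 9-15%, with the identity term explaining roughly half the
    variance of the per-feature mean log ratio.
    """

    n_features: int = 18_849
    x_fraction: float = 0.167
    n_arrays: int = 6
    dye_swap_balanced: bool = True
    divergence_model: dict[str, IdentityModel] = field(
        default_factory=_default_divergence_model
    )
    #: hybridization-efficiency loss per unit identity loss
    beta_div: float = 13.0
    #: SD of the per-feature probe effect on M, shared across arrays (log2)
    sigma_feature: float = 0.18
    #: divergence-coupled probe-effect SD per unit divergence: mismatch
    #: placement, indels and GC only perturb hybridization when the sample
    #: actually mismatches the probe, so this term vanishes at identity 1
    sigma_feature_div: float = 13.0
    #: square root of the prior scale of per-array measurement noise on M
    sigma_array: float = 0.33
    #: prior df of the inverse-chi-square spread of per-feature noise variances
    var_df: float = 5.0
    dye_bias: DyeBias = field(default_factory=DyeBias)
    a_mean: float = 12.0
    a_sd: float = 1.0
    #: per-array jitter of a feature's A around its feature-level value
    a_array_jitter: float = 0.1
    bg_mean: float = 100.0
    bg_sd: float = 15.0
    confounder_probs: ConfounderProbs = field(default_factory=ConfounderProbs)
    #: nonspecific cross-hybridization floor, as a fraction of a two-copy
    #: locus' specific signal: DNA that is present but mismatched still
    #: binds weakly, so diverged orthologs stay measurable (and reliably
    #: negative) instead of dropping out; physically deleted DNA gives
    #: nothing at all
    nonspecific_frac: float = 0.025
    #: multiplicative signal suppression on heterochromatic features
    het_suppression: float = 0.5
    #: SD (log2) of the per-channel lognormal jitter on heterochromatic features
    het_jitter_sd: float = 0.6
    #: correlation of a feature's identity across simulated species
    identity_correlation: float = 0.8
    tech_error_prob: float = 0.002
    #: force all true copy ratios to 1 (null experiment for FDR checks)
    null_copy_ratio: bool = False
    seed: int = 0

    def validate(self) -> None:
        probs = asdict(self.confounder_probs)
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"confounder probability {name}={p} not in [0,1]")
        for name in ("sigma_feature", "sigma_feature_div", "sigma_array", "a_sd",
                     "bg_sd", "het_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.x_fraction <= 1.0:
            raise ConfigurationError("x_fraction must lie in [0,1]")
        if not 0.0 <= self.het_suppression <= 1.0:
            raise ConfigurationError("het_suppression must lie in [0,1]")
        if self.beta_div < 0:
            raise ConfigurationError("beta_div must be >= 0")
        if self.x_fraction * self.n_features < 10:
            raise ConfigurationError(
                "x_fraction * n_features < 10: too few planted positives to evaluate"
            )


def _genome_meta() -> pd.DataFrame:
    return pd.DataFrame(
        _CHROMOSOMES, columns=["chromosome", "length_bp", "is_x", "is_heterochromatin"]
    )


def conserved_set_sizes(n_features: int) -> tuple[int, int]:
    """Sizes of the two conserved normalization sets, scaled below full size."""
    if n_features >= 18_849:
        return 1000, 100
    return max(10, round(0.053 * n_features)), max(5, round(0.005 * n_features))


def hybridization_efficiency(identity, beta_div: float):
    """Linear-with-clamp hybridization efficiency, ``h(1) = 1``.

    ``h = max(0, 1 - beta_div * (1 - identity))``; scalar or array input.
    """
    identity = np.asarray(identity, dtype=float)
    if np.any((identity < 0) | (identity > 1)):
        raise ValueError("identity must lie in [0, 1]")
    h = np.maximum(0.0, 1.0 - beta_div * (1.0 - identity))
    if h.ndim == 0:
        return float(h)
    return h


def simulate_truth(config: SimulationConfig):
    """Draw feature annotation and per-feature ground truth.

    Returns ``(annotation, truth, meta)`` where ``meta`` maps genome label
    (:data:`PLATFORM` plus every simulated species) to its genome-meta
    table.  Deterministic given ``config.seed``.

    Ground-truth columns: base copy counts (female test 2, male reference
    1 on the X and 2 on autosomes), one ``identity_<species>`` column per
    simulated species (correlated across species through a shared
    conservation score), confounder labels, and paralog-family bookkeeping
    (numbers of extra loci per genome and their identities).  Conserved
    normalization sets are the features with the highest minimum identity
    across species (the generator's proxy for "highly conserved among the
    compared species").
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    n = config.n_features
    nx = int(np.floor(n * config.x_fraction))

    feature_id = np.array([f"F{i:06d}" for i in range(n)])
    is_x = np.zeros(n, dtype=bool)
    is_x[:nx] = True
    chromosome = np.empty(n, dtype=object)
    chromosome[:nx] = "X"
    chromosome[nx:] = np.array(_AUTOSOME_ARMS, dtype=object)[np.arange(n - nx) % 4]

    meta_platform = _genome_meta()
    lengths = meta_platform.set_index("chromosome")["length_bp"]
    # euchromatic probes sit away from chromosome ends; telomere-window
    # hits then arise only from genuinely telomeric/heterochromatic loci
    margin = 2 * 25_000
    position = (
        margin + rng.random(n) * (chromosome_lengths(chromosome, lengths) - 2 * margin)
    ).astype(int)

    # identities, correlated across species through a shared conservation score
    rho = config.identity_correlation
    shared = rng.standard_normal(n)
    identities: dict[str, np.ndarray] = {}
    for sp, model in config.divergence_model.items():
        z = rho * shared + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
        ident = model.mean_identity + model.sd_identity * z
        identities[sp] = np.clip(ident, model.min_identity, 1.0)

    # confounders: independent draws at the configured probabilities
    p = config.confounder_probs
    deleted = rng.random(n) < p.deletion
    moved_off_x = is_x & (rng.random(n) < p.move_off_x)
    moved_onto_x = ~is_x & (rng.random(n) < p.move_onto_x)
    heterochromatic = rng.random(n) < p.heterochromatic
    paralog_family = rng.random(n) < p.paralog_family

    # paralog families: extra similar loci in the reference and/or test genome
    n_extra = np.where(paralog_family, 1 + rng.poisson(0.7, size=n), 0)
    side = rng.random(n)  # <0.4 ref-only, <0.8 test-only, else both
    extra_ref = np.where(paralog_family & ((side < 0.4) | (side >= 0.8)), n_extra, 0)
    extra_test = np.where(paralog_family & (side >= 0.4), n_extra, 0)
    paralog_identity_ref = np.where(
        extra_ref > 0, rng.uniform(0.90, 0.99, size=n), np.nan
    )
    # test-side paralog identity: the ortholog identity degraded a little
    paralog_offset = rng.uniform(0.0, 0.05, size=n)

    copies_ref = np.where(is_x, 1, 2)
    truth = pd.DataFrame({
        "feature_id": feature_id,
        "is_x": is_x,
        "copies_test": copies_ref if config.null_copy_ratio else 2,
        "copies_ref": copies_ref,
        "deleted": deleted,
        "moved_off_x": moved_off_x,
        "moved_onto_x": moved_onto_x,
        "heterochromatic": heterochromatic,
        "paralog_family": paralog_family,
        "extra_ref_loci": extra_ref,
        "extra_test_loci": extra_test,
        "paralog_identity_ref": paralog_identity_ref,
        "paralog_offset": paralog_offset,
    })
    for sp in identities:
        truth[f"identity_{sp}"] = identities[sp]

    # conserved sets: highest minimum identity across the simulated species
    n1000, n100 = conserved_set_sizes(n)
    min_ident = np.min(np.column_stack(list(identities.values())), axis=1)
    order = np.lexsort((np.arange(n), -min_ident))  # stable under ties
    conserved_1000 = np.zeros(n, dtype=bool)
    conserved_1000[order[:n1000]] = True
    conserved_100 = np.zeros(n, dtype=bool)
    conserved_100[order[:n100]] = True

    annotation = pd.DataFrame({
        "feature_id": feature_id,
        "chromosome": chromosome,
        "position_bp": position,
        "is_x": is_x,
        "conserved_1000": conserved_1000,
        "conserved_100": conserved_100,
        "length_bp": rng.integers(400, 600, size=n),
        "gc_fraction": np.round(np.clip(rng.normal(0.43, 0.05, size=n), 0.2, 0.8), 4),
    })

    meta = {PLATFORM: meta_platform}
    for sp in config.divergence_model:
        if sp != PLATFORM:
            meta[sp] = _genome_meta()
    return annotation, truth, meta


def chromosome_lengths(chromosome: np.ndarray, lengths: pd.Series) -> np.ndarray:
    return pd.Series(chromosome).map(lengths).to_numpy(dtype=float)


def _channel_sums(truth: pd.DataFrame, species: str, config: SimulationConfig):
    """Specific-hybridization channel sums (test, reference) per feature."""
    ident = truth[f"identity_{species}"].to_numpy(dtype=float)
    h_orth = hybridization_efficiency(ident, config.beta_div)
    par_test_ident = np.clip(
        ident - truth["paralog_offset"].to_numpy(dtype=float), 0.0, 1.0
    )
    h_par_test = hybridization_efficiency(par_test_ident, config.beta_div)
    par_ref_ident = np.nan_to_num(
        truth["paralog_identity_ref"].to_numpy(dtype=float), nan=0.0
    )
    h_par_ref = hybridization_efficiency(par_ref_ident, config.beta_div)

    copies_test = truth["copies_test"].to_numpy(dtype=float)
    copies_ref = truth["copies_ref"].to_numpy(dtype=float)
    deleted = truth["deleted"].to_numpy(dtype=bool)

    # paralog loci are autosomal: 2 copies in the female test sample and in
    # the male reference
    test_sum = np.where(deleted, 0.0, copies_test * h_orth) + (
        2.0 * truth["extra_test_loci"].to_numpy(dtype=float) * h_par_test
    )
    ref_sum = copies_ref * 1.0 + (
        2.0 * truth["extra_ref_loci"].to_numpy(dtype=float) * h_par_ref
    )
    if np.any(ref_sum <= 0):
        raise ValidationError("reference channel sum is zero for some feature")
    return test_sum, ref_sum


def expected_log_ratio(truth: pd.DataFrame, species: str, config: SimulationConfig):
    """Expected per-feature M (log2 test/reference) for one test species.

    ``M = log2( sum_loci copies_test * h(id_test) /
                sum_loci copies_ref  * h(id_ref) )``
    summed over the probe's target locus and any paralog-family loci.
    Reference-genome loci hybridize at full efficiency (identity 1).
    Features whose test-channel sum is zero (fully diverged or deleted)
    return NaN — with no specific test signal, M is undefined.

    This is the pure competitive-hybridization expectation; the array
    simulator additionally adds the nonspecific binding floor (for DNA
    that is present but mismatched) and the heterochromatic suppression
    jitter before reconstructing channel intensities.
    """
    test_sum, ref_sum = _channel_sums(truth, species, config)
    with np.errstate(divide="ignore"):
        m = np.log2(test_sum / ref_sum)
    return np.where(test_sum > 0, m, np.nan)


def expected_observed_log_ratio(
    truth: pd.DataFrame, species: str, config: SimulationConfig
):
    """Expected M as the arrays actually measure it: competitive ratio of
    the specific channel sums plus the nonspecific binding floor.  Deleted
    DNA contributes nothing (NaN: the feature will fail QC); diverged DNA
    bottoms out at the floor instead of vanishing."""
    test_sum, ref_sum = _channel_sums(truth, species, config)
    deleted = truth["deleted"].to_numpy(dtype=bool)
    ns = 2.0 * config.nonspecific_frac
    test_eff = np.where(deleted, 0.0, test_sum + ns)
    ref_eff = ref_sum + ns
    with np.errstate(divide="ignore"):
        m = np.log2(test_eff / ref_eff)
    return np.where(test_eff > 0, m, np.nan)


def make_design(
    species: str, n_arrays: int, reference_sample: str = "platform_male",
    dye_swap_balanced: bool = True,
) -> pd.DataFrame:
    """Dye-swap-balanced hybridization design for one test species."""
    if dye_swap_balanced:
        orient = np.where(np.arange(n_arrays) % 2 == 0, 1, -1)
    else:
        orient = np.ones(n_arrays, dtype=int)
    return pd.DataFrame({
        "array_id": [f"{species}_a{i + 1}" for i in range(n_arrays)],
        "test_sample": species,
        "reference_sample": reference_sample,
        "dye_orientation": orient,
    })


def dye_bias_curve(a: np.ndarray, config: SimulationConfig) -> np.ndarray:
    z = (np.asarray(a, dtype=float) - config.a_mean) / config.a_sd
    return config.dye_bias.amplitude * (z**3 - 3.0 * z) / 2.0


def simulate_arrays(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    config: SimulationConfig,
    species: str | None = None,
) -> pd.DataFrame:
    """Simulate scan tables for every array in ``design``.

    Per feature: mean log intensity ``A ~ N(a_mean, a_sd)``; observed
    ``M = expected_log_ratio + probe effect (N(0, sigma_feature), shared
    across arrays) + orientation * dye_bias(A) + per-array noise`` whose
    per-feature variance is drawn from a scaled inverse chi-square prior
    ``sigma_array^2 * var_df / chi2(var_df)``.  Channel intensities are
    reconstructed as ``2^(A + M/2)`` (test) and ``2^(A - M/2)``
    (reference), routed to channel 1/2 by dye orientation, and summed with
    truncated-normal backgrounds.  Heterochromatic features get both
    channels suppressed by ``het_suppression`` with independent lognormal
    jitter per channel (shared across arrays), degrading their ratios.
    Signal-free features (NaN expected M) emit background-level foreground
    and are left for QC to flag.
    """
    config.validate()
    if species is None:
        species = design["test_sample"].iloc[0]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    n = len(truth)

    m_expected = expected_observed_log_ratio(truth, species, config)
    dropout = np.isnan(m_expected)

    a_feat = rng.normal(config.a_mean, config.a_sd, size=n)
    ident = truth[f"identity_{species}"].to_numpy(dtype=float)
    probe_sd = np.sqrt(
        config.sigma_feature**2 + (config.sigma_feature_div * (1.0 - ident)) ** 2
    )
    probe_effect = rng.normal(0.0, probe_sd)
    # per-feature measurement-noise variance: scaled inverse chi-square
    d = config.var_df
    noise_var = config.sigma_array**2 * d / rng.chisquare(d, size=n)
    noise_sd = np.sqrt(noise_var)

    het = truth["heterochromatic"].to_numpy(dtype=bool)
    jit_test = np.where(het, rng.normal(0.0, config.het_jitter_sd, size=n), 0.0)
    jit_ref = np.where(het, rng.normal(0.0, config.het_jitter_sd, size=n), 0.0)
    suppress = np.where(het, config.het_suppression, 1.0)

    m_center = np.where(dropout, 0.0, m_expected) + probe_effect + (jit_test - jit_ref)

    tables = []
    for _, row in design.iterrows():
        orient = int(row["dye_orientation"])
        a_ij = a_feat + rng.normal(0.0, config.a_array_jitter, size=n)
        m_ij = m_center + orient * dye_bias_curve(a_ij, config) + rng.normal(
            0.0, noise_sd
        )
        # suppression and the symmetric half of the het jitter act on A
        a_eff = a_ij + np.log2(suppress) + (jit_test + jit_ref) / 2.0
        ch_test = np.where(dropout, 0.0, 2.0 ** (a_eff + m_ij / 2.0))
        ch_ref = 2.0 ** (a_eff - m_ij / 2.0)
        if orient == 1:
            ch1, ch2 = ch_test, ch_ref
        else:
            ch1, ch2 = ch_ref, ch_test
        bg1 = np.maximum(0.0, rng.normal(config.bg_mean, config.bg_sd, size=n))
        bg2 = np.maximum(0.0, rng.normal(config.bg_mean, config.bg_sd, size=n))
        qc = np.where(
            rng.random(n) < config.tech_error_prob, QC_TECHNICAL_ERROR, QC_OK
        )
        tables.append(pd.DataFrame({
            "array_id": row["array_id"],
            "feature_id": truth["feature_id"],
            "fg1": ch1 + bg1,
            "bg1": bg1,
            "bg1_sd": config.bg_sd,
            "fg2": ch2 + bg2,
            "bg2": bg2,
            "bg2_sd": config.bg_sd,
            "qc_flag": qc,
        }))
    return pd.concat(tables, ignore_index=True)


def _evalue(identity: np.ndarray, length: np.ndarray) -> np.ndarray:
    # monotone in identity and length, always below the 1e-14 top-hit cutoff
    exponent = 15.0 + 150.0 * np.maximum(0.0, identity - 0.75) * (length / 500.0)
    return 10.0 ** (-exponent)


def simulate_hit_tables(
    truth: pd.DataFrame,
    annotation: pd.DataFrame,
    meta: dict[str, pd.DataFrame],
    config: SimulationConfig,
    species: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fabricate BLAST-tabular-shaped hit tables consistent with the truth.

    Reference-genome hits: every feature hits its own locus at 100%
    identity, plus one hit per reference-side paralog locus.  Heterologous
    hits: every non-deleted ortholog hits the like-named chromosome — or an
    autosome if moved off the X, the X if moved onto it, a heterochromatic
    scaffold if heterochromatic — plus hits for test-side paralog loci.
    Percent identity equals 100x the true identity; e-values shrink with
    identity and feature length and always qualify for the top-hit cutoff.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    ident = truth[f"identity_{species}"].to_numpy(dtype=float)
    length = annotation["length_bp"].to_numpy(dtype=float)
    chrom = annotation["chromosome"].to_numpy()
    pos = annotation["position_bp"].to_numpy(dtype=float)
    n = len(truth)

    meta_ref = meta[PLATFORM].set_index("chromosome")
    meta_het = meta[species].set_index("chromosome")
    het_scaffolds = list(meta_het.index[meta_het["is_heterochromatin"]])

    def hit_rows(fid, chroms, start, pid, length_bp, genome):
        start = np.asarray(start, dtype=int)
        end = start + np.asarray(length_bp, dtype=int) - 1
        return pd.DataFrame({
            "query_id": fid,
            "subject_genome": genome,
            "subject_chromosome": chroms,
            "subject_start": start,
            "subject_end": end,
            "percent_identity": np.round(100.0 * np.asarray(pid, dtype=float), 2),
            "e_value": _evalue(np.asarray(pid, dtype=float), np.asarray(length_bp)),
            "bitscore": np.round(
                2.0 * np.asarray(length_bp, dtype=float) * np.asarray(pid), 1
            ),
        })

    # --- reference genome hits -------------------------------------------
    ref_parts = [
        hit_rows(truth["feature_id"], chrom, pos + 1, np.ones(n), length, PLATFORM)
    ]
    par_ref = truth["extra_ref_loci"].to_numpy(dtype=int)
    for i in np.flatnonzero(par_ref):
        k = par_ref[i]
        arms = rng.choice(_AUTOSOME_ARMS, size=k)
        starts = [
            rng.integers(1, meta_ref.loc[a, "length_bp"] - 1000) for a in arms
        ]
        ref_parts.append(hit_rows(
            [truth["feature_id"].iat[i]] * k, arms, starts,
            [truth["paralog_identity_ref"].iat[i]] * k, [length[i]] * k, PLATFORM,
        ))
    hits_ref = pd.concat(ref_parts, ignore_index=True)

    # --- heterologous genome hits ----------------------------------------
    deleted = truth["deleted"].to_numpy(dtype=bool)
    keep = ~deleted
    het_chrom = chrom.astype(object).copy()
    off_x = truth["moved_off_x"].to_numpy(dtype=bool)
    onto_x = truth["moved_onto_x"].to_numpy(dtype=bool)
    hetero = truth["heterochromatic"].to_numpy(dtype=bool)
    het_chrom[off_x] = rng.choice(_AUTOSOME_ARMS, size=int(off_x.sum()))
    het_chrom[onto_x] = "X"
    if het_scaffolds:
        het_chrom[hetero] = rng.choice(het_scaffolds, size=int(hetero.sum()))
    limits = pd.Series(het_chrom).map(meta_het["length_bp"]).to_numpy(dtype=float)
    het_pos = np.minimum(pos, limits - 1200.0)  # ortholog at a similar position
    het_pos = np.maximum(het_pos, 0.0)
    het_parts = [hit_rows(
        truth.loc[keep, "feature_id"], het_chrom[keep], het_pos[keep] + 1,
        ident[keep], length[keep], species,
    )]
    par_test = np.where(keep, truth["extra_test_loci"].to_numpy(dtype=int), 0)
    par_test_ident = np.clip(ident - truth["paralog_offset"].to_numpy(), 0.0, 1.0)
    for i in np.flatnonzero(par_test):
        k = par_test[i]
        arms = rng.choice(_AUTOSOME_ARMS, size=k)
        starts = [
            rng.integers(1, meta_het.loc[a, "length_bp"] - 1000) for a in arms
        ]
        het_parts.append(hit_rows(
            [truth["feature_id"].iat[i]] * k, arms, starts,
            [par_test_ident[i]] * k, [length[i]] * k, species,
        ))
    hits_het = pd.concat(het_parts, ignore_index=True)
    return hits_het, hits_ref
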