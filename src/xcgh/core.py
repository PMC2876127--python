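"""Domain tables and file formats for cross-species aCGH analysis.

All tabular data are carried as :class:`pandas.DataFrame` objects with
validated column sets:

``annotation``
    One row per array feature: ``feature_id``, ``chromosome``,
    ``position_bp``, ``is_x``, ``conserved_1000``, ``conserved_100``,
    ``length_bp``, ``gc_fraction``.  The conserved columns mark membership
    in the ~1000- and ~100-gene conserved normalization sets; the smaller
    set is required to be nested in the larger one.

``scan``
    Per (array, feature) two-channel fluorescence: ``array_id``,
    ``feature_id``, ``fg1``, ``bg1``, ``bg1_sd``, ``fg2``, ``bg2``,
    ``bg2_sd``, ``qc_flag`` (``ok`` / ``low_signal`` / ``technical_error``).
    A minimal GPR-like dialect; full GenePix parsing is out of scope.

``hits``
    BLAST tabular (outfmt 6) records against one subject genome, with
    subject coordinates order-normalized to start <= end (strand is
    irrelevant to every rule applied here and is discarded).

``genome meta``
    Per chromosome/scaffold: ``chromosome``, ``length_bp``, ``is_x``,
    ``is_heterochromatin``.

``design``
    Per hybridization: ``array_id``, ``test_sample``, ``reference_sample``,
    ``dye_orientation`` (+1 = test sample in channel 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "QC_OK",
    "QC_LOW_SIGNAL",
    "QC_TECHNICAL_ERROR",
    "read_feature_annotation",
    "write_feature_annotation",
    "validate_annotation",
    "read_scan_table",
    "write_scan_table",
    "read_genome_meta",
    "write_genome_meta",
    "read_design",
    "write_design",
    "read_hit_table",
    "write_hit_table",
    "derive_divergence_profile",
]


class FormatError(ValueError):
    """A file does not conform to its declared tabular format."""


class ValidationError(ValueError):
    """A parsed table violates a domain invariant."""


QC_OK = "ok"
QC_LOW_SIGNAL = "low_signal"
QC_TECHNICAL_ERROR = "technical_error"
QC_FLAGS = (QC_OK, QC_LOW_SIGNAL, QC_TECHNICAL_ERROR)

ANNOTATION_COLUMNS = [
    "feature_id",
    "chromosome",
    "position_bp",
    "is_x",
    "conserved_1000",
    "conserved_100",
    "length_bp",
    "gc_fraction",
]

SCAN_COLUMNS = [
    "array_id",
    "feature_id",
    "fg1",
    "bg1",
    "bg1_sd",
    "fg2",
    "bg2",
    "bg2_sd",
    "qc_flag",
]

GENOME_META_COLUMNS = ["chromosome", "length_bp", "is_x", "is_heterochromatin"]

DESIGN_COLUMNS = ["array_id", "test_sample", "reference_sample", "dye_orientation"]

HIT_COLUMNS = [
    "query_id",
    "subject_genome",
    "subject_chromosome",
    "subject_start",
    "subject_end",
    "percent_identity",
    "e_value",
    "bitscore",
]

#: 12 standard columns of BLAST ``-outfmt 6``
BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

TELOMERE_WINDOW_BP = 25_000


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s): {', '.join(missing)}")


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "1": True, "0": False, "true": True, "false": False,
        "True": True, "False": False, 1: True, 0: False,
        True: True, False: False,
    }
    out = series.map(mapping)
    if out.isna().any():
        bad = series[out.isna()].unique()[:5]
        raise FormatError(f"cannot interpret boolean values: {list(bad)}")
    return out.astype(bool)


# ---------------------------------------------------------------------------
# annotation


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    _require_columns(ann, ANNOTATION_COLUMNS, "annotation")
    ann = ann.copy()
    for col in ("is_x", "conserved_1000", "conserved_100"):
        ann[col] = _as_bool(ann[col])
    dup = ann["feature_id"][ann["feature_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"duplicate feature_id values: {sorted(dup.unique())[:10]}"
        )
    if (ann["position_bp"] < 0).any():
        raise ValidationError("position_bp must be >= 0")
    if (ann["length_bp"] <= 0).any():
        raise ValidationError("length_bp must be > 0")
    gc = ann["gc_fraction"].astype(float)
    if ((gc < 0) | (gc > 1)).any():
        raise ValidationError("gc_fraction must lie in [0, 1]")
    bad = ann["conserved_100"] & ~ann["conserved_1000"]
    if bad.any():
        offenders = ann.loc[bad, "feature_id"].tolist()[:10]
        raise ValidationError(
            "conserved_100 must be a subset of conserved_1000; offenders: "
            f"{offenders}"
        )
    return ann


def read_feature_annotation(path) -> pd.DataFrame:
    """Read a feature annotation TSV and validate its invariants."""
    ann = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "chromosome": str})
    return validate_annotation(ann)


def write_feature_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    for col in ("is_x", "conserved_1000", "conserved_100"):
        out[col] = out[col].astype(int)
    out[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scan tables


def read_scan_table(path) -> pd.DataFrame:
    scan = pd.read_csv(path, sep="\t", dtype={"array_id": str, "feature_id": str})
    _require_columns(scan, SCAN_COLUMNS, "scan table")
    for col in ("fg1", "bg1", "fg2", "bg2", "bg1_sd", "bg2_sd"):
        vals = scan[col].astype(float)
        if (vals < 0).any():
            raise ValidationError(f"scan table: negative values in {col}")
        scan[col] = vals
    unknown = set(scan["qc_flag"].unique()) - set(QC_FLAGS)
    if unknown:
        raise ValidationError(f"scan table: unknown qc_flag values {sorted(unknown)}")
    dup = scan.duplicated(subset=["array_id", "feature_id"])
    if dup.any():
        raise ValidationError("scan table: duplicate (array_id, feature_id) rows")
    return scan


def write_scan_table(scan: pd.DataFrame, path) -> None:
    scan[SCAN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome metadata


def read_genome_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    _require_columns(meta, GENOME_META_COLUMNS, "genome meta")
    meta["is_x"] = _as_bool(meta["is_x"])
    meta["is_heterochromatin"] = _as_bool(meta["is_heterochromatin"])
    if (meta["length_bp"] <= 0).any():
        raise ValidationError("genome meta: chromosome lengths must be > 0")
    if meta["chromosome"].duplicated().any():
        raise ValidationError("genome meta: duplicate chromosome names")
    return meta


def write_genome_meta(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out["is_x"] = out["is_x"].astype(int)
    out["is_heterochromatin"] = out["is_heterochromatin"].astype(int)
    out[GENOME_META_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hybridization design


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"array_id": str})
    _require_columns(design, DESIGN_COLUMNS, "design")
    if not set(design["dye_orientation"].unique()) <= {1, -1}:
        raise ValidationError("design: dye_orientation must be +1 or -1")
    if design["reference_sample"].nunique() > 1:
        raise ValidationError("design: reference_sample must be identical across arrays")
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BLAST tabular hits


def read_hit_table(path, subject_genome: str) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular (outfmt 6) file.

    The subject sequence id is taken as the chromosome/scaffold name within
    ``subject_genome``.  Subject coordinates are order-normalized so that
    ``subject_start <= subject_end``; the original order (minus-strand hits
    have start > end) carries no information used downstream.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS,
                          dtype={"qseqid": str, "sseqid": str}, comment="#")
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=BLAST6_COLUMNS)
    if len(raw) == 0:
        return pd.DataFrame(columns=HIT_COLUMNS)
    for col in ("pident", "sstart", "send", "evalue", "bitscore"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 1
            raise FormatError(
                f"hit table {path}: non-numeric value in column {col!r} at line {line}"
            )
        raw[col] = vals
    if (raw["evalue"] < 0).any():
        raise ValidationError("hit table: negative e-value")
    hits = pd.DataFrame({
        "query_id": raw["qseqid"],
        "subject_genome": subject_genome,
        "subject_chromosome": raw["sseqid"],
        "subject_start": np.minimum(raw["sstart"], raw["send"]).astype(int),
        "subject_end": np.maximum(raw["sstart"], raw["send"]).astype(int),
        "percent_identity": raw["pident"].astype(float),
        "e_value": raw["evalue"].astype(float),
        "bitscore": raw["bitscore"].astype(float),
    })
    return hits


def write_hit_table(hits: pd.DataFrame, path) -> None:
    """Write hits back out as 12-column BLAST tabular.

    Query-side alignment columns that the domain model does not retain
    (alignment length, mismatches, gap opens, query coordinates) are emitted
    as zeros; they are never read back into anything.
    """
    n = len(hits)
    out = pd.DataFrame({
        "qseqid": hits["query_id"],
        "sseqid": hits["subject_chromosome"],
        "pident": hits["percent_identity"],
        "length": np.zeros(n, dtype=int),
        "mismatch": np.zeros(n, dtype=int),
        "gapopen": np.zeros(n, dtype=int),
        "qstart": np.zeros(n, dtype=int),
        "qend": np.zeros(n, dtype=int),
        "sstart": hits["subject_start"],
        "send": hits["subject_end"],
        "evalue": hits["e_value"],
        "bitscore": hits["bitscore"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# divergence / confounder profile


def _check_chromosomes(hits: pd.DataFrame, meta: pd.DataFrame, label: str) -> None:
    unknown = set(hits["subject_chromosome"]) - set(meta["chromosome"])
    if unknown:
        raise ValidationError(
            f"{label} hits reference unknown chromosome(s): {sorted(unknown)[:10]}"
        )


def derive_divergence_profile(
    hits_het: pd.DataFrame,
    hits_ref: pd.DataFrame,
    annotation: pd.DataFrame,
    meta_het: pd.DataFrame,
    meta_ref: pd.DataFrame,
    e_top: float = 1e-14,
    e_count: float = 1e-10,
) -> pd.DataFrame:
    """Per-feature divergence summary and confounder flags from hit tables.

    For each feature the profile records the percent identity of the top
    heterologous hit (lowest e-value below ``e_top``, ties broken by highest
    bitscore then lowest subject coordinate), hit counts in both genomes at
    ``e_count``, their ratio, and the chromosomal confounder flags:

    - ``no_hit``: no heterologous hit below ``e_top`` (candidate deletion).
    - ``autosomal_only``: X-linked feature whose heterologous hits all fall
      on non-X chromosomes (candidate movement off the X / deletion).
    - ``het_x_hit``: autosomal feature with at least one hit on the
      heterologous X (candidate movement onto the X).
    - ``tel_or_het``: some hit lies on a heterochromatic scaffold or within
      25 kb of a chromosome end.
    - ``ref_not_found``: the feature has no qualifying hit to the platform
      genome itself.

    Movement and telomere/heterochromatin rules use the permissive
    ``e_count`` threshold ("any hit"); the top-hit identity and ``no_hit``
    use the stringent ``e_top``.
    """
    missing = (set(hits_het["query_id"]) | set(hits_ref["query_id"])) - set(
        annotation["feature_id"]
    )
    if missing:
        raise ValidationError(
            f"hits reference unannotated feature(s): {sorted(missing)[:10]}"
        )
    _check_chromosomes(hits_het, meta_het, "heterologous")
    _check_chromosomes(hits_ref, meta_ref, "reference")

    het_meta = meta_het.set_index("chromosome")
    het_x_chroms = set(het_meta.index[het_meta["is_x"]])
    het_het_chroms = set(het_meta.index[het_meta["is_heterochromatin"]])
    chrom_len = het_meta["length_bp"]

    prof = pd.DataFrame({
        "feature_id": annotation["feature_id"].to_numpy(),
        "is_x": annotation["is_x"].to_numpy(),
    })
    prof = prof.set_index("feature_id", drop=False)

    # top hit at stringent threshold; deterministic tie-breaking
    strong = hits_het[hits_het["e_value"] < e_top]
    if len(strong):
        ordered = strong.sort_values(
            ["e_value", "bitscore", "subject_start"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        top = ordered.drop_duplicates("query_id", keep="first").set_index("query_id")
        prof["top_hit_pid"] = prof.index.map(top["percent_identity"])
    else:
        prof["top_hit_pid"] = np.nan
    prof["no_hit"] = prof["top_hit_pid"].isna()

    het_count = hits_het[hits_het["e_value"] < e_count]
    ref_count = hits_ref[hits_ref["e_value"] < e_count]
    prof["n_hits_het"] = (
        prof.index.map(het_count.groupby("query_id").size()).fillna(0).astype(int)
    )
    prof["n_hits_ref"] = (
        prof.index.map(ref_count.groupby("query_id").size()).fillna(0).astype(int)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = prof["n_hits_het"] / prof["n_hits_ref"]
    prof["hit_ratio"] = ratio.where(prof["n_hits_ref"] >= 1, np.nan)

    on_x = het_count["subject_chromosome"].isin(het_x_chroms)
    has_x_hit = set(het_count.loc[on_x, "query_id"])
    has_any_hit = set(het_count["query_id"])
    prof["autosomal_only"] = prof["is_x"] & prof["feature_id"].isin(
        has_any_hit - has_x_hit
    )
    prof["het_x_hit"] = ~prof["is_x"] & prof["feature_id"].isin(has_x_hit)

    in_het = het_count["subject_chromosome"].isin(het_het_chroms)
    lengths = het_count["subject_chromosome"].map(chrom_len)
    near_tel = (het_count["subject_start"] <= TELOMERE_WINDOW_BP) | (
        het_count["subject_end"] >= lengths - TELOMERE_WINDOW_BP
    )
    prof["tel_or_het"] = prof["feature_id"].isin(
        set(het_count.loc[in_het | near_tel, "query_id"])
    )

    ref_strong = hits_ref[hits_ref["e_value"] < e_top]
    prof["ref_not_found"] = ~prof["feature_id"].isin(set(ref_strong["query_id"]))

    return prof.reset_index(drop=True).drop(columns=["is_x"])
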