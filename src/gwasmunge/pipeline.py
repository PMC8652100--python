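"""The QC pipeline: row-level filters and the check orchestrator.

``run_pipeline`` executes the full battery of standardization and QC checks
in fixed numeric order on a parsed raw table, against a reference backend,
under a :class:`QCConfig`.  Every check contributes an entry to the
:class:`QCReport`, which tracks rows dropped (with a reason per row) and
cells imputed, and satisfies the conservation invariant
``rows_in == rows_out + total_dropped``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CheckError, SumstatsError
from .formats import RawTable
from . import harmonize
from .headers import (
    CANONICAL_NAMES,
    SIGNED_COLUMNS,
    dedupe_columns,
    load_column_map,
    normalize_snp_ids,
    resolve_traits,
    split_composite_columns,
    standardize_headers,
    validate_required_columns,
    validate_signed_column,
)
from .reference import ReferenceBackend, normalize_chrom

logger = logging.getLogger("gwasmunge")

_SMALLEST_DOUBLE = 5e-324  # smallest positive (subnormal) IEEE-754 double
_ALLELE_RE = re.compile(r"^[ACGT]+$")
_NUMERIC_COLUMNS = (
    "Z", "OR", "BETA", "LOG_ODDS", "SIGNED_SUMSTAT", "SE", "FRQ", "INFO",
    "N", "N_CAS", "N_CON", "NSTUDY",
)

#: Registry of the implemented checks, in execution order.  Ids are stable;
#: id 20 is intentionally absent.
CHECKS: list[tuple[int, str]] = [
    (1, "VCF format detection and import"),
    (2, "delimiter/compression handling (tab, space, comma; gz, bgz)"),
    (3, "header synonym canonicalization"),
    (4, "multiple trait/model detection"),
    (5, "SNP ID uniformity (rs prefix, CHR:BP hybrids)"),
    (6, "composite CHR:BP:A2:A1 column split"),
    (7, "composite CHR:BP column split"),
    (8, "combined A1/A2 column split"),
    (9, "impute missing CHR/BP from reference"),
    (10, "impute missing SNP ID from reference"),
    (11, "impute missing alleles from reference"),
    (12, "required columns present (SNP, CHR, BP, P, A1, A2)"),
    (13, "signed/effect column present"),
    (14, "drop rows with missing data"),
    (15, "duplicated columns removed"),
    (16, "p-values below 5e-324 handled"),
    (17, "N is integer; N outliers removed"),
    (18, "rsID validity flagged"),
    (19, "duplicate rows by SNP ID removed"),
    (21, "duplicate rows by base-pair position removed"),
    (22, "presence on reference genome (positional rescue)"),
    (23, "INFO score filter"),
    (24, "strand-ambiguous SNPs removed"),
    (25, "non-biallelic SNPs removed"),
    (26, "allele flipping against reference"),
    (27, "chromosome X/Y/MT SNPs removed"),
    (28, "output is LDSC-ready"),
    (29, "effect columns not zero"),
    (30, "standard error positive"),
    (31, "dropped and imputed values reported"),
]


@dataclass
class QCConfig:
    """Tunable switches and thresholds of the QC pipeline.

    Defaults follow common best practice: INFO cut-off 0.9, sample-size
    outliers beyond mean + 5·sd removed, sub-representable p-values
    converted to 0, non-autosomal variants removed, and all
    reference-dependent checks enabled.
    """

    info_threshold: float = 0.9
    n_std_multiplier: float = 5.0
    convert_small_p: bool = True
    remove_nonautosomal: bool = True
    strand_ambig_filter: bool = True
    biallelic_filter: bool = True
    allele_flip_check: bool = True
    rsid_on_reference_filter: bool = True
    require_signed: bool = True
    trait_selection: Optional[str] = None
    build: str = "GRCh37"
    output_format: str = "tabular"
    user_synonyms: Optional[dict] = None

    def __post_init__(self):
        if not 0.0 <= self.info_threshold <= 1.0:
            raise ValueError("info_threshold must lie in [0, 1]")
        if self.n_std_multiplier <= 0:
            raise ValueError("n_std_multiplier must be positive")
        if self.build not in ("GRCh37", "GRCh38"):
            raise ValueError(f"unknown build {self.build!r}")
        if self.output_format not in ("tabular", "vcf", "ldsc"):
            raise ValueError(f"unknown output format {self.output_format!r}")


@dataclass
class CheckEntry:
    """Per-check ledger line of the audit report."""

    check_id: int
    name: str
    rows_in: int
    rows_dropped: int = 0
    cells_imputed: int = 0
    modified: int = 0
    corrected: int = 0
    notes: str = ""


class QCReport:
    """Audit trail: per-check counts, dropped rows with reasons, imputed cells."""

    def __init__(self):
        self.entries: list[CheckEntry] = []
        self.dropped_records: list[dict] = []
        self.imputed_records: list[dict] = []
        self.flip_records: list[harmonize.FlipRecord] = []
        self.rows_initial: Optional[int] = None
        self.rows_final: Optional[int] = None

    # -- building --------------------------------------------------------
    def add(self, entry: CheckEntry) -> CheckEntry:
        self.entries.append(entry)
        return entry

    def record_drops(self, check_id: int, df_dropped: pd.DataFrame, reasons):
        if isinstance(reasons, str):
            reasons = [reasons] * len(df_dropped)
        for (i, _row), reason in zip(df_dropped.iterrows(), reasons):
            self.dropped_records.append(
                {
                    "key": harmonize._row_key(df_dropped, i),
                    "check": check_id,
                    "reason": reason,
                }
            )

    def record_imputations(self, check_id: int, cells):
        for key, column, value in cells:
            self.imputed_records.append(
                {"key": key, "check": check_id, "column": column, "value": value}
            )

    # -- views -----------------------------------------------------------
    def entry(self, check_id: int) -> CheckEntry:
        for e in self.entries:
            if e.check_id == check_id:
                return e
        raise KeyError(check_id)

    @property
    def total_dropped(self) -> int:
        return sum(e.rows_dropped for e in self.entries)

    @property
    def total_imputed(self) -> int:
        return sum(e.cells_imputed for e in self.entries)

    def dropped_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped_records, columns=["key", "check", "reason"])

    def imputed_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.imputed_records, columns=["key", "check", "column", "value"]
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.entries])

    def as_expected_dict(self) -> dict[int, dict[str, int]]:
        """Counts in the shape the fixture generator's ground truth uses."""
        out: dict[int, dict[str, int]] = {}
        for e in self.entries:
            d = {
                "dropped": e.rows_dropped,
                "imputed_cells": e.cells_imputed,
                "modified": e.modified,
                "corrected": e.corrected,
            }
            if e.check_id == 26:
                d["flipped"] = e.modified
            out[e.check_id] = d
        return out

    def verify_conservation(self):
        """Assert rows_in == rows_out + sum of per-check drops."""
        if self.rows_initial is None or self.rows_final is None:
            raise SumstatsError("report incomplete: pipeline did not finish")
        if self.rows_initial != self.rows_final + self.total_dropped:
            raise SumstatsError(
                f"conservation violated: {self.rows_initial} in != "
                f"{self.rows_final} out + {self.total_dropped} dropped"
            )

    def to_tsv(self, directory: str) -> list[str]:
        import os

        paths = []
        for name, table in [
            ("qc_summary.tsv", self.summary()),
            ("qc_dropped.tsv", self.dropped_table()),
            ("qc_imputed.tsv", self.imputed_table()),
        ]:
            p = os.path.join(directory, name)
            table.to_csv(p, sep="\t", index=False)
            paths.append(p)
        return paths


# ---------------------------------------------------------------------------
# row-level filters
# ---------------------------------------------------------------------------

def _is_missing(s: pd.Series) -> pd.Series:
    return s.isna() | s.astype(str).str.strip().isin(["", "nan", "None", "NA"])


def drop_missing(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Drop rows with a missing value in any canonical column present.

    Missing values in unmapped (non-canonical) columns are ignored — gaps
    in annotation columns are not grounds for exclusion.
    """
    canon = [c for c in df.columns if c in CANONICAL_NAMES]
    if not canon:
        return df, df.iloc[0:0], []
    miss = pd.DataFrame({c: _is_missing(df[c]) for c in canon})
    bad = miss.any(axis=1)
    reasons = [
        "missing value in " + ", ".join(miss.columns[miss.loc[i]])
        for i in df.index[bad]
    ]
    return df.loc[~bad], df.loc[bad], reasons


def handle_small_pvalues(
    df: pd.DataFrame, config: QCConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], int, int]:
    """Resolve p-values below 5e-324, the smallest representable double.

    Textual values like ``1e-350`` underflow to 0 on parse; they are set to
    0 (counted) when ``convert_small_p``, else their rows are dropped.
    Values at or above 5e-324 pass untouched (the bound is a strict
    less-than).  Literal input zeros are kept but flagged.  Non-numeric
    p-values drop their rows; p outside [0, 1] is a hard error.

    Returns ``(kept, dropped, reasons, n_converted, n_zero_flagged)``; the
    kept table's P column is numeric afterwards.
    """
    raw = df["P"].astype(str).str.strip()
    parsed = pd.to_numeric(raw, errors="coerce")
    nonnumeric = parsed.isna()
    if ((parsed < 0) | (parsed > 1)).any():
        bad = parsed[(parsed < 0) | (parsed > 1)].iloc[0]
        raise CheckError(16, f"p-value {bad} outside [0, 1]")
    # textual magnitude below 5e-324: parses to exactly 0 with a nonzero digit
    mantissa_nonzero = raw.str.split(r"[eE]").str[0].str.contains(r"[1-9]", regex=True)
    underflow = (parsed == 0) & mantissa_nonzero & ~nonnumeric
    literal_zero = (parsed == 0) & ~mantissa_nonzero & ~nonnumeric

    drop_mask = nonnumeric.copy()
    reasons = ["non-numeric p-value"] * int(nonnumeric.sum())
    n_converted = 0
    if underflow.any():
        if config.convert_small_p:
            n_converted = int(underflow.sum())
        else:
            drop_mask |= underflow
            reasons += ["p-value below 5e-324 (conversion disabled)"] * int(
                underflow.sum()
            )
    out = df.loc[~drop_mask].copy()
    out["P"] = parsed.loc[~drop_mask]
    return out, df.loc[drop_mask], reasons, n_converted, int(literal_zero.sum())


def filter_n_outliers(
    df: pd.DataFrame, config: QCConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], int]:
    """Coerce N to integer and drop sample-size outliers.

    N is rounded half away from zero; rows with N ≤ 0 are dropped; rows with
    N > mean + k·sd (k = ``n_std_multiplier``) are dropped, with mean and sd
    (ddof=1) computed on the coerced column before any dropping.
    Returns ``(kept, dropped, reasons, n_coerced)``.
    """
    if "N" not in df.columns:
        return df, df.iloc[0:0], [], 0
    n = pd.to_numeric(df["N"], errors="coerce")
    rounded = np.sign(n) * np.floor(np.abs(n) + 0.5)
    n_coerced = int((rounded != n).sum())
    sd = float(rounded.std(ddof=1)) if len(rounded) > 1 else 0.0
    if np.isnan(sd):
        sd = 0.0
    thresh = float(rounded.mean()) + config.n_std_multiplier * sd
    nonpos = rounded <= 0
    outlier = (rounded > thresh) & ~nonpos
    bad = nonpos | outlier
    reasons = []
    for i in df.index[bad]:
        if nonpos.loc[i]:
            reasons.append("sample size N not positive")
        else:
            reasons.append(
                f"N outlier: {int(rounded.loc[i])} > mean+{config.n_std_multiplier:g}*sd"
                f" = {thresh:.1f}"
            )
    out = df.loc[~bad].copy()
    out["N"] = rounded.loc[~bad].astype("int64")
    return out, df.loc[bad], reasons, n_coerced


def dedupe_rows(
    df: pd.DataFrame, key: str
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Remove duplicate rows under ``key`` (``rsid`` or ``position``), keep-first."""
    if key == "rsid":
        dup = df.duplicated(subset=["SNP"], keep="first")
        reason = "duplicate row (same SNP ID)"
    elif key == "position":
        dup = df.duplicated(subset=["CHR", "BP"], keep="first")
        reason = "duplicate row (same CHR:BP)"
    else:
        raise ValueError(f"unknown dedupe key {key!r}")
    return df.loc[~dup], df.loc[dup], [reason] * int(dup.sum())


def filter_info(
    df: pd.DataFrame, config: QCConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Drop rows with INFO below the threshold (strict <) or outside [0, 1]."""
    if "INFO" not in df.columns:
        return df, df.iloc[0:0], []
    info = pd.to_numeric(df["INFO"], errors="coerce")
    out_of_range = (info < 0) | (info > 1)
    low = (info < config.info_threshold) & ~out_of_range
    bad = out_of_range | low
    reasons = [
        "INFO outside [0, 1]" if out_of_range.loc[i]
        else f"INFO {info.loc[i]:g} < {config.info_threshold:g}"
        for i in df.index[bad]
    ]
    return df.loc[~bad], df.loc[bad], reasons


def remove_nonautosomal(
    df: pd.DataFrame, config: QCConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Drop rows on X, Y or MT when enabled (chromosomes already normalized)."""
    mask = df["CHR"].astype(str).isin(["X", "Y", "MT"])
    return (
        df.loc[~mask],
        df.loc[mask],
        [f"non-autosomal chromosome {df.at[i, 'CHR']}" for i in df.index[mask]],
    )


def check_effect_columns(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Drop rows whose signed effect is exactly zero (OR == 1 is fine)."""
    bad = pd.Series(False, index=df.index)
    for col in ("Z", "BETA", "LOG_ODDS", "SIGNED_SUMSTAT", "OR"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad |= vals == 0
    reasons = ["signed effect column equal to 0"] * int(bad.sum())
    return df.loc[~bad], df.loc[bad], reasons


def check_standard_error(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Drop rows whose SE is not strictly positive."""
    if "SE" not in df.columns:
        return df, df.iloc[0:0], []
    se = pd.to_numeric(df["SE"], errors="coerce")
    bad = se <= 0
    return df.loc[~bad], df.loc[bad], ["standard error not positive"] * int(bad.sum())


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def _coerce_positions_and_alleles(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize CHR tokens, make BP numeric, uppercase/validate alleles."""
    if "CHR" in df.columns:
        df["CHR"] = [normalize_chrom(v) for v in df["CHR"]]
    if "BP" in df.columns:
        bp = pd.to_numeric(df["BP"], errors="coerce")
        bp[bp < 1] = np.nan
        df["BP"] = bp
    for col in ("A1", "A2"):
        if col in df.columns:
            up = df[col].astype(str).str.strip().str.upper()
            df[col] = up.where(up.str.match(_ALLELE_RE), other=pd.NA)
    return df


def _coerce_numeric_columns(df: pd.DataFrame) -> pd.DataFrame:
    for col in _NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def run_pipeline(
    raw: RawTable,
    config: Optional[QCConfig] = None,
    backend: Optional[ReferenceBackend] = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Run the full standardization and QC battery on a raw table.

    Checks run in fixed numeric order: ingest bookkeeping → header
    canonicalization → trait selection → ID normalization → composite
    splits → reference imputation → column validation → missing-data drop →
    duplicate columns → small p → N outliers → rsID validity → row dedup
    (rsID, then position) → on-reference rescue → INFO → strand-ambiguity →
    biallelic → allele flip → non-autosomal → effect/SE sanity.  Optional
    checks honour their :class:`QCConfig` switches.  Reference-dependent
    checks are skipped when ``backend`` is None.

    Returns the standardized table and the :class:`QCReport`; the report's
    conservation invariant is verified before returning.
    """
    config = config or QCConfig()
    if backend is not None and backend.build != config.build:
        raise SumstatsError(
            f"backend build {backend.build} does not match config {config.build}"
        )
    report = QCReport()
    colmap = load_column_map(config.user_synonyms)

    n0 = len(raw.rows)
    report.rows_initial = n0
    fmt = raw.source_format
    report.add(CheckEntry(1, "VCF format detection and import", n0,
                          notes=f"container={fmt.container}"))
    report.add(CheckEntry(2, "delimiter/compression handling", n0,
                          notes=f"delimiter={fmt.delimiter}, compression={fmt.compression}"))

    df, unmapped = standardize_headers(raw, colmap)
    renamed = [r for r in df.attrs.get("header_renames", []) if r[0] != r[1]]
    report.add(CheckEntry(3, "header synonym canonicalization", len(df),
                          modified=len(renamed),
                          notes=("unmapped: " + ", ".join(unmapped)) if unmapped else ""))

    df, traits = resolve_traits(df, colmap, config.trait_selection)
    report.add(CheckEntry(4, "multiple trait/model detection", len(df),
                          notes=("traits: " + ", ".join(traits)) if traits else ""))

    df, n_norm = normalize_snp_ids(df)
    report.add(CheckEntry(5, "SNP ID uniformity", len(df), modified=n_norm))

    df, split_events = split_composite_columns(df)
    for cid, tag in ((6, "CHR:BP:A2:A1"), (7, "CHR:BP"), (8, "A1/A2")):
        hits = [e for e in split_events if
                (cid == 6 and "A2+A1" in e) or
                (cid == 7 and e.endswith("CHR+BP")) or
                (cid == 8 and e.endswith("A1+A2"))]
        report.add(CheckEntry(cid, f"composite {tag} column split", len(df),
                              modified=len(hits),
                              notes="; ".join(hits)))

    df = _coerce_positions_and_alleles(df)

    for cid, op in ((9, harmonize.impute_chr_bp),
                    (10, harmonize.impute_rsid),
                    (11, harmonize.impute_alleles)):
        if backend is not None:
            df, cells = op(df, backend)
        else:
            cells = []
        report.add(CheckEntry(cid, dict(CHECKS)[cid], len(df),
                              cells_imputed=len(cells)))
        report.record_imputations(cid, cells)

    validate_required_columns(df)
    report.add(CheckEntry(12, "required columns present", len(df)))
    signed_present = validate_signed_column(df, require=config.require_signed)
    report.add(CheckEntry(13, "signed/effect column present", len(df),
                          notes=", ".join(signed_present)))

    df = _coerce_numeric_columns(df)
    df, dropped, reasons = drop_missing(df)
    e = report.add(CheckEntry(14, "drop rows with missing data", len(df) + len(dropped),
                              rows_dropped=len(dropped)))
    report.record_drops(14, dropped, reasons)

    df, dup_cols = dedupe_columns(df)
    report.add(CheckEntry(15, "duplicated columns removed", len(df),
                          modified=len(dup_cols),
                          notes=("dropped: " + ", ".join(dup_cols)) if dup_cols else ""))

    df, dropped, reasons, n_conv, n_zero = handle_small_pvalues(df, config)
    report.add(CheckEntry(16, "p-values below 5e-324 handled", len(df) + len(dropped),
                          rows_dropped=len(dropped), modified=n_conv,
                          notes=(f"{n_zero} literal zero p-value(s) flagged"
                                 if n_zero else "")))
    report.record_drops(16, dropped, reasons)

    df, dropped, reasons, n_coerced = filter_n_outliers(df, config)
    report.add(CheckEntry(17, "N integer coercion and outlier removal",
                          len(df) + len(dropped), rows_dropped=len(dropped),
                          modified=n_coerced))
    report.record_drops(17, dropped, reasons)

    df, n_flagged = harmonize.validate_rsids(df)
    report.add(CheckEntry(18, "rsID validity flagged", len(df), modified=n_flagged))

    for cid, key in ((19, "rsid"), (21, "position")):
        df, dropped, reasons = dedupe_rows(df, key)
        report.add(CheckEntry(cid, f"duplicate rows by {key} removed",
                              len(df) + len(dropped), rows_dropped=len(dropped)))
        report.record_drops(cid, dropped, reasons)

    if backend is not None and config.rsid_on_reference_filter:
        df, dropped, reasons, corrected = harmonize.check_on_reference(df, backend)
        report.add(CheckEntry(22, "presence on reference genome",
                              len(df) + len(dropped), rows_dropped=len(dropped),
                              corrected=corrected))
        report.record_drops(22, dropped, reasons)
    else:
        report.add(CheckEntry(22, "presence on reference genome", len(df),
                              notes="skipped"))

    df, dropped, reasons = filter_info(df, config)
    report.add(CheckEntry(23, "INFO score filter", len(df) + len(dropped),
                          rows_dropped=len(dropped)))
    report.record_drops(23, dropped, reasons)

    if config.strand_ambig_filter:
        df, dropped = harmonize.remove_strand_ambiguous(df)
        report.add(CheckEntry(24, "strand-ambiguous SNPs removed",
                              len(df) + len(dropped), rows_dropped=len(dropped)))
        report.record_drops(24, dropped, "strand-ambiguous allele pair (A/T or C/G)")
    else:
        report.add(CheckEntry(24, "strand-ambiguous SNPs removed", len(df),
                              notes="skipped"))

    if backend is not None and config.biallelic_filter:
        df, dropped = harmonize.remove_nonbiallelic(df, backend)
        report.add(CheckEntry(25, "non-biallelic SNPs removed",
                              len(df) + len(dropped), rows_dropped=len(dropped)))
        report.record_drops(25, dropped, "site is multi-allelic in the reference")
    else:
        report.add(CheckEntry(25, "non-biallelic SNPs removed", len(df),
                              notes="skipped"))

    if backend is not None and config.allele_flip_check:
        df, dropped, reasons, flips = harmonize.flip_alleles(df, backend)
        n_flipped = sum(1 for f in flips if f.action == "flipped")
        report.flip_records = flips
        report.add(CheckEntry(26, "allele flipping against reference",
                              len(df) + len(dropped), rows_dropped=len(dropped),
                              modified=n_flipped))
        report.record_drops(26, dropped, reasons)
    else:
        report.add(CheckEntry(26, "allele flipping against reference", len(df),
                              notes="skipped"))

    if config.remove_nonautosomal:
        df, dropped, reasons = remove_nonautosomal(df, config)
        report.add(CheckEntry(27, "chromosome X/Y/MT SNPs removed",
                              len(df) + len(dropped), rows_dropped=len(dropped)))
        report.record_drops(27, dropped, reasons)
    else:
        report.add(CheckEntry(27, "chromosome X/Y/MT SNPs removed", len(df),
                              notes="skipped"))

    report.add(CheckEntry(28, "output is LDSC-ready", len(df),
                          notes="applied at write time"))

    df, dropped, reasons = check_effect_columns(df)
    report.add(CheckEntry(29, "effect columns not zero", len(df) + len(dropped),
                          rows_dropped=len(dropped)))
    report.record_drops(29, dropped, reasons)

    df, dropped, reasons = check_standard_error(df)
    report.add(CheckEntry(30, "standard error positive", len(df) + len(dropped),
                          rows_dropped=len(dropped)))
    report.record_drops(30, dropped, reasons)

    # finalize: typed canonical columns, helper columns removed
    df = df.drop(columns=[c for c in df.columns if c.startswith("_")])
    if "BP" in df.columns:
        df["BP"] = pd.to_numeric(df["BP"]).astype("int64")
    df = df.reset_index(drop=True)
    report.rows_final = len(df)
    report.add(CheckEntry(31, "dropped and imputed values reported", len(df),
                          notes=(f"{report.total_dropped} dropped, "
                                 f"{report.total_imputed} cells imputed")))
    report.verify_conservation()
    return df, report
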