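"""Reference-dependent per-variant harmonization.

Imputation of missing rsIDs, coordinates and alleles from the reference
catalogue; rsID validity flagging; on-reference enforcement with positional
rescue; removal of strand-ambiguous and non-biallelic variants; and allele
flipping so that every retained row's A1 equals the catalogue reference
allele, with effect and frequency columns transformed accordingly
(BETA/Z/LOG_ODDS/SIGNED_SUMSTAT negated, OR inverted, FRQ complemented).

All operations are table → (table, bookkeeping); nothing mutates the
reference backend.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import ReferenceBackend, is_strand_ambiguous

_RS_VALID = re.compile(r"^rs\d+$")

NEGATED_ON_FLIP = ("BETA", "Z", "LOG_ODDS", "SIGNED_SUMSTAT")


@dataclass(frozen=True)
class FlipRecord:
    """Outcome of the allele-flip check for one row."""

    rsid: str
    action: str  # kept | flipped | dropped_no_match | dropped_or_zero

    def __post_init__(self):
        if self.action not in ("kept", "flipped", "dropped_no_match", "dropped_or_zero"):
            raise ValueError(f"bad flip action {self.action!r}")


def _is_missing(s: pd.Series) -> pd.Series:
    return s.isna() | s.astype(str).str.strip().isin(["", "nan", "None", "NA"])


def _row_key(df: pd.DataFrame, i) -> str:
    snp = str(df.at[i, "SNP"]).strip() if "SNP" in df.columns else ""
    if snp and snp.lower() != "nan":
        return snp
    chrom = df.at[i, "CHR"] if "CHR" in df.columns else "?"
    bp = df.at[i, "BP"] if "BP" in df.columns else "?"
    return f"{chrom}:{bp}"


def impute_chr_bp(
    df: pd.DataFrame, backend: ReferenceBackend
) -> tuple[pd.DataFrame, list[tuple[str, str, object]]]:
    """Fill missing CHR/BP cells from the catalogue, keyed by rsID.

    Rows whose rsID is absent from the backend keep their missing values
    (later checks drop them).  Returns the imputed-cell records
    ``(rsid, column, value)``.
    """
    if "SNP" not in df.columns:
        return df, []
    for col in ("CHR", "BP"):
        if col not in df.columns:
            df[col] = pd.Series([pd.NA] * len(df), index=df.index, dtype=object)
    missing = _is_missing(df["CHR"]) | _is_missing(df["BP"])
    if not missing.any():
        return df, []
    rsids = df.loc[missing, "SNP"].astype(str).str.strip()
    found = backend.query_by_rsid(set(rsids))
    imputed = []
    for i in df.index[missing]:
        v = found.get(str(df.at[i, "SNP"]).strip())
        if v is None:
            continue
        if _is_missing(df.loc[[i], "CHR"]).iloc[0]:
            df.at[i, "CHR"] = v.chrom
            imputed.append((v.rsid, "CHR", v.chrom))
        if _is_missing(df.loc[[i], "BP"]).iloc[0]:
            df.at[i, "BP"] = v.pos
            imputed.append((v.rsid, "BP", v.pos))
    return df, imputed


def impute_rsid(
    df: pd.DataFrame, backend: ReferenceBackend
) -> tuple[pd.DataFrame, list[tuple[str, str, object]]]:
    """Fill missing SNP cells from the catalogue, keyed by (CHR, BP).

    At a locus with several catalogued variants the row's alleles decide;
    with no allele match (or no alleles) the cell stays missing.
    """
    if "CHR" not in df.columns or "BP" not in df.columns:
        return df, []
    if "SNP" not in df.columns:
        df["SNP"] = pd.Series([""] * len(df), index=df.index, dtype=object)
    missing = _is_missing(df["SNP"])
    if not missing.any():
        return df, []
    imputed = []
    for i in df.index[missing]:
        if _is_missing(df.loc[[i], "CHR"]).iloc[0] or _is_missing(df.loc[[i], "BP"]).iloc[0]:
            continue
        try:
            locus = (str(df.at[i, "CHR"]).strip(), int(float(df.at[i, "BP"])))
        except (TypeError, ValueError):
            continue
        cands = backend.by_position.get(locus, [])
        pick = None
        if len(cands) == 1:
            pick = cands[0]
        elif len(cands) > 1 and "A1" in df.columns and "A2" in df.columns:
            a1 = str(df.at[i, "A1"]).strip().upper()
            a2 = str(df.at[i, "A2"]).strip().upper()
            matches = [
                v
                for v in cands
                if {a1, a2} <= ({v.ref} | set(v.alts))
            ]
            if len(matches) == 1:
                pick = matches[0]
        if pick is not None:
            df.at[i, "SNP"] = pick.rsid
            imputed.append((pick.rsid, "SNP", pick.rsid))
    return df, imputed


def impute_alleles(
    df: pd.DataFrame, backend: ReferenceBackend
) -> tuple[pd.DataFrame, list[tuple[str, str, object]]]:
    """Fill missing A1 with the catalogue ref, missing A2 with the only alt.

    A2 at a multi-allelic site is undecidable and stays missing.
    """
    if "SNP" not in df.columns:
        return df, []
    for col in ("A1", "A2"):
        if col not in df.columns:
            df[col] = pd.Series([pd.NA] * len(df), index=df.index, dtype=object)
    missing = _is_missing(df["A1"]) | _is_missing(df["A2"])
    if not missing.any():
        return df, []
    found = backend.query_by_rsid(
        set(df.loc[missing, "SNP"].astype(str).str.strip())
    )
    imputed = []
    for i in df.index[missing]:
        v = found.get(str(df.at[i, "SNP"]).strip())
        if v is None:
            continue
        if _is_missing(df.loc[[i], "A1"]).iloc[0]:
            df.at[i, "A1"] = v.ref
            imputed.append((v.rsid, "A1", v.ref))
        if _is_missing(df.loc[[i], "A2"]).iloc[0] and v.is_biallelic:
            df.at[i, "A2"] = v.alts[0]
            imputed.append((v.rsid, "A2", v.alts[0]))
    return df, imputed


def validate_rsids(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Flag SNP IDs that are not ``rs``+digits; they are retained.

    Flagged rows are excluded from rsID-keyed reference operations but may
    still be rescued positionally.  The flag lives in the boolean column
    ``_rsid_valid`` (dropped before output).
    """
    if "SNP" not in df.columns:
        return df, 0
    valid = df["SNP"].astype(str).str.strip().str.match(_RS_VALID)
    df["_rsid_valid"] = valid.to_numpy(dtype=bool)
    return df, int((~valid).sum())


def check_on_reference(
    df: pd.DataFrame, backend: ReferenceBackend
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], int]:
    """Enforce presence on the reference catalogue.

    Rows whose rsID is catalogued pass.  Rows whose rsID is unknown are
    re-keyed by (CHR, BP): a positional hit with compatible alleles corrects
    the rsID to the catalogue's; otherwise the row is dropped.  Returns
    ``(kept, dropped, reasons, corrected_count)``.
    """
    known = backend.query_by_rsid(set(df["SNP"].astype(str).str.strip()))
    drop_idx = []
    reasons = []
    corrected = 0
    for i in df.index:
        rsid = str(df.at[i, "SNP"]).strip()
        if rsid in known:
            continue
        fixed = False
        try:
            locus = (str(df.at[i, "CHR"]).strip(), int(float(df.at[i, "BP"])))
            cands = backend.by_position.get(locus, [])
        except (TypeError, ValueError):
            cands = []
        a1 = str(df.at[i, "A1"]).strip().upper()
        a2 = str(df.at[i, "A2"]).strip().upper()
        for v in cands:
            if {a1, a2} <= ({v.ref} | set(v.alts)):
                df.at[i, "SNP"] = v.rsid
                if "_rsid_valid" in df.columns:
                    df.at[i, "_rsid_valid"] = True
                corrected += 1
                fixed = True
                break
        if not fixed:
            drop_idx.append(i)
            reasons.append("not found on reference genome by rsID or CHR:BP")
    dropped = df.loc[drop_idx]
    kept = df.drop(index=drop_idx)
    return kept, dropped, reasons, corrected


def remove_strand_ambiguous(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove rows whose allele pair is palindromic (A/T or C/G)."""
    mask = [
        is_strand_ambiguous(df.at[i, "A1"], df.at[i, "A2"]) for i in df.index
    ]
    mask = pd.Series(mask, index=df.index)
    return df.loc[~mask], df.loc[mask]


def remove_nonbiallelic(
    df: pd.DataFrame, backend: ReferenceBackend
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove rows whose catalogued site has more than one alternate allele.

    Rows not resolvable in the catalogue are kept (they were already
    handled by the on-reference check, or that check was disabled).
    """
    known = backend.query_by_rsid(set(df["SNP"].astype(str).str.strip()))
    mask = pd.Series(
        [
            (v := known.get(str(df.at[i, "SNP"]).strip())) is not None
            and not v.is_biallelic
            for i in df.index
        ],
        index=df.index,
    )
    return df.loc[~mask], df.loc[mask]


def flip_alleles(
    df: pd.DataFrame, backend: ReferenceBackend
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], list[FlipRecord]]:
    """Orient every row so A1 matches the catalogue reference allele.

    Per row: A1 already equal to the catalogue ref → kept; A1 equal to an
    alt with A2 equal to ref → alleles swapped and effect/frequency columns
    transformed (BETA, Z, LOG_ODDS, SIGNED_SUMSTAT negated; OR inverted;
    FRQ complemented; SE, P, N untouched); neither orientation → dropped.
    Rows whose rsID is not catalogued pass through unflipped.  Returns
    ``(kept, dropped, reasons, flip_records)``.
    """
    known = backend.query_by_rsid(set(df["SNP"].astype(str).str.strip()))
    records: list[FlipRecord] = []
    drop_idx: list = []
    reasons: list[str] = []
    present_negate = [c for c in NEGATED_ON_FLIP if c in df.columns]
    has_or = "OR" in df.columns
    has_frq = "FRQ" in df.columns
    for i in df.index:
        rsid = str(df.at[i, "SNP"]).strip()
        v = known.get(rsid)
        if v is None:
            records.append(FlipRecord(rsid, "kept"))
            continue
        a1 = str(df.at[i, "A1"]).strip().upper()
        a2 = str(df.at[i, "A2"]).strip().upper()
        if a1 == v.ref:
            records.append(FlipRecord(rsid, "kept"))
            continue
        if a1 in v.alts and a2 == v.ref:
            if has_or:
                orv = pd.to_numeric(pd.Series([df.at[i, "OR"]]), errors="coerce").iloc[0]
                if orv == 0:
                    drop_idx.append(i)
                    reasons.append("allele flip required but OR=0 (1/OR undefined)")
                    records.append(FlipRecord(rsid, "dropped_or_zero"))
                    continue
            df.at[i, "A1"], df.at[i, "A2"] = a2, a1
            for col in present_negate:
                val = pd.to_numeric(pd.Series([df.at[i, col]]), errors="coerce").iloc[0]
                if pd.notna(val):
                    df.at[i, col] = -val
            if has_or:
                orv = pd.to_numeric(pd.Series([df.at[i, "OR"]]), errors="coerce").iloc[0]
                if pd.notna(orv):
                    df.at[i, "OR"] = 1.0 / orv
            if has_frq:
                frq = pd.to_numeric(pd.Series([df.at[i, "FRQ"]]), errors="coerce").iloc[0]
                if pd.notna(frq):
                    df.at[i, "FRQ"] = 1.0 - frq
            records.append(FlipRecord(rsid, "flipped"))
            continue
        drop_idx.append(i)
        reasons.append(
            f"alleles {a1}/{a2} match neither orientation of catalogue "
            f"{v.ref}/{'|'.join(v.alts)}"
        )
        records.append(FlipRecord(rsid, "dropped_no_match"))
    dropped = df.loc[drop_idx]
    kept = df.drop(index=drop_idx)
    return kept, dropped, reasons, records
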