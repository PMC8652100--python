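"""Header canonicalization and column-level structural checks.

Covers synonym-based renaming, multi-trait column detection, composite
column splitting (``CHR:BP:A2:A1``, ``CHR:BP``, ``A1/A2``), SNP-ID
normalization, required/signed column validation and duplicate-column
removal.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .errors import CheckError
from .formats import RawTable

CANONICAL_NAMES = {
    "SNP", "BP", "CHR", "A1", "A2", "P", "Z", "OR", "BETA", "LOG_ODDS",
    "SIGNED_SUMSTAT", "N", "N_CAS", "N_CON", "NSTUDY", "INFO", "FRQ", "SE",
}
SIGNED_COLUMNS = ("Z", "OR", "BETA", "LOG_ODDS", "SIGNED_SUMSTAT")
REQUIRED_COLUMNS = ("SNP", "CHR", "BP", "P", "A1", "A2")

_DUP_RE = re.compile(r"^(?P<canon>[A-Z0-9_]+)__dup\d+$")
_RS_RE = re.compile(r"^rs\d+$", re.IGNORECASE)
_INT_RE = re.compile(r"^\d+$")
_CHR_BP_RE = re.compile(r"^(chr)?([0-9XYMTxymt]+):(\d+)$", re.IGNORECASE)
_ALLELE_RE = re.compile(r"^[ACGT]+$", re.IGNORECASE)
_PAIR_RE = re.compile(r"^([ACGTacgt]+)/([ACGTacgt]+)$")


def load_column_map(extra: Optional[dict[str, str]] = None) -> dict[str, str]:
    """Load the synonym→canonical dictionary shipped with the package.

    Matching is case-insensitive on whitespace-stripped, uppercased header
    strings.  ``extra`` merges user-supplied mappings (same key convention);
    a user mapping may not contradict a bundled one.
    """
    mapping: dict[str, str] = {}
    text = (
        resources.files("gwasmunge.data")
        .joinpath("column_synonyms.tsv")
        .read_text(encoding="utf-8")
    )
    for line in text.splitlines()[1:]:  # first line is the column header
        if not line.strip():
            continue
        syn, canon = line.split("\t")
        syn = syn.strip().upper()
        if canon not in CANONICAL_NAMES:
            raise ValueError(f"resource maps {syn} to unknown canonical {canon}")
        if syn in mapping and mapping[syn] != canon:
            raise ValueError(f"synonym {syn} maps to both {mapping[syn]} and {canon}")
        mapping[syn] = canon
    if extra:
        for syn, canon in extra.items():
            syn = syn.strip().upper()
            if canon not in CANONICAL_NAMES:
                raise ValueError(f"user mapping {syn}→{canon}: unknown canonical name")
            if syn in mapping and mapping[syn] != canon:
                raise ValueError(
                    f"user mapping {syn}→{canon} contradicts bundled {mapping[syn]}"
                )
            mapping[syn] = canon
    return mapping


def standardize_headers(
    raw: RawTable | pd.DataFrame, colmap: dict[str, str]
) -> tuple[pd.DataFrame, list[str]]:
    """Rename every recognized header to its canonical name.

    Returns the renamed DataFrame and the list of unmapped headers (kept
    verbatim).  When two raw headers canonicalize to the same name the
    second and later ones get a ``__dupN`` suffix; duplicate-column removal
    drops them later, preserving keep-first semantics.
    """
    df = raw.to_frame() if isinstance(raw, RawTable) else raw.copy()
    renames: list[tuple[str, str]] = []
    unmapped: list[str] = []
    seen: dict[str, int] = {}
    new_cols = []
    for col in df.columns:
        canon = colmap.get(str(col).strip().upper())
        if canon is None:
            unmapped.append(str(col))
            new_cols.append(col)
            continue
        if canon in seen:
            seen[canon] += 1
            new = f"{canon}__dup{seen[canon]}"
        else:
            seen[canon] = 0
            new = canon
        renames.append((str(col), new))
        new_cols.append(new)
    df.columns = new_cols
    df.attrs["header_renames"] = renames
    df.attrs["unmapped_headers"] = unmapped
    return df, unmapped


def detect_multiple_traits(
    headers: Iterable[str], colmap: dict[str, str]
) -> dict[str, dict[str, str]]:
    """Detect repeated effect-column stems carrying distinct trait suffixes.

    A header like ``BETA.height`` is read as stem ``BETA`` + suffix
    ``height`` (separators ``.``, ``_``, ``-``).  Only stems observed with
    two or more distinct suffixes count as multi-trait.  Returns
    ``{suffix: {stem_canonical: original_header}}`` for the detected traits.
    """
    stems: dict[str, dict[str, str]] = {}
    for h in headers:
        h = str(h)
        if h.strip().upper() in colmap:
            continue  # direct synonym, not a suffixed column
        for sep in (".", "_", "-"):
            if sep not in h:
                continue
            prefix, suffix = h.rsplit(sep, 1)
            canon = colmap.get(prefix.strip().upper())
            if canon is not None and suffix:
                stems.setdefault(canon, {})[suffix] = h
                break
    traits: dict[str, dict[str, str]] = {}
    for canon, by_suffix in stems.items():
        if len(by_suffix) >= 2:
            for suffix, h in by_suffix.items():
                traits.setdefault(suffix, {})[canon] = h
    return traits


def resolve_traits(
    df: pd.DataFrame, colmap: dict[str, str], trait_selection: Optional[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Apply multi-trait resolution: keep one trait's columns, drop the rest.

    No detected traits → table unchanged.  Traits detected without a valid
    selection → hard error listing them.  With a selection, the selected
    trait's suffixed columns are renamed to their canonical stems and the
    other traits' columns dropped.
    """
    traits = detect_multiple_traits(df.columns, colmap)
    if not traits:
        return df, []
    if trait_selection is None or trait_selection not in traits:
        raise CheckError(
            4,
            "multiple traits/models detected, select one of: "
            + ", ".join(sorted(traits)),
        )
    keep = traits[trait_selection]
    drop_cols = [
        h
        for suffix, cols in traits.items()
        if suffix != trait_selection
        for h in cols.values()
    ]
    df = df.drop(columns=drop_cols)
    df = df.rename(columns={h: canon for canon, h in keep.items()})
    return df, sorted(traits)


def _classify_composite(value: str) -> str:
    """Classify one cell as c4 (CHR:BP:A2:A1), c2 (CHR:BP), pair, or other."""
    v = value.strip()
    if not v:
        return "empty"
    m = _PAIR_RE.match(v)
    if m:
        return "pair"
    parts = v.split(":")
    if len(parts) == 4 and _INT_RE.match(parts[1]) and _ALLELE_RE.match(parts[2]) and _ALLELE_RE.match(parts[3]):
        return "c4"
    if len(parts) == 2 and _INT_RE.match(parts[1]) and parts[0]:
        return "c2"
    return "other"


def _column_all_empty(df: pd.DataFrame, col: str) -> bool:
    if col not in df.columns:
        return True
    s = df[col].astype(str).str.strip()
    return bool((s.eq("") | s.eq("nan")).all())


def split_composite_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Split composite ``CHR:BP:A2:A1`` / ``CHR:BP`` / ``A1/A2`` columns.

    Candidate columns are SNP, A1 and unmapped (non-canonical) columns.  A
    column is split only when *all* its non-empty values match the same
    composite pattern; a mix of 2-field and 4-field values is a hard error.
    A split never overwrites an existing non-empty canonical column; the
    composite source column is dropped.
    """
    split_events: list[str] = []
    candidates = [
        c
        for c in df.columns
        if c in ("SNP", "A1") or c not in CANONICAL_NAMES
    ]
    for col in candidates:
        values = df[col].astype(str)
        kinds = {_classify_composite(v) for v in values}
        kinds.discard("empty")
        if not kinds or "other" in kinds:
            continue
        if kinds == {"c4"} or kinds == {"c2"}:
            nfields = 4 if kinds == {"c4"} else 2
            parts = values.str.strip().str.split(":", expand=True)
            targets = (
                [("CHR", 0), ("BP", 1), ("A2", 2), ("A1", 3)]
                if nfields == 4
                else [("CHR", 0), ("BP", 1)]
            )
            for canon, idx in targets:
                if _column_all_empty(df, canon):
                    df[canon] = parts[idx].str.strip()
            df = df.drop(columns=[col])
            split_events.append(f"{col}→" + "+".join(t for t, _ in targets))
        elif kinds == {"pair"}:
            parts = values.str.strip().str.split("/", expand=True)
            ok = True
            for canon, idx in [("A1", 0), ("A2", 1)]:
                if not _column_all_empty(df, canon):
                    ok = False
            if ok:
                df["A1"] = parts[0].str.strip()
                df["A2"] = parts[1].str.strip()
                df = df.drop(columns=[col])
                split_events.append(f"{col}→A1+A2")
        elif kinds <= {"c2", "c4"}:
            bad = [
                str(v)
                for v in values.head(50)
                if _classify_composite(str(v)) in ("c2", "c4")
            ][:3]
            raise CheckError(
                6,
                f"column {col!r} mixes 2-field and 4-field composite values, "
                f"e.g. {bad}",
            )
    return df, split_events


def normalize_snp_ids(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Make the SNP column uniform: rs-prefixed IDs, no CHR:BP hybrids.

    Bare integers get an ``rs`` prefix; ``CHR:BP`` values are blanked (the
    rsID is imputed later from the reference) with CHR/BP filled in when
    those cells are empty; existing rs IDs are lower-cased on the prefix.
    """
    if "SNP" not in df.columns:
        return df, 0
    changed = 0
    snp = df["SNP"].astype(str)
    new_snp = snp.copy()
    for i, v in snp.items():
        v = v.strip()
        if _INT_RE.match(v):
            new_snp.at[i] = "rs" + v
            changed += 1
        elif _RS_RE.match(v):
            if not v.startswith("rs"):
                new_snp.at[i] = "rs" + v[2:]
                changed += 1
        else:
            m = _CHR_BP_RE.match(v)
            if m:
                chrom, bp = m.group(2), m.group(3)
                if "CHR" in df.columns:
                    cur = str(df.at[i, "CHR"]).strip()
                    if cur in ("", "nan", "None"):
                        df.at[i, "CHR"] = chrom
                else:
                    df["CHR"] = ""
                    df.at[i, "CHR"] = chrom
                if "BP" in df.columns:
                    cur = str(df.at[i, "BP"]).strip()
                    if cur in ("", "nan", "None"):
                        df.at[i, "BP"] = bp
                else:
                    df["BP"] = ""
                    df.at[i, "BP"] = bp
                new_snp.at[i] = ""
                changed += 1
    df["SNP"] = new_snp
    return df, changed


def validate_required_columns(df: pd.DataFrame) -> None:
    """Hard-error unless SNP, CHR, BP, P, A1 and A2 are all present."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CheckError(
            12,
            "missing required column(s) "
            + ", ".join(missing)
            + "; columns seen: "
            + ", ".join(map(str, df.columns)),
        )


def validate_signed_column(df: pd.DataFrame, require: bool = True) -> list[str]:
    """Return the signed/effect columns present; error if none and required."""
    present = [c for c in SIGNED_COLUMNS if c in df.columns]
    if not present and require:
        raise CheckError(
            13,
            "no signed/effect column found; accepted: " + ", ".join(SIGNED_COLUMNS),
        )
    return present


def dedupe_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop later duplicates of canonical columns (keep-first)."""
    dropped = [c for c in df.columns if _DUP_RE.match(str(c))]
    if dropped:
        df = df.drop(columns=dropped)
    return df, dropped
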