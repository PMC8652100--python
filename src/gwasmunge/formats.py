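"""Input/output for GWAS summary-statistic files.

Handles dialect sniffing (tab / comma / whitespace-run delimited text, plain
or gzip/bgzip compressed, or GWAS-VCF), parsing into a :class:`RawTable`
with verbatim headers, and writing the standardized table back out as
tab-delimited text, GWAS-VCF, or an LDSC-ready munged file.

Conventions: A1 is the non-effect (reference) allele and A2 the effect
(alternative) allele, matching the GWAS-VCF orientation where REF maps to A1
and ALT to A2.  A GWAS-VCF stores per-sample effect size (ES), standard
error (SE), -log10 p (LP), effect-allele frequency (AF) and sample size (SS);
one VCF sample corresponds to one trait.
"""

from __future__ import annotations

import gzip
import math
import os
import re
import shutil
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam

from .errors import CheckError, FormatError

#: Canonical column order for tabular output: identifiers and alleles first,
#: then statistics/metadata.
CANONICAL_ORDER = [
    "SNP", "CHR", "BP", "A1", "A2",
    "P", "Z", "OR", "BETA", "LOG_ODDS", "SIGNED_SUMSTAT", "SE",
    "FRQ", "INFO", "N", "N_CAS", "N_CON", "NSTUDY",
]

_GZIP_MAGIC = b"\x1f\x8b"
_DELIM_CHARS = {"tab": "\t", "comma": ",", "space": None}  # None => \s+ run


@dataclass(frozen=True)
class FormatDescriptor:
    """Resolved physical dialect of an input file.

    ``container`` is ``"delimited"`` or ``"vcf"``; ``delimiter`` is one of
    ``tab``/``comma``/``space`` for delimited containers and ``None`` for
    VCF; ``compression`` is ``none``/``gzip``/``bgzip``.  Derived from file
    content (magic bytes plus the first non-comment lines), never from the
    file extension.
    """

    container: str
    delimiter: Optional[str]
    compression: str

    def __post_init__(self):
        if self.container not in ("delimited", "vcf"):
            raise ValueError(f"bad container {self.container!r}")
        if self.container == "vcf" and self.delimiter is not None:
            raise ValueError("vcf container cannot carry a delimiter")
        if self.compression not in ("none", "gzip", "bgzip"):
            raise ValueError(f"bad compression {self.compression!r}")


@dataclass
class RawTable:
    """A parsed but not yet canonicalized summary-statistics table.

    Headers are kept byte-for-byte as observed in the file so the audit
    report can name them; every row has exactly ``len(headers)`` fields.
    """

    headers: list[str]
    rows: list[list[str]]
    source_format: FormatDescriptor = field(
        default_factory=lambda: FormatDescriptor("delimited", "tab", "none")
    )

    def __post_init__(self):
        ncol = len(self.headers)
        for i, row in enumerate(self.rows):
            if len(row) != ncol:
                raise ValueError(f"row {i} has {len(row)} fields, expected {ncol}")

    def to_frame(self) -> pd.DataFrame:
        """Return the table as an all-string DataFrame (verbatim headers)."""
        return pd.DataFrame(self.rows, columns=self.headers, dtype=object)


def _detect_compression(first_bytes: bytes) -> str:
    if not first_bytes.startswith(_GZIP_MAGIC):
        return "none"
    # bgzip is gzip with FEXTRA set and a "BC" extra subfield.
    if len(first_bytes) >= 4 and first_bytes[3] & 0x04:
        # extra field starts at offset 12 (after XLEN at 10-11)
        if len(first_bytes) >= 12:
            xlen = int.from_bytes(first_bytes[10:12], "little")
            extra = first_bytes[12 : 12 + xlen]
            off = 0
            while off + 4 <= len(extra):
                si1, si2 = extra[off], extra[off + 1]
                slen = int.from_bytes(extra[off + 2 : off + 4], "little")
                if si1 == 0x42 and si2 == 0x43:  # 'B','C'
                    return "bgzip"
                off += 4 + slen
    return "gzip"


def _split_line(line: str, delim_name: str) -> list[str]:
    line = line.rstrip("\r\n")
    char = _DELIM_CHARS[delim_name]
    if char is None:
        return re.split(r"\s+", line.strip())
    return line.split(char)


def sniff_format(first_bytes: bytes, first_lines: str) -> FormatDescriptor:
    """Infer the file dialect from raw leading bytes and decompressed text.

    ``first_bytes`` are the first raw (possibly compressed) bytes of the
    file, used only for compression detection; ``first_lines`` is already
    decompressed text containing at least the header line and ideally the
    first data line.

    The delimiter is the candidate among tab, comma and whitespace-run that
    splits the header and the first data line into the same (>1) number of
    fields, preferring the candidate producing the most fields.
    """
    compression = _detect_compression(first_bytes)
    lines = [ln for ln in first_lines.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty input: no non-blank lines found")
    if lines[0].startswith("##fileformat=VCF"):
        return FormatDescriptor("vcf", None, compression)

    # skip meta/comment lines ('##...') preceding the header
    body = [ln for ln in lines if not ln.startswith("##")]
    if not body:
        raise FormatError("only comment lines found before end of preview")
    header, data = body[0], (body[1] if len(body) > 1 else None)

    best: tuple[int, str] | None = None
    tried = {}
    for name in ("tab", "comma", "space"):
        nh = len(_split_line(header, name))
        nd = len(_split_line(data, name)) if data is not None else nh
        tried[name] = (nh, nd)
        if nh == nd and nh > 1:
            if best is None or nh > best[0]:
                best = (nh, name)
    if best is None:
        raise FormatError(
            "cannot determine delimiter: none of tab/comma/space splits header "
            f"and first data row into matching field counts (tried {tried})"
        )
    return FormatDescriptor("delimited", best[1], compression)


def sniff_path(path: str | os.PathLike) -> FormatDescriptor:
    """Sniff a file on disk (reads magic bytes, decompresses a preview)."""
    path = os.fspath(path)
    with open(path, "rb") as fh:
        head = fh.read(1 << 16)
    if not head:
        raise FormatError(f"{path}: empty file")
    compression = _detect_compression(head)
    try:
        if compression == "none":
            text = head.decode("utf-8", errors="replace")
        else:
            with gzip.open(path, "rt", errors="replace") as fh:
                text = "".join(fh.readline() for _ in range(200))
    except (OSError, EOFError) as exc:
        raise FormatError(f"{path}: unreadable compressed stream ({exc})") from exc
    desc = sniff_format(head, text)
    return desc


def _open_text(path: str, compression: str):
    if compression == "none":
        return open(path, "rt", encoding="utf-8", errors="replace")
    return gzip.open(path, "rt", encoding="utf-8", errors="replace")


def read_sumstats(path: str | os.PathLike, sample: Optional[str] = None) -> RawTable:
    """Read a summary-statistics file of any supported dialect.

    Dispatches to :func:`read_gwas_vcf` when the content sniffs as VCF.
    Raises :class:`FormatError` on truncated compressed streams and on
    ragged rows (listing the offending line numbers).
    """
    path = os.fspath(path)
    desc = sniff_path(path)
    if desc.container == "vcf":
        return read_gwas_vcf(path, sample=sample)

    headers: list[str] | None = None
    rows: list[list[str]] = []
    ragged: list[int] = []
    try:
        with _open_text(path, desc.compression) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                if headers is None and line.startswith("##"):
                    continue  # comment lines before the header
                fields = _split_line(line, desc.delimiter)
                if headers is None:
                    headers = fields
                    continue
                if len(fields) != len(headers):
                    ragged.append(lineno)
                    continue
                rows.append(fields)
    except (OSError, EOFError) as exc:
        raise FormatError(f"{path}: unreadable/truncated stream ({exc})") from exc
    if headers is None:
        raise FormatError(f"{path}: no header line found")
    if ragged:
        shown = ", ".join(map(str, ragged[:10]))
        raise FormatError(
            f"{path}: {len(ragged)} ragged row(s) with wrong field count "
            f"at line(s) {shown}"
        )
    return RawTable(headers=headers, rows=rows, source_format=desc)


def _format_p_from_lp(lp: float) -> str:
    """Convert a -log10 p back to a textual p-value, preserving underflow."""
    p = 10.0 ** (-lp)
    if p == 0.0:  # below the smallest subnormal double: keep textual form
        return f"1e-{lp:g}"
    return f"{p:.10g}"


def _fmt_num(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return f"{v:.10g}"
    return str(v)


def read_gwas_vcf(path: str | os.PathLike, sample: Optional[str] = None) -> RawTable:
    """Read a GWAS-VCF into a :class:`RawTable` with canonical headers.

    Field mapping: ID→SNP, CHROM→CHR, POS→BP, REF→A1, ALT→A2; per-sample
    ES→BETA, SE→SE, LP→P (as 10^-LP), AF→FRQ, SS→N.  A multi-sample (i.e.
    multi-trait) file requires ``sample``; otherwise the error lists the
    available sample IDs.
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        head = fh.read(1 << 16)
    compression = _detect_compression(head)

    tmpdir = None
    open_path = path
    if compression == "gzip":
        # htslib rejects non-bgzf gzip for VCF in some modes; hand it a
        # decompressed temp copy.
        tmpdir = tempfile.mkdtemp(prefix="gwasmunge_vcf_")
        open_path = os.path.join(tmpdir, "in.vcf")
        try:
            with gzip.open(path, "rb") as src, open(open_path, "wb") as dst:
                shutil.copyfileobj(src, dst)
        except (OSError, EOFError) as exc:
            shutil.rmtree(tmpdir, ignore_errors=True)
            raise FormatError(f"{path}: unreadable compressed stream ({exc})") from exc
    try:
        try:
            vf = pysam.VariantFile(open_path)
        except (OSError, ValueError) as exc:
            raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
        with vf:
            samples = list(vf.header.samples)
            if sample is None:
                if len(samples) > 1:
                    raise FormatError(
                        f"{path}: multi-sample GWAS-VCF, select one trait of: "
                        + ", ".join(samples)
                    )
                sample = samples[0] if samples else None
            elif sample not in samples:
                raise FormatError(
                    f"{path}: sample {sample!r} not found; available: "
                    + ", ".join(samples)
                )

            fmt_map = [("ES", "BETA"), ("SE", "SE"), ("AF", "FRQ"), ("SS", "N")]
            have_fmt = set(vf.header.formats.keys())
            headers = ["SNP", "CHR", "BP", "A1", "A2"]
            for key, canon in fmt_map:
                if key in have_fmt:
                    headers.append(canon)
            if "LP" in have_fmt:
                headers.append("P")

            rows = []
            for rec in vf:
                alt = rec.alts[0] if rec.alts else ""
                row = [
                    rec.id or "",
                    str(rec.chrom),
                    str(rec.pos),
                    rec.ref or "",
                    alt,
                ]
                sdata = rec.samples[sample] if sample is not None else {}
                for key, _canon in fmt_map:
                    if key in have_fmt:
                        v = sdata.get(key) if sample is not None else None
                        if isinstance(v, tuple):
                            v = v[0] if v else None
                        if _canon == "N" and v is not None:
                            row.append(str(int(round(float(v)))))
                        else:
                            row.append(_fmt_num(v))
                if "LP" in have_fmt:
                    lp = sdata.get("LP") if sample is not None else None
                    if isinstance(lp, tuple):
                        lp = lp[0] if lp else None
                    row.append("" if lp is None else _format_p_from_lp(float(lp)))
                rows.append(row)
    finally:
        if tmpdir is not None:
            shutil.rmtree(tmpdir, ignore_errors=True)
    return RawTable(
        headers=headers,
        rows=rows,
        source_format=FormatDescriptor("vcf", None, compression),
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_CHROM_SORT = {str(c): i for i, c in enumerate(list(range(1, 23)) + ["X", "Y", "MT"])}


def _ordered_columns(df: pd.DataFrame) -> list[str]:
    known = [c for c in CANONICAL_ORDER if c in df.columns]
    extras = [c for c in df.columns if c not in CANONICAL_ORDER]
    return known + extras


def _zscore_for_ldsc(df: pd.DataFrame) -> pd.Series:
    """Signed Z statistic for LDSC: Z if present, else BETA/SE, else from P."""
    from scipy.stats import norm

    if "Z" in df.columns:
        return pd.to_numeric(df["Z"], errors="coerce")
    if "BETA" in df.columns and "SE" in df.columns:
        beta = pd.to_numeric(df["BETA"], errors="coerce")
        se = pd.to_numeric(df["SE"], errors="coerce")
        return beta / se
    sign_src = None
    for col in ("BETA", "LOG_ODDS", "SIGNED_SUMSTAT"):
        if col in df.columns:
            sign_src = pd.to_numeric(df[col], errors="coerce")
            break
    if sign_src is None and "OR" in df.columns:
        sign_src = np.log(pd.to_numeric(df["OR"], errors="coerce"))
    if sign_src is None or "P" not in df.columns:
        raise CheckError(
            28,
            "LDSC output requires a signed statistic (Z, or BETA/SE, or a "
            "signed column plus P)",
        )
    p = pd.to_numeric(df["P"], errors="coerce")
    mag = np.abs(norm.ppf(p / 2.0))
    return np.sign(sign_src) * mag


def write_output(
    table: pd.DataFrame,
    path: str | os.PathLike,
    format: str = "tabular",
    compress: bool = True,
    sample_id: str = "TRAIT",
) -> str:
    """Write a pipeline-clean table as ``tabular``, ``vcf`` or ``ldsc``.

    ``tabular``: tab-delimited, canonical column order, gzip-compressed by
    default.  ``vcf``: GWAS-VCF with per-sample ES/SE/LP/AF/SS fields
    (bgzip-compressed when ``compress``).  ``ldsc``: exactly the columns
    LDSC's munged format consumes — SNP, A1, A2, Z, N.
    """
    path = os.fspath(path)
    if format == "tabular":
        out = table[_ordered_columns(table)]
        out.to_csv(
            path, sep="\t", index=False, compression="gzip" if compress else None
        )
        return path

    if format == "ldsc":
        if "N" not in table.columns:
            raise CheckError(28, "LDSC output requires an N (sample size) column")
        z = _zscore_for_ldsc(table)
        out = pd.DataFrame(
            {
                "SNP": table["SNP"],
                "A1": table["A1"],
                "A2": table["A2"],
                "Z": z,
                "N": pd.to_numeric(table["N"], errors="coerce").round().astype("Int64"),
            }
        )
        out.to_csv(
            path, sep="\t", index=False, compression="gzip" if compress else None
        )
        return path

    if format == "vcf":
        return _write_gwas_vcf(table, path, compress=compress, sample_id=sample_id)

    raise ValueError(f"unknown output format {format!r}")


def _write_gwas_vcf(
    table: pd.DataFrame, path: str, compress: bool, sample_id: str
) -> str:
    header = pysam.VariantHeader()
    header.add_meta("source", "gwasmunge")
    chroms = sorted(
        {str(c) for c in table["CHR"]},
        key=lambda c: (_CHROM_SORT.get(c, 99), c),
    )
    for c in chroms:
        header.contigs.add(c)
    header.formats.add("ES", 1, "Float", "Effect size estimate relative to the alternative allele")
    header.formats.add("SE", 1, "Float", "Standard error of effect size estimate")
    header.formats.add("LP", 1, "Float", "-log10 p-value for effect estimate")
    header.formats.add("AF", 1, "Float", "Alternative allele frequency")
    header.formats.add("SS", 1, "Integer", "Sample size used to estimate genetic effect")
    header.add_sample(sample_id)

    mode = "wz" if compress else "w"
    have = table.columns
    with pysam.VariantFile(path, mode, header=header) as vf:
        for _, row in table.iterrows():
            rec = vf.new_record(
                contig=str(row["CHR"]),
                start=int(row["BP"]) - 1,
                stop=int(row["BP"]) - 1 + len(str(row["A1"])),
                alleles=(str(row["A1"]), str(row["A2"])),
                id=str(row["SNP"]) if row["SNP"] else None,
            )
            smp = rec.samples[sample_id]
            if "BETA" in have and pd.notna(row.get("BETA")):
                smp["ES"] = float(row["BETA"])
            if "SE" in have and pd.notna(row.get("SE")):
                smp["SE"] = float(row["SE"])
            if "P" in have and pd.notna(row.get("P")):
                p = float(row["P"])
                smp["LP"] = 999.0 if p <= 0 else -math.log10(p)
            if "FRQ" in have and pd.notna(row.get("FRQ")):
                smp["AF"] = float(row["FRQ"])
            if "N" in have and pd.notna(row.get("N")):
                smp["SS"] = int(round(float(row["N"])))
            vf.write(rec)
    return path
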