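"""Synthetic summary-statistics fixture generator.

Draws variants from a :class:`~gwasmunge.reference.ReferenceBackend` and
emits a raw table in one of the bundled header dialects (emulating the most
common consortium formats), with controllable, counted corruptions: header
synonyms, missing identifiers/coordinates/alleles, flipped allele
orientation (with correspondingly negated effect and complemented
frequency, so un-flipping is verifiable), bare-integer rsIDs, ``CHR:BP``
composite IDs, duplicated rows, sub-threshold INFO, p-value underflow
strings, sample-size outliers, zero effects, non-positive standard errors
and non-autosomal rows.

Every corruption is recorded per row in a :class:`GroundTruth`, which also
pre-computes the per-check drop/impute counts the QC pipeline should report
under default settings — the generator is the oracle for the pipeline's
audit report.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from typing import Optional

import numpy as np

from .errors import SumstatsError
from .formats import FormatDescriptor, RawTable
from .reference import ReferenceBackend, ReferenceVariant, is_strand_ambiguous

_BASES = ("A", "C", "G", "T")


def load_dialects() -> dict:
    """Load the bundled header-dialect presets."""
    text = (
        resources.files("gwasmunge.data")
        .joinpath("dialects.json")
        .read_text(encoding="utf-8")
    )
    return json.loads(text)


@dataclass
class CorruptionSpec:
    """Counts of rows to corrupt, one attribute per corruption kind."""

    missing_snp: int = 0
    missing_chr_bp: int = 0
    missing_alleles: int = 0
    flipped: int = 0
    bare_rsid: int = 0
    chr_bp_id: int = 0
    duplicate_row: int = 0
    duplicate_position: int = 0
    low_info: int = 0
    p_underflow: int = 0
    n_outlier: int = 0
    zero_beta: int = 0
    nonpositive_se: int = 0
    nonautosomal: int = 0
    strand_ambiguous: int = 0
    nonbiallelic: int = 0
    not_on_reference: int = 0
    stale_rsid: int = 0
    missing_p: int = 0

    def counts(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def total(self) -> int:
        return sum(self.counts().values())


@dataclass
class GroundTruth:
    """What was corrupted, and what the pipeline should do about it.

    ``rows``: corruption kind → list of true rsIDs affected.
    ``originals``: rsid → clean canonical values (pre-corruption), for
    verifying that allele un-flipping restores them.
    ``expected``: check id → expected ``dropped`` / ``imputed_cells`` /
    ``modified`` / ``corrected`` / ``flipped`` counts under default QC
    settings (small-p conversion on, N-outlier multiplier 5).
    ``n_rows_written``: total rows emitted including duplicates.
    """

    rows: dict[str, list[str]] = field(default_factory=dict)
    originals: dict[str, dict[str, str]] = field(default_factory=dict)
    expected: dict[int, dict[str, int]] = field(default_factory=dict)
    n_rows_written: int = 0

    @property
    def total_dropped(self) -> int:
        return sum(e.get("dropped", 0) for e in self.expected.values())

    def to_json(self, path: str) -> str:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "rows": self.rows,
                    "originals": self.originals,
                    "expected": {str(k): v for k, v in self.expected.items()},
                    "n_rows_written": self.n_rows_written,
                },
                fh,
                indent=1,
            )
        return path


def _clean_class(backend: ReferenceBackend) -> dict[str, list[ReferenceVariant]]:
    """Partition the catalogue into the variant classes the generator uses."""
    pools: dict[str, list[ReferenceVariant]] = {
        "clean": [],
        "special": [],
        "ambiguous": [],
        "nonbiallelic": [],
    }
    collision_pairs: list[tuple[ReferenceVariant, ReferenceVariant]] = []
    seen_pairs = set()
    for v in backend.variants:
        at_pos = backend.by_position[(v.chrom, v.pos)]
        if len(at_pos) > 1:
            key = (v.chrom, v.pos)
            if key not in seen_pairs and len(at_pos) == 2:
                a, b = at_pos
                good = all(
                    x.is_biallelic
                    and x.chrom not in ("X", "Y", "MT")
                    and not is_strand_ambiguous(x.ref, x.alts[0])
                    for x in (a, b)
                )
                if good:
                    collision_pairs.append((a, b))
                seen_pairs.add(key)
            continue
        ambiguous = v.is_biallelic and is_strand_ambiguous(v.ref, v.alts[0])
        if v.chrom in ("X", "Y", "MT"):
            if v.is_biallelic and not ambiguous:
                pools["special"].append(v)
        elif not v.is_biallelic:
            if not is_strand_ambiguous(v.ref, v.alts[0]):
                pools["nonbiallelic"].append(v)
        elif ambiguous:
            pools["ambiguous"].append(v)
        else:
            pools["clean"].append(v)
    pools["collision_pairs"] = collision_pairs  # type: ignore[assignment]
    return pools


_N_BASE = 50_000


def _clean_values(rng: np.random.Generator, v: ReferenceVariant) -> dict[str, str]:
    beta = 0.0
    while abs(beta) < 1e-4:
        beta = rng.normal(0.0, 0.1)
    beta = round(float(beta), 6)
    se = round(float(rng.uniform(0.05, 0.2)), 6)
    n_total = _N_BASE + int(rng.integers(-50, 51))
    n_cas = n_total // 2 + int(rng.integers(-20, 21))
    return {
        "SNP": v.rsid,
        "CHR": v.chrom,
        "BP": str(v.pos),
        "A1": v.ref,
        "A2": v.alts[0],
        "BETA": f"{beta:g}",
        "SE": f"{se:g}",
        "P": f"{rng.uniform(1e-8, 0.99):.6g}",
        "FRQ": f"{round(float(rng.uniform(0.05, 0.95)), 6):g}",
        "INFO": f"{round(float(rng.uniform(0.9, 1.0)), 4):g}",
        "N": str(n_total),
        "N_CAS": str(n_cas),
        "N_CON": str(n_total - n_cas),
        "Z": f"{round(beta / se, 6):g}",
        "OR": f"{round(math.exp(beta), 6):g}",
    }


def make_sumstats_fixture(
    backend: ReferenceBackend,
    seed: int,
    n_rows: int = 100,
    corruption: Optional[CorruptionSpec] = None,
    dialect: str = "canonical",
) -> tuple[RawTable, GroundTruth]:
    """Generate a raw summary-statistics table with known corruptions.

    Returns the raw table (headers in the chosen dialect) and the ground
    truth recording every corrupted row and the per-check outcome the QC
    pipeline should produce.  Deterministic for a fixed seed.
    """
    corruption = corruption or CorruptionSpec()
    dialects = load_dialects()
    if dialect not in dialects:
        raise SumstatsError(f"unknown dialect {dialect!r}; known: {sorted(dialects)}")
    preset = dialects[dialect]
    cols: dict[str, str] = preset["columns"]
    composite = bool(preset.get("composite_id", False))
    rng = np.random.default_rng(seed)

    # -- contradiction checks -------------------------------------------
    c = corruption
    def _need(col: str, *kinds: str):
        for kind in kinds:
            if getattr(c, kind) > 0 and col not in cols:
                raise SumstatsError(
                    f"corruption {kind!r} needs a {col} column, absent from "
                    f"dialect {dialect!r}"
                )
    _need("INFO", "low_info")
    _need("P", "p_underflow", "missing_p")
    _need("N", "n_outlier")
    _need("BETA", "zero_beta", "flipped")
    _need("SE", "nonpositive_se")
    _need("SNP", "missing_snp", "bare_rsid", "chr_bp_id", "stale_rsid")
    if composite:
        for kind in ("missing_snp", "missing_chr_bp", "bare_rsid", "chr_bp_id",
                     "stale_rsid", "not_on_reference"):
            if getattr(c, kind) > 0:
                raise SumstatsError(
                    f"corruption {kind!r} contradicts composite-ID dialect"
                )
    has_chr_bp = ("CHR" in cols and "BP" in cols) or composite
    if not has_chr_bp:
        for kind in ("not_on_reference", "stale_rsid", "missing_chr_bp",
                     "duplicate_position", "missing_snp"):
            if getattr(c, kind) > 0:
                raise SumstatsError(
                    f"corruption {kind!r} needs CHR/BP columns, absent from "
                    f"dialect {dialect!r}"
                )
    if ("A1" not in cols or "A2" not in cols) and not composite:
        if c.missing_alleles or c.flipped or c.strand_ambiguous:
            raise SumstatsError(f"dialect {dialect!r} lacks allele columns")

    pools = _clean_class(backend)
    n_special_rows = c.nonautosomal
    n_ambig_rows = c.strand_ambiguous
    n_nonbi_rows = c.nonbiallelic
    n_fake_rows = c.not_on_reference
    n_collision = c.duplicate_position
    n_clean_needed = n_rows - n_special_rows - n_ambig_rows - n_nonbi_rows - n_fake_rows - n_collision
    if n_clean_needed < 0:
        raise SumstatsError("class-level corruption counts exceed n_rows")
    cell_level = (
        c.missing_snp + c.missing_chr_bp + c.missing_alleles + c.flipped
        + c.bare_rsid + c.chr_bp_id + c.low_info + c.p_underflow + c.n_outlier
        + c.zero_beta + c.nonpositive_se + c.stale_rsid + c.missing_p
        + c.duplicate_row
    )
    if cell_level > n_clean_needed:
        raise SumstatsError(
            "cell-level corruption counts exceed the clean rows available"
        )
    for pool, need in [("clean", n_clean_needed), ("special", n_special_rows),
                       ("ambiguous", n_ambig_rows), ("nonbiallelic", n_nonbi_rows),
                       ("collision_pairs", n_collision)]:
        if need > len(pools[pool]):
            raise SumstatsError(
                f"reference backend has only {len(pools[pool])} {pool} variants, "
                f"{need} needed; grow the catalogue"
            )

    def _draw(pool: str, k: int) -> list:
        items = pools[pool]
        idx = rng.choice(len(items), size=k, replace=False) if k else []
        return [items[int(i)] for i in idx]

    rows: list[dict[str, str]] = []     # canonical value dicts
    tags: list[list[str]] = []          # corruption tags per row
    truth = GroundTruth()

    def _add(v: ReferenceVariant, tag: Optional[str] = None) -> dict[str, str]:
        vals = _clean_values(rng, v)
        rows.append(vals)
        tags.append([tag] if tag else [])
        if tag:
            truth.rows.setdefault(tag, []).append(v.rsid)
        return vals

    for v in _draw("clean", n_clean_needed):
        _add(v)
    for v in _draw("special", n_special_rows):
        _add(v, "nonautosomal")
    for v in _draw("ambiguous", n_ambig_rows):
        _add(v, "strand_ambiguous")
    for v in _draw("nonbiallelic", n_nonbi_rows):
        _add(v, "nonbiallelic")
    collision_extras: list[dict[str, str]] = []
    collision_hosts: set[int] = set()
    for a, b in _draw("collision_pairs", n_collision):
        # the kept first occurrence behaves like a clean row, but must not
        # receive a row-dropping cell corruption or its partner would no
        # longer be a positional duplicate at the dedup stage
        _add(a)
        collision_hosts.add(len(rows) - 1)
        vals_b = _clean_values(rng, b)
        collision_extras.append(vals_b)
        truth.rows.setdefault("duplicate_position", []).append(b.rsid)
    used_positions = {(v.chrom, int(v.pos)) for v in backend.variants}
    for i in range(n_fake_rows):
        chrom = str(rng.integers(1, 23))
        pos = 90_000_000 + i
        while (chrom, pos) in used_positions:
            pos += 1
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES
                              if b != ref and not is_strand_ambiguous(ref, b)]))
        fake = ReferenceVariant(f"rs{900000000 + i}", chrom, pos, ref, (alt,))
        _add(fake, "not_on_reference")

    # -- cell-level corruptions on distinct clean rows -------------------
    clean_idx = [i for i, t in enumerate(tags) if not t and i not in collision_hosts]
    rng.shuffle(clean_idx)
    cursor = 0

    def _take(kind: str, k: int) -> list[int]:
        nonlocal cursor
        chosen = clean_idx[cursor : cursor + k]
        cursor += k
        for i in chosen:
            tags[i].append(kind)
            truth.rows.setdefault(kind, []).append(rows[i]["SNP"])
        return chosen

    for i in _take("flipped", c.flipped):
        r = rows[i]
        truth.originals[r["SNP"]] = dict(r)
        r["A1"], r["A2"] = r["A2"], r["A1"]
        r["BETA"] = f"{-float(r['BETA']):g}"
        r["FRQ"] = f"{round(1.0 - float(r['FRQ']), 6):g}"
        r["Z"] = f"{-float(r['Z']):g}"
        r["OR"] = f"{round(1.0 / float(r['OR']), 6):g}"
    for i in _take("missing_snp", c.missing_snp):
        rows[i]["SNP"] = ""
    for i in _take("missing_chr_bp", c.missing_chr_bp):
        rows[i]["CHR"] = ""
        rows[i]["BP"] = ""
    for i in _take("missing_alleles", c.missing_alleles):
        rows[i]["A1"] = ""
        rows[i]["A2"] = ""
    for i in _take("bare_rsid", c.bare_rsid):
        rows[i]["SNP"] = rows[i]["SNP"][2:]
    for i in _take("chr_bp_id", c.chr_bp_id):
        rows[i]["SNP"] = f"{rows[i]['CHR']}:{rows[i]['BP']}"
    for i in _take("low_info", c.low_info):
        rows[i]["INFO"] = f"{round(float(rng.uniform(0.1, 0.8)), 4):g}"
    for i in _take("p_underflow", c.p_underflow):
        rows[i]["P"] = "1e-350"
    for i in _take("n_outlier", c.n_outlier):
        rows[i]["N"] = str(_N_BASE * 50)
    for i in _take("zero_beta", c.zero_beta):
        rows[i]["BETA"] = "0"
        rows[i]["Z"] = "0"
    for i in _take("nonpositive_se", c.nonpositive_se):
        rows[i]["SE"] = "-0.05"
    for i in _take("stale_rsid", c.stale_rsid):
        # _take recorded the true rsid before this overwrite
        rows[i]["SNP"] = f"rs{910000000 + i}"
    for i in _take("missing_p", c.missing_p):
        rows[i]["P"] = ""
    dup_extras: list[dict[str, str]] = []
    src = clean_idx[cursor : cursor + c.duplicate_row]
    cursor += c.duplicate_row
    for i in src:
        dup_extras.append(dict(rows[i]))
        truth.rows.setdefault("duplicate_row", []).append(rows[i]["SNP"])

    # shuffle base rows, then append duplicates/collisions at the end so
    # keep-first semantics are well defined
    order = rng.permutation(len(rows))
    rows = [rows[int(i)] for i in order]
    tags = [tags[int(i)] for i in order]
    for extra in dup_extras:
        rows.append(extra)
        tags.append(["duplicate_row"])
    for extra in collision_extras:
        rows.append(extra)
        tags.append(["duplicate_position"])
    truth.n_rows_written = len(rows)

    # -- expected per-check outcome under default settings ---------------
    exp: dict[int, dict[str, int]] = {}

    def bump(check: int, key: str, k: int = 1):
        exp.setdefault(check, {})[key] = exp.setdefault(check, {}).get(key, 0) + k

    n_values = []
    for r, t in zip(rows, tags):
        if "bare_rsid" in t or "chr_bp_id" in t:
            bump(5, "modified")
        if composite:
            bump(10, "imputed_cells")  # composite column replaces SNP entirely
        elif "missing_snp" in t or "chr_bp_id" in t:
            bump(10, "imputed_cells")
        if not has_chr_bp:
            if "chr_bp_id" not in t:
                bump(9, "imputed_cells", 2)
        elif "missing_chr_bp" in t:
            bump(9, "imputed_cells", 2)
        if "missing_alleles" in t:
            bump(11, "imputed_cells", 2)
        if "missing_p" in t:
            bump(14, "dropped")
        if "p_underflow" in t:
            bump(16, "modified")
        if "duplicate_row" in t:
            bump(19, "dropped")
        if "duplicate_position" in t:
            bump(21, "dropped")
        if "not_on_reference" in t:
            bump(22, "dropped")
        if "stale_rsid" in t:
            bump(22, "corrected")
        if "low_info" in t:
            bump(23, "dropped")
        if "strand_ambiguous" in t:
            bump(24, "dropped")
        if "nonbiallelic" in t:
            bump(25, "dropped")
        if "flipped" in t:
            bump(26, "flipped")
        if "nonautosomal" in t:
            bump(27, "dropped")
        if "zero_beta" in t:
            bump(29, "dropped")
        if "nonpositive_se" in t:
            bump(30, "dropped")
        if "N" in cols and "missing_p" not in t:
            n_values.append((float(r["N"]), "n_outlier" in t))
    # N outliers: verify with the same mean + 5*sd rule the pipeline uses,
    # on the rows still present at that stage (after earlier drops the
    # outlier remains dominant, so membership is stable)
    if n_values:
        arr = np.array([v for v, _ in n_values])
        thresh = arr.mean() + 5.0 * arr.std(ddof=1) if len(arr) > 1 else np.inf
        for v, flagged in n_values:
            if flagged and not v > thresh:
                raise SumstatsError(
                    "n_outlier corruption did not exceed the mean+5*sd bound; "
                    "increase n_rows"
                )
        bump(17, "dropped", sum(1 for v, f in n_values if f))
        if 17 in exp and exp[17].get("dropped") != c.n_outlier:
            raise SumstatsError("n_outlier ground truth inconsistent")
    truth.expected = exp

    # -- render in the requested dialect ---------------------------------
    headers = list(cols.values())
    out_rows = []
    for r in rows:
        rendered = []
        for canon, header in cols.items():
            if composite and canon == "SNP":
                rendered.append(f"{r['CHR']}:{r['BP']}:{r['A2']}:{r['A1']}")
            else:
                rendered.append(r.get(canon, ""))
        out_rows.append(rendered)
    raw = RawTable(
        headers=headers,
        rows=out_rows,
        source_format=FormatDescriptor("delimited", "tab", "none"),
    )
    return raw, truth
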