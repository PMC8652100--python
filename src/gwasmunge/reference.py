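"""Reference variant-catalogue backend.

Reference-dependent QC (imputing missing rsIDs/coordinates/alleles,
on-reference filtering, biallelic filtering and allele flipping) works
against a minimal contract: rsID ↔ (chromosome, position) ↔ allele lookups
over a catalogue of known variants for one genome build.  The catalogue can
come from a dbSNP-style VCF, a plain-text serialized catalogue, or the
synthetic generator used throughout the test-suite.

Positions are 1-based (VCF convention); chromosome names are bare tokens
(``1``–``22``, ``X``, ``Y``, ``MT``) with ``chr`` prefixes, ``M`` and the
PLINK numeric sex codes (23→X, 24→Y) normalized on ingest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import FormatError, SumstatsError

AUTOSOMES = [str(c) for c in range(1, 23)]
VALID_CHROMS = set(AUTOSOMES) | {"X", "Y", "MT"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def normalize_chrom(token: object) -> Optional[str]:
    """Normalize a chromosome token; return ``None`` when unrecognizable.

    ``chr1``/``Chr1``/``1`` → ``1``; ``M``/``chrM`` → ``MT``; ``23`` → ``X``;
    ``24`` → ``Y``.  Tokens 25/26 (PLINK XY/MT ambiguity) are rejected with a
    hard error rather than guessed at.
    """
    if token is None:
        return None
    t = str(token).strip().upper()
    if t.startswith("CHR"):
        t = t[3:]
    if t in ("", "NAN", "NONE", "NA"):
        return None
    if t == "M":
        t = "MT"
    elif t == "23":
        t = "X"
    elif t == "24":
        t = "Y"
    elif t in ("25", "26"):
        raise SumstatsError(
            f"ambiguous numeric chromosome code {t!r} (PLINK XY/MT); "
            "recode to X/Y/MT explicitly"
        )
    return t if t in VALID_CHROMS else None


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True when the unordered allele pair is A/T or C/G (palindromic)."""
    pair = {str(a1).upper(), str(a2).upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass(frozen=True)
class ReferenceVariant:
    """One catalogued variant site."""

    rsid: str
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        if not self.ref or not all(self.alts):
            raise ValueError(f"{self.rsid}: empty allele")
        if self.ref in self.alts:
            raise ValueError(f"{self.rsid}: ref allele repeated in alts")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


class ReferenceBackend:
    """In-memory variant catalogue with rsID and positional views."""

    def __init__(self, variants: Iterable[ReferenceVariant], build: str = "GRCh37"):
        if build not in ("GRCh37", "GRCh38"):
            raise ValueError(f"unknown genome build {build!r}")
        self.build = build
        self.by_rsid: dict[str, ReferenceVariant] = {}
        self.by_position: dict[tuple[str, int], list[ReferenceVariant]] = {}
        for v in variants:
            if v.rsid in self.by_rsid:
                raise ValueError(f"duplicate rsid in catalogue: {v.rsid}")
            self.by_rsid[v.rsid] = v
            self.by_position.setdefault((v.chrom, v.pos), []).append(v)

    def __len__(self) -> int:
        return len(self.by_rsid)

    @property
    def variants(self) -> list[ReferenceVariant]:
        return list(self.by_rsid.values())

    # -- queries ---------------------------------------------------------
    def query_by_rsid(self, rsids: Iterable[str]) -> dict[str, ReferenceVariant]:
        out = {}
        for r in rsids:
            v = self.by_rsid.get(r)
            if v is not None:
                out[r] = v
        return out

    def query_by_position(
        self, loci: Iterable[tuple[str, int]]
    ) -> dict[tuple[str, int], list[ReferenceVariant]]:
        return {
            (chrom, pos): list(self.by_position.get((str(chrom), int(pos)), []))
            for chrom, pos in loci
        }

    # -- serialization ---------------------------------------------------
    def to_catalogue(self, path: str | os.PathLike) -> str:
        """Write a sorted, tab-delimited catalogue (rsid chrom pos ref alts)."""
        path = os.fspath(path)
        order = {c: i for i, c in enumerate(AUTOSOMES + ["X", "Y", "MT"])}
        rows = sorted(
            self.by_rsid.values(), key=lambda v: (order.get(v.chrom, 99), v.pos)
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"##build={self.build}\n")
            fh.write("#rsid\tchrom\tpos\tref\talts\n")
            for v in rows:
                fh.write(f"{v.rsid}\t{v.chrom}\t{v.pos}\t{v.ref}\t{','.join(v.alts)}\n")
        return path

    @classmethod
    def from_catalogue(
        cls, path: str | os.PathLike, build: Optional[str] = None
    ) -> "ReferenceBackend":
        path = os.fspath(path)
        variants = []
        file_build = None
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##build="):
                    file_build = line.split("=", 1)[1].strip()
                    continue
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 5:
                    raise FormatError(f"{path}: malformed catalogue line: {line!r}")
                rsid, chrom, pos, ref, alts = fields
                variants.append(
                    ReferenceVariant(
                        rsid, chrom, int(pos), ref, tuple(alts.split(","))
                    )
                )
        return cls(variants, build=build or file_build or "GRCh37")

    @classmethod
    def from_dbsnp_vcf(
        cls, path: str | os.PathLike, build: str = "GRCh37"
    ) -> "ReferenceBackend":
        """Adapter loading a dbSNP-style sites VCF into the catalogue.

        Provided for real-data use; the bundled tests rely exclusively on
        the synthetic generator.
        """
        import pysam

        variants = []
        with pysam.VariantFile(os.fspath(path)) as vf:
            for rec in vf:
                chrom = normalize_chrom(rec.chrom)
                if chrom is None or rec.id is None or not rec.alts:
                    continue
                variants.append(
                    ReferenceVariant(
                        rec.id,
                        chrom,
                        rec.pos,
                        rec.ref.upper(),
                        tuple(a.upper() for a in rec.alts),
                    )
                )
        return cls(variants, build=build)


# module-level wrappers matching the functional interface used elsewhere
def query_by_rsid(
    backend: ReferenceBackend, rsids: Iterable[str]
) -> dict[str, ReferenceVariant]:
    return backend.query_by_rsid(rsids)


def query_by_position(
    backend: ReferenceBackend, loci: Iterable[tuple[str, int]]
) -> dict[tuple[str, int], list[ReferenceVariant]]:
    return backend.query_by_position(loci)


def make_synthetic_reference(
    seed: int,
    n_variants: int = 5000,
    chroms: Optional[Sequence[str]] = None,
    nonbiallelic_frac: float = 0.05,
    ambiguous_frac: float = 0.15,
    position_collisions: int = 0,
    build: str = "GRCh37",
) -> ReferenceBackend:
    """Generate a deterministic synthetic variant catalogue.

    Emulates the shape of a dbSNP slice: unique rsIDs, strictly increasing
    positions per chromosome, SNV alleles with ``ambiguous_frac`` of the
    biallelic sites palindromic (A/T or C/G) and ``nonbiallelic_frac``
    multi-allelic.  ``position_collisions`` adds that many extra variants
    sharing a position with an existing one (distinct rsID and alleles), so
    positional-ambiguity handling is exercisable.  Fully determined by
    ``seed``.
    """
    if not (0 <= nonbiallelic_frac <= 1 and 0 <= ambiguous_frac <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if n_variants > 5_000_000:
        raise ValueError("n_variants exceeds the synthetic position space")
    rng = np.random.default_rng(seed)
    if chroms is None:
        chroms = AUTOSOMES + ["X", "Y", "MT"]
    chroms = [str(c) for c in chroms]
    bad = [c for c in chroms if c not in VALID_CHROMS]
    if bad:
        raise ValueError(f"unknown chromosomes requested: {bad}")

    # allocate counts: special chromosomes get a small fixed share so
    # non-autosomal behaviour is always exercisable
    special = [c for c in chroms if c in ("X", "Y", "MT")]
    autosomal = [c for c in chroms if c not in ("X", "Y", "MT")]
    counts: dict[str, int] = {c: 0 for c in chroms}
    n_special_each = 0
    if special and autosomal:
        n_special_each = max(1, int(0.02 * n_variants)) if n_variants >= 20 else 1
        n_special_each = min(n_special_each, n_variants // (len(special) + 1))
    remaining = n_variants - n_special_each * len(special)
    for c in special:
        counts[c] = n_special_each
    pool = autosomal if autosomal else special
    base, extra = divmod(remaining, len(pool))
    for i, c in enumerate(pool):
        counts[c] += base + (1 if i < extra else 0)

    rs_numbers = rng.permutation(np.arange(10_000, 10_000 + 10 * n_variants))[
        : n_variants + position_collisions
    ]
    bases = np.array(["A", "C", "G", "T"])
    variants: list[ReferenceVariant] = []
    k = 0
    for chrom in chroms:
        n = counts[chrom]
        if n == 0:
            continue
        gaps = rng.integers(1, 1000, size=n)
        positions = np.cumsum(gaps) + 10_000
        for pos in positions:
            ref = str(rng.choice(bases))
            if rng.random() < ambiguous_frac:
                alt1 = _COMPLEMENT[ref]
            else:
                others = [b for b in bases if b != ref and b != _COMPLEMENT[ref]]
                alt1 = str(rng.choice(others))
            alts = (alt1,)
            if rng.random() < nonbiallelic_frac:
                rest = [b for b in bases if b not in (ref, alt1)]
                alts = (alt1, str(rng.choice(rest)))
            variants.append(
                ReferenceVariant(f"rs{rs_numbers[k]}", chrom, int(pos), ref, alts)
            )
            k += 1

    # extra variants colliding positionally with existing biallelic sites
    biallelic = [v for v in variants if v.is_biallelic]
    if position_collisions > len(biallelic):
        raise ValueError("not enough sites to host the requested collisions")
    targets = rng.choice(len(biallelic), size=position_collisions, replace=False)
    for t in targets:
        host = biallelic[int(t)]
        taken = {host.ref} | set(host.alts)
        ref_choices = [b for b in bases if b not in taken]
        if not ref_choices:
            ref_choices = [b for b in bases if b != host.ref]
        ref = str(rng.choice(ref_choices))
        alt_choices = [
            b for b in bases if b != ref and b != _COMPLEMENT[ref] and b not in taken
        ] or [b for b in bases if b != ref and b != _COMPLEMENT[ref]]
        alt = str(rng.choice(alt_choices))
        variants.append(
            ReferenceVariant(f"rs{rs_numbers[k]}", host.chrom, host.pos, ref, (alt,))
        )
        k += 1

    return ReferenceBackend(variants, build=build)
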