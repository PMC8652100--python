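# Methods

## Scope and model

`gwasmunge` standardizes GWAS summary statistics: one row per variant with
canonical columns SNP, CHR, BP, A1, A2, P and optional effect/metadata
columns (Z, OR, BETA, LOG_ODDS, SIGNED_SUMSTAT, SE, FRQ, INFO, N, N_CAS,
N_CON, NSTUDY). The orientation convention is fixed throughout: A1 is the
non-effect (reference) allele, A2 the effect (alternative) allele, and FRQ
is the frequency of A2. This matches GWAS-VCF, where REF maps to A1, ALT
to A2, and the per-sample fields ES/SE/LP/AF/SS map to
BETA/SE/P(=10^−LP)/FRQ/N.

The canonical in-memory container is a pandas DataFrame; `RawTable` is a
thin wrapper that preserves the observed header strings byte-for-byte so
the audit report can name them.

## Reference backend

Reference-dependent checks (imputation, on-reference enforcement,
biallelic filtering, allele flipping) run against a minimal contract: a
catalogue of variants (`rsid, chrom, pos, ref, alts`) with consistent
rsID- and position-keyed views, for one genome build (GRCh37 or GRCh38 —
the build is a required user input, not inferred). Only variant-site
alleles are stored; no genomic sequence is needed because all comparisons
are between allele strings. Flip comparisons therefore use catalogue
alleles rather than sequence context, which is equivalent for SNVs.
Adapters load a catalogue from the plain-text serialized form or from a
dbSNP-style sites VCF; the test-suite uses the synthetic generator
exclusively, so nothing needs downloading.

Chromosomes are bare tokens `1`–`22`, `X`, `Y`, `MT` internally; `chr`
prefixes, `M`, and the PLINK numeric codes 23/24 are normalized on ingest.
Codes 25/26 (PLINK XY/MT ambiguity across tool generations) are rejected
with a hard error rather than silently guessed; any other unrecognizable
token becomes a missing value and the row falls to the missing-data check.
Positions are 1-based (VCF convention).

## Check order and semantics

Checks run in one fixed order (ingest → headers → traits → ID
normalization → composite splits → imputation → validation → missing-data
→ duplicate columns → small P → N outliers → rsID validity → row dedup by
rsID then position → on-reference → INFO → strand-ambiguity → biallelic →
flip → non-autosomal → effect/SE sanity → report). Imputation precedes
the missing-data drop, which is the only coherent sequence: a recoverable
blank must get its chance before row removal. Decisions worth recording:

- **Header synonyms.** The bundled dictionary has 276 unique
  case-insensitive mappings onto the 18 canonical names, assembled from
  common consortium outputs (PLINK/PLINK2, METAL, SAIGE, BOLT-LMM,
  SNPTEST, GWAS-SSF, daner, …). No synonym maps to two canonical names;
  every canonical name maps to itself, making canonicalization idempotent.
  Users can merge extra mappings but not contradict bundled ones.
- **Duplicate columns** keep the first occurrence in document order —
  deterministic and lossless for the retained column. Multiple signed
  columns (e.g. BETA and Z) are all retained; the requirement is at least
  one, and arbitration would discard information.
- **Trait suffixes** are recognized with separators `.`, `_`, `-` after a
  stem that maps to a canonical name, and only when the same stem occurs
  with two or more distinct suffixes — a lone `FREQ_XYZ` is not a trait.
- **Composite splits** fire only when every non-empty value in a column
  matches the same pattern; allele fields must match `^[ACGT]+$` so
  annotation columns (`gene/intron`) cannot false-positive. A mix of
  2-field and 4-field values is a hard error. Splits never overwrite an
  existing non-empty canonical column. The 4-field order is CHR:BP:A2:A1.
- **Small p-values.** The boundary is 5e-324, the smallest positive
  (subnormal) IEEE-754 double, with strict "lower than" semantics: a
  textual value that underflows to zero on parse but has a nonzero
  mantissa digit is below the boundary; `5e-324` itself survives. Such
  values are set to 0 by default (configurable to drop instead). A literal
  input `0` is retained but flagged — silently rewriting it would hide a
  data problem. P outside [0, 1] is a hard error, not a row drop: it
  signals a mis-mapped column, not a bad variant. Non-numeric p-values
  drop their rows.
- **N outliers.** N is coerced by rounding half away from zero
  (deterministic, locale-free); rows with N ≤ 0 are dropped; rows with
  N > mean + k·sd are dropped, k = 5 by default. Mean and sd (ddof = 1)
  are computed once on the coerced column before any dropping — no
  iterative re-screening, so the result is order-independent.
- **rsID validity** (`^rs\d+$`) only flags: other identifiers remain
  usable, but are excluded from rsID-keyed reference lookups.
- **On-reference enforcement** rescues unknown rsIDs positionally: if the
  (CHR, BP) locus carries a catalogued variant whose allele set contains
  the row's alleles, the rsID is corrected to the catalogue's; otherwise
  the row is dropped with a recorded reason.
- **Strand-ambiguous** variants (allele pair A/T or C/G, its own reverse
  complement) are removed using the row's own alleles — ambiguity is
  orientation-independent, so no reference is needed. There is no
  strand-flip rescue (complementing a mismatching pair to match the
  reference): ambiguous variants are removed and non-ambiguous
  orientation mismatches dropped, never complemented.
- **Allele flipping** leaves rows with A1 = catalogue ref untouched; swaps
  and transforms rows with A1 = alt, A2 = ref (BETA/Z/LOG_ODDS/
  SIGNED_SUMSTAT negated, OR inverted, FRQ complemented, SE/P/N
  unchanged); drops rows matching neither orientation (a distinct reason
  records OR = 0 rows, where 1/OR is undefined). Rows absent from the
  catalogue pass through unflipped — they were already handled by the
  on-reference check, and dropping them twice would double-count. The
  operation is an involution on synthetically flipped data and idempotent
  (after one pass every retained A1 equals the catalogue ref, so a second
  pass flips nothing).
- **Zero effects.** A signed statistic exactly 0 drops the row; OR
  exactly 1 (the odds-ratio null) is *not* treated as zero-effect, but OR
  exactly 0 is. SE must be strictly positive.
- **Missing data** in unmapped (non-canonical) columns never drops a row;
  only recognized columns count.

The report satisfies conservation (`rows_in == rows_out + Σ drops`) and is
verified before the pipeline returns. LDSC readiness is a write-time
property: output columns SNP, A1, A2, Z, N, with Z taken from the Z
column, else BETA/SE, else sign(signed statistic)·|Φ⁻¹(P/2)|.

## Synthetic data

The synthetic reference emulates a dbSNP slice: unique rsIDs, strictly
increasing positions per chromosome (uniform gaps of 1–999 bp), SNV
alleles with 15% of biallelic sites palindromic (A/T or C/G; dbSNP-scale
catalogues run somewhat higher, but the exact fraction only scales one
drop count) and 5% multi-allelic; X, Y and MT each receive a 2% share so
non-autosomal behaviour is always exercisable, and an optional number of
positional collision pairs exercises locus-ambiguity handling.

The fixture generator draws clean variants (biallelic, non-ambiguous,
autosomal, collision-free) and applies counted, per-row-disjoint
corruptions: missing SNP/CHR+BP/alleles, reversed allele orientation with
correspondingly negated BETA/Z, inverted OR and complemented FRQ, bare
integer rsIDs, `CHR:BP` hybrid IDs, duplicated rows (appended, so
keep-first is well defined), positional duplicates from collision pairs,
sub-threshold INFO, `1e-350` p-value strings, 50× sample-size outliers,
zero effects, negative SEs, X/Y/MT rows, palindromic and multi-allelic
variants, fabricated off-catalogue variants, and stale rsIDs at correct
positions. Clean statistics are BETA ~ N(0, 0.1), SE ~ U(0.05, 0.2),
P ~ U(1e-8, 0.99), FRQ ~ U(0.05, 0.95), INFO ~ U(0.9, 1.0), N ≈ 50 000 ± 50
(tight, so no clean row ever trips the outlier bound), with case/control
counts splitting N roughly in half.

Because each corruption has a single unambiguous pipeline outcome, the
generator can pre-compute the expected per-check drop/impute/modify counts
under default settings; the test-suite and acceptance script compare the
pipeline's audit report against this ground truth *exactly*. For the
sample-size outlier the generator verifies its planted value against the
same mean + 5·sd rule on the full N vector at generation time, so the
truth is computed, not assumed. For dialects that omit coordinate columns
(e.g. the LDSC-style preset), a clean fixture still passes with zero
drops, but coordinate imputation is then inherent (two cells per row), so
the zero-imputation invariant applies only to dialects carrying all five
identifier columns; corruptions that such a dialect cannot express are
rejected as contradictory at generation time.

What the generator does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, indels, genuine genotyping batch effects, or
build mismatches. Passing tests therefore demonstrate the correctness of
the standardization logic, not robustness to every pathology of real
consortium files.

## Numerical choices

- Delimiter sniffing decompresses a preview and picks the candidate (tab,
  comma, whitespace-run) splitting header and first data line into the
  same field count, preferring more fields, tab first on ties; bgzip is
  distinguished from plain gzip by the `BC` extra subfield in the gzip
  header. Detection never uses the file extension.
- "Space-delimited" means any whitespace run, since real files mix spaces
  and tabs.
- Tabular output is gzip (universally readable) rather than bgzip;
  GWAS-VCF output is bgzip via htslib. VCF FORMAT floats are serialized
  with ~6 significant digits, so a VCF round trip preserves effect sizes
  to ~1e-6 relative and p-values (through LP) to ~1e-5 relative — the
  round-trip tests assert at those tolerances.
- Problem sizes in the test-suite and acceptance script (catalogues of
  3000–4000 variants, tables of 40–200 rows) are chosen so every variant
  class and corruption is represented many times over while the whole
  battery completes in seconds; all counts scale linearly and nothing in
  the logic depends on table size.

## Known limitations

Genome-build inference, liftover, multi-trait VCF emission, tabix
indexing, strand-flip rescue and FRQ-based MAF filtering are out of scope.
The on-reference and biallelic checks silently pass rows they cannot
resolve when the catalogue lacks the variant; with a sparse catalogue the
pipeline is accordingly permissive.
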