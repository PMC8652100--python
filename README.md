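# gwasmunge

Standardization and quality control of GWAS summary statistics.

## The problem

Genome-wide association studies distribute their results as per-variant
summary statistics — effect size, standard error, p-value, allele
frequency, sample size — but the files come in dozens of mutually
incompatible layouts: different header names, composite `CHR:BP:A2:A1`
identifier columns, mixed rsID conventions, inconsistent effect-allele
orientation. Downstream tools (LDSC, MAGMA, meta-analysis pipelines)
require one canonical, quality-controlled format.

`gwasmunge` ingests a summary-statistics file in delimited text
(`.tsv`/`.txt`/`.csv`, plain, gzip or bgzip) or GWAS-VCF, canonicalizes the
headers through a dictionary of 276 synonyms, runs a battery of 30 QC
checks against a reference variant catalogue, and writes standardized
tabular, GWAS-VCF or LDSC-ready output plus a full audit report of every
row dropped (with reason) and every cell imputed.

Conventions: **A1 is the non-effect (reference) allele, A2 the effect
(alternative) allele**, matching GWAS-VCF where REF↔A1 and ALT↔A2. FRQ is
the frequency of A2.

## The checks

The pipeline runs in fixed order: format sniffing → header synonym
canonicalization → multi-trait selection → SNP-ID normalization
(`12345`→`rs12345`, `1:1000` hybrids resolved) → composite column splits →
imputation of missing CHR/BP, rsID and alleles from the reference →
required/signed column validation → missing-data removal → duplicate
columns → sub-representable p-values (below 5e-324) → sample-size outliers
(beyond mean + 5·sd) → rsID validity → duplicate rows by rsID and by
position → on-reference enforcement with positional rescue → INFO filter
(< 0.9) → strand-ambiguous (A/T, C/G) removal → non-biallelic removal →
**allele flipping** → X/Y/MT removal → zero-effect and non-positive-SE
removal → audit report.

Allele flipping is the core harmonization step: for each variant, if A1
does not match the catalogue reference allele but the orientation is
reversed (A1 = alt, A2 = ref), the alleles are swapped and the statistics
transformed —

```
BETA → −BETA    Z → −Z    LOG_ODDS → −LOG_ODDS    SIGNED_SUMSTAT → −SIGNED_SUMSTAT
OR → 1/OR       FRQ → 1−FRQ        (SE, P, N unchanged)
```

— giving consistent directionality of allelic effects across studies.
Rows matching neither orientation are dropped with a recorded reason.

## Worked example

Generate a synthetic reference catalogue plus a corrupted 100-row fixture,
then standardize it:

```
$ gwasmunge make-fixture --seed 7 --n-variants 2000 --n-rows 100 \
      --corrupt flipped=10 --corrupt low_info=5 --corrupt missing_snp=3 --out-dir .
catalogue.tsv
sumstats.tsv
truth.json

$ gwasmunge format sumstats.tsv --ref-catalogue catalogue.tsv --report-dir qc_report
INFO gwasmunge: reference catalogue: 2000 variants (GRCh37)
INFO gwasmunge: input dialect: FormatDescriptor(container='delimited', delimiter='tab', compression='none')
INFO gwasmunge: 100 rows in, 95 rows out, 5 dropped, 3 cells imputed
INFO gwasmunge: audit report written to qc_report
sumstats.standardized.tsv.gz
```

The 5 dropped rows are the sub-threshold INFO corruptions (the audit
report names each one: `rs17389  23  INFO 0.2365 < 0.9` …), the 3 imputed
cells are the blanked rsIDs recovered positionally from the catalogue, and
the 10 orientation-flipped rows were flipped back (`qc_report/qc_summary.tsv`,
check 26). The output is tab-delimited, canonically ordered and typed:

```
SNP      CHR  BP     A1  A2  P         BETA      SE        FRQ       INFO    N
rs12300  7    41941  G   A   0.160874  0.127218  0.129797  0.282429  0.9678  50043
```

`--format ldsc` instead writes exactly the columns LDSC consumes
(`SNP A1 A2 Z N`, with Z = BETA/SE when no Z column is present);
`--format vcf` writes a GWAS-VCF with per-sample ES/SE/LP/AF/SS fields.
Every QC switch is a flag (`--info-threshold`, `--n-std`,
`--keep-chr-xym`, `--no-strand-ambig-filter`, `--no-allele-flip`, …).

The same pipeline is available as a library:

```python
import gwasmunge as gm
raw = gm.read_sumstats("sumstats.tsv")
backend = gm.ReferenceBackend.from_catalogue("catalogue.tsv")
table, report = gm.run_pipeline(raw, gm.QCConfig(), backend)   # a DataFrame + audit
gm.write_output(table, "out.tsv.gz")
```

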