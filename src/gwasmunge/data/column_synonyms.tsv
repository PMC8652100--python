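synonym	canonical
SNP	SNP
SNPID	SNP
SNP_ID	SNP
SNP.ID	SNP
SNP_NAME	SNP
SNPNAME	SNP
MARKERNAME	SNP
MARKER_NAME	SNP
MARKER	SNP
MARKER_ID	SNP
RSID	SNP
RS_ID	SNP
RSIDS	SNP
RS_NUMBER	SNP
RS_NUMBERS	SNP
RSNUMBER	SNP
RS	SNP
ID	SNP
VARIANT_ID	SNP
VARIANTID	SNP
VARIANT	SNP
DBSNP_ID	SNP
DBSNPID	SNP
DBSNP	SNP
CHR	CHR
CHROMOSOME	CHR
CHROM	CHR
CHR_ID	CHR
CHR_NAME	CHR
CHR_NUM	CHR
CHROMOSOME_NUMBER	CHR
#CHROM	CHR
#CHR	CHR
HG18CHR	CHR
HG19CHR	CHR
HG38CHR	CHR
CHR.HG19	CHR
CHR_HG19	CHR
CHR_HG38	CHR
CHR_B37	CHR
CHR_B38	CHR
SCAFFOLD	CHR
BP	BP
BASE_PAIR	BP
BASEPAIR	BP
BASE_PAIR_LOCATION	BP
POS	BP
POSITION	BP
POSITIONS	BP
PHYSPOS	BP
BP_HG19	BP
BP_HG38	BP
POS_HG19	BP
POS_HG38	BP
POS_B37	BP
POS_B38	BP
POS_GRCH37	BP
POS_GRCH38	BP
BP.GRCH37	BP
BP.GRCH38	BP
LOCATION	BP
LOC	BP
A1	A1
ALLELE1	A1
ALLELE_1	A1
ALLELE.1	A1
REF	A1
REFERENCE_ALLELE	A1
REF_ALLELE	A1
REFERENCE	A1
NON_EFFECT_ALLELE	A1
NONEFFECT_ALLELE	A1
NON_EFFECT	A1
NON_EFF_ALLELE	A1
OTHER_ALLELE	A1
OTHERALLELE	A1
NEA	A1
NON_RISK_ALLELE	A1
MAJOR_ALLELE	A1
ALLELEA	A1
ALLELE_A	A1
NON_CODED_ALLELE	A1
A2	A2
ALLELE2	A2
ALLELE_2	A2
ALLELE.2	A2
ALT	A2
ALTERNATIVE_ALLELE	A2
ALT_ALLELE	A2
ALTERNATE_ALLELE	A2
EFFECT_ALLELE	A2
EFF_ALLELE	A2
EFFECT_ALL	A2
EA	A2
RISK_ALLELE	A2
MINOR_ALLELE	A2
INC_ALLELE	A2
TESTED_ALLELE	A2
TEST_ALLELE	A2
CODED_ALLELE	A2
ALLELEB	A2
ALLELE_B	A2
P	P
PVAL	P
PVALUE	P
P_VALUE	P
P.VALUE	P
P-VALUE	P
P_VAL	P
P.VAL	P
GC_PVALUE	P
PVAL_GC	P
P_DGC	P
P_GC	P
P_BOLT_LMM	P
P_BOLT_LMM_INF	P
P_LINREG	P
P_SAIGE	P
P_SCORE	P
SCORE_P	P
WALD_P	P
LRT_P	P
FREQUENTIST_ADD_PVALUE	P
MTAG_PVAL	P
ALL_INV_VAR_META_P	P
Z	Z
ZSCORE	Z
Z_SCORE	Z
Z.SCORE	Z
ZSTAT	Z
Z_STAT	Z
ZSTATISTIC	Z
Z_STATISTIC	Z
GC_ZSCORE	Z
MTAG_Z	Z
ZVALUE	Z
Z_VALUE	Z
OR	OR
ODDS_RATIO	OR
ODDSRATIO	OR
ODDS-RATIO	OR
EXP_B	OR
EXP(B)	OR
BETA	BETA
B	BETA
EFFECT	BETA
EFFECTS	BETA
EFFECT_SIZE	BETA
EFFECTSIZE	BETA
EFFECT_ESTIMATE	BETA
EST	BETA
ESTIMATE	BETA
BETA1	BETA
BETA_SNP	BETA
GWAS_BETA	BETA
MTAG_BETA	BETA
ALL_INV_VAR_META_BETA	BETA
LOG_ODDS	LOG_ODDS
LOGOR	LOG_ODDS
LOG_OR	LOG_ODDS
LOG.OR	LOG_ODDS
LOG(OR)	LOG_ODDS
LNOR	LOG_ODDS
LOG_ODDS_RATIO	LOG_ODDS
SIGNED_SUMSTAT	SIGNED_SUMSTAT
SIGNED_SUMSTATS	SIGNED_SUMSTAT
SIGNED_STATISTIC	SIGNED_SUMSTAT
SIGNED_STAT	SIGNED_SUMSTAT
N	N
N_TOTAL	N
NTOTAL	N
TOTAL_N	N
N_SAMPLES	N
NSAMPLES	N
SAMPLESIZE	N
SAMPLE_SIZE	N
SAMPLE_SIZES	N
TOTALSAMPLESIZE	N
TOTAL_SAMPLE_SIZE	N
N_ANALYZED	N
NCOMPLETESAMPLES	N
N_SUM	N
NEFF	N
N_EFF	N
N_EFFECTIVE	N
OBS_CT	N
ALL_TOTAL	N
NMISS	N
N_COMPLETE_SAMPLES	N
N_CAS	N_CAS
NCAS	N_CAS
N_CASE	N_CAS
NCASE	N_CAS
N_CASES	N_CAS
NCASES	N_CAS
CASES	N_CAS
CASES_N	N_CAS
N_CASES_TOTAL	N_CAS
N_AFF	N_CAS
N_AFFECTED	N_CAS
NCA	N_CAS
N_CON	N_CON
NCON	N_CON
N_CONTROL	N_CON
NCONTROL	N_CON
N_CONTROLS	N_CON
NCONTROLS	N_CON
CONTROLS	N_CON
CONTROLS_N	N_CON
N_CONTROLS_TOTAL	N_CON
N_UNAFF	N_CON
N_UNAFFECTED	N_CON
NCO	N_CON
NSTUDY	NSTUDY
N_STUDY	NSTUDY
NSTUDIES	NSTUDY
N_STUDIES	NSTUDY
NUMBER_OF_STUDIES	NSTUDY
INFO	INFO
INFO_SCORE	INFO
INFOSCORE	INFO
IMPINFO	INFO
IMP_INFO	INFO
IMPUTATION_INFO	INFO
IMPUTATION_QUALITY	INFO
IMPUTATION_SCORE	INFO
IMPUTATIONINFO	INFO
IMPQUALITY	INFO
RSQ	INFO
RSQR	INFO
R2	INFO
MACH_R2	INFO
MININFO	INFO
MIN_INFO	INFO
FRQ	FRQ
FREQ	FRQ
FRQ_U	FRQ
F_U	FRQ
FREQ_U	FRQ
MAF	FRQ
AF	FRQ
EAF	FRQ
A2FREQ	FRQ
A2FRQ	FRQ
ALT_FREQ	FRQ
ALTFREQ	FRQ
AF_ALT	FRQ
FREQ_ALT	FRQ
AF_ALLELE2	FRQ
FREQ1	FRQ
EFFECT_ALLELE_FREQ	FRQ
EFFECT_ALLELE_FREQUENCY	FRQ
FREQ_TESTED_ALLELE	FRQ
FREQ_EFFECT_ALLELE	FRQ
CODED_ALLELE_FREQUENCY	FRQ
MINOR_AF	FRQ
MINOR_ALLELE_FREQ	FRQ
MINOR_ALLELE_FREQUENCY	FRQ
FREQ_A2	FRQ
FRQ_A2	FRQ
SE	SE
STDERR	SE
STD_ERR	SE
STDER	SE
STANDARD_ERROR	SE
STD_ERROR	SE
SEBETA	SE
SE_BETA	SE
BETA_SE	SE
STDERR_BETA	SE
SE_OF_BETA	SE
STANDARD_ERROR_OF_BETA	SE
LOG_ODDS_SE	SE
SE_LOG_ODDS	SE
ALL_INV_VAR_META_SEBETA	SE
SE.2GC	SE
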