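{
  "canonical": {
    "composite_id": false,
    "columns": {
      "SNP": "SNP", "CHR": "CHR", "BP": "BP", "A1": "A1", "A2": "A2",
      "BETA": "BETA", "SE": "SE", "P": "P", "FRQ": "FRQ", "INFO": "INFO", "N": "N"
    }
  },
  "ldsc": {
    "composite_id": false,
    "columns": {"SNP": "snp", "A1": "a1", "A2": "a2", "Z": "z", "N": "n", "P": "p"}
  },
  "plink_assoc": {
    "composite_id": false,
    "columns": {
      "SNP": "SNP", "CHR": "CHR", "BP": "BP", "A1": "A1", "A2": "A2",
      "FRQ": "FRQ", "OR": "OR", "SE": "SE", "P": "P", "N": "NMISS"
    }
  },
  "plink2_glm": {
    "composite_id": false,
    "columns": {
      "SNP": "ID", "CHR": "#CHROM", "BP": "POS", "A1": "REF", "A2": "ALT",
      "FRQ": "ALT_FREQ", "BETA": "BETA", "SE": "SE", "P": "P",
      "N": "OBS_CT", "INFO": "MACH_R2"
    }
  },
  "metal": {
    "composite_id": false,
    "columns": {
      "SNP": "MarkerName", "CHR": "Chromosome", "BP": "Position",
      "A1": "Allele1", "A2": "Allele2", "FRQ": "Freq1", "BETA": "Effect",
      "SE": "StdErr", "P": "P-value", "N": "TotalSampleSize"
    }
  },
  "daner": {
    "composite_id": false,
    "columns": {
      "SNP": "SNP", "CHR": "CHR", "BP": "BP", "A1": "A1", "A2": "A2",
      "FRQ": "FRQ_U", "INFO": "INFO", "OR": "OR", "SE": "SE", "P": "P",
      "N_CAS": "Nca", "N_CON": "Nco"
    }
  },
  "saige": {
    "composite_id": false,
    "columns": {
      "SNP": "SNPID", "CHR": "CHR", "BP": "POS", "A1": "Allele1", "A2": "Allele2",
      "FRQ": "AF_Allele2", "BETA": "BETA", "SE": "SE", "P": "p.value",
      "N": "N", "INFO": "imputationInfo"
    }
  },
  "bolt_lmm": {
    "composite_id": false,
    "columns": {
      "SNP": "SNP", "CHR": "CHR", "BP": "BP", "A1": "ALLELE1", "A2": "ALLELE2",
      "INFO": "INFO", "BETA": "BETA", "SE": "SE", "P": "P_BOLT_LMM", "N": "N"
    }
  },
  "snptest": {
    "composite_id": false,
    "columns": {
      "SNP": "rsid", "CHR": "chromosome", "BP": "position",
      "A1": "alleleA", "A2": "alleleB", "INFO": "info", "BETA": "beta",
      "SE": "se", "P": "frequentist_add_pvalue", "N": "all_total"
    }
  },
  "gwas_ssf": {
    "composite_id": false,
    "columns": {
      "SNP": "variant_id", "CHR": "chromosome", "BP": "base_pair_location",
      "A1": "other_allele", "A2": "effect_allele", "BETA": "beta",
      "SE": "standard_error", "P": "p_value",
      "FRQ": "effect_allele_frequency", "N": "n"
    }
  },
  "gcta_ma": {
    "composite_id": false,
    "columns": {
      "SNP": "SNP", "CHR": "CHR", "BP": "BP", "A1": "A1", "A2": "A2",
      "FRQ": "FREQ", "BETA": "b", "SE": "SE", "P": "P", "N": "N"
    }
  },
  "composite_id": {
    "composite_id": true,
    "columns": {
      "SNP": "variant", "BETA": "beta", "SE": "se", "P": "pval",
      "FRQ": "minor_AF", "N": "n_complete_samples"
    }
  }
}
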