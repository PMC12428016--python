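{
  "record_id": "OR896919",
  "species": "Potamotrygon leopoldi",
  "genome_length_bp": 17504,
  "gene_counts": {"PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 1},
  "strand_counts": {"heavy": 28, "light": 9},
  "composition_percent": {
    "whole_genome": {"A": 32.32, "T": 24.41, "C": 12.84, "G": 30.42},
    "rRNA": {"A": 35.63, "T": 21.12, "C": 25.98, "G": 17.27},
    "control_region": {"A": 33.55, "T": 29.92, "C": 24.30, "G": 12.24}
  },
  "at_content_percent": {"whole_genome": 56.73, "rRNA": 56.75},
  "reported_skews": {"at_skew": 0.13, "gc_skew": -0.40},
  "trna_length_range_bp": [67, 75],
  "pcg_total_length_bp": 11444,
  "pcg_length_extremes_bp": {"ATP8": 168, "ND5": 1836},
  "pcg_fraction_of_genome_percent": 64.70,
  "total_codons": 3811,
  "enc_average": 57.65,
  "cr_tandem_repeat_unit_lengths_bp": [128, 20],
  "trf_min_alignment_score": 30,
  "positive_selection_site_counts": {"ND1": 1, "ND4": 1, "ND5": 3, "COX1": 6, "COX2": 3},
  "comparison_accessions": {
    "Potamotrygon falkneri": "MZ203140",
    "Potamotrygon orbignyi": "MN178254",
    "Potamotrygon motoro": "KF709642",
    "Potamotrygon magdalenae": "KX151183",
    "Callorhinchus milii": "HM137147"
  }
}
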