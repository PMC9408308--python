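[
  {
    "term_id": "substitution",
    "name": "substitution",
    "definition": "Replacement of one nucleotide by another in an mRNA coding region.",
    "level": "RNA",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  },
  {
    "term_id": "transition",
    "name": "transition",
    "definition": "Substitution replacing a purine with the other purine or a pyrimidine with the other pyrimidine; describes the chemical change of the base group.",
    "level": "RNA",
    "parent": "substitution",
    "provenance": "ontology figure; code not transcribed",
    "external_code": null
  },
  {
    "term_id": "transversion",
    "name": "transversion",
    "definition": "Substitution replacing a purine with a pyrimidine or vice versa; describes the chemical change of the base group.",
    "level": "RNA",
    "parent": "substitution",
    "provenance": "ontology figure; code not transcribed",
    "external_code": null
  },
  {
    "term_id": "missense",
    "name": "missense",
    "definition": "Coding-region substitution that changes the encoded amino acid.",
    "level": "RNA",
    "parent": "substitution",
    "provenance": "ontology figure; code not transcribed",
    "external_code": null
  },
  {
    "term_id": "nonsense",
    "name": "nonsense",
    "definition": "Coding-region substitution that introduces a stop codon at the variant site.",
    "level": "RNA",
    "parent": "substitution",
    "provenance": "ontology figure; code not transcribed",
    "external_code": null
  },
  {
    "term_id": "synonymous",
    "name": "synonymous",
    "definition": "Coding-region substitution that replaces a codon with another codon for the same amino acid and has no demonstrated effect on expression or protein.",
    "level": "RNA",
    "parent": "substitution",
    "provenance": "ontology figure; code not transcribed",
    "external_code": null
  },
  {
    "term_id": "unsense",
    "name": "unsense",
    "definition": "Coding-region substitution that affects gene expression and protein production without introducing a stop codon at the variant site, e.g. by impairing splicing, splicing regulation or miRNA-mediated regulation.",
    "level": "RNA",
    "parent": "substitution",
    "provenance": "ontology figure; code not transcribed",
    "external_code": null
  },
  {
    "term_id": "mech_tf_binding",
    "name": "TF_BINDING",
    "definition": "Alteration of a transcription-factor binding site overlapping the coding sequence (dual-use codon), affecting transcription.",
    "level": "DNA",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  },
  {
    "term_id": "mech_splice_site",
    "name": "SPLICE_SITE",
    "definition": "Alteration or creation of an exonic splice site.",
    "level": "RNA",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  },
  {
    "term_id": "mech_ese",
    "name": "ESE",
    "definition": "Alteration of an exonic splicing enhancer motif.",
    "level": "RNA",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  },
  {
    "term_id": "mech_ess",
    "name": "ESS",
    "definition": "Alteration or creation of an exonic splicing silencer motif.",
    "level": "RNA",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  },
  {
    "term_id": "mech_mrna_structure_stability",
    "name": "MRNA_STRUCTURE_STABILITY",
    "definition": "Change in mRNA secondary structure or stability affecting transcript abundance.",
    "level": "RNA",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  },
  {
    "term_id": "mech_mirna_binding",
    "name": "MIRNA_BINDING",
    "definition": "Alteration of an exonic miRNA binding site affecting regulation of gene expression.",
    "level": "RNA",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  },
  {
    "term_id": "mech_codon_usage_translation",
    "name": "CODON_USAGE_TRANSLATION",
    "definition": "Change in translation speed or efficiency due to codon usage bias and tRNA pool limitations.",
    "level": "PROTEIN",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  },
  {
    "term_id": "mech_cotranslational_folding",
    "name": "COTRANSLATIONAL_FOLDING",
    "definition": "Altered co-translational folding leading to conformational or activity change.",
    "level": "PROTEIN",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  },
  {
    "term_id": "mech_ptm",
    "name": "PTM",
    "definition": "Change affecting a post-translational modification of the encoded protein.",
    "level": "PROTEIN",
    "parent": null,
    "provenance": "artifact",
    "external_code": null
  }
]
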