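{
  "ligand_block": {
    "structure_id": "4-character structure accession",
    "het_code": "up-to-3-character chemical component code",
    "chain_id": "chain carrying the ligand copy",
    "residue_number": "author residue number of the ligand copy",
    "heavy_atoms": "number of non-hydrogen atoms modeled",
    "mol_weight": "molecular weight in g/mol from modeled atoms",
    "covalent": "true when a LINK record joins the ligand to the polymer",
    "skip_reasons": "semicolon-joined consistency flags, empty when clean"
  },
  "structure_block": {
    "structure_id": "4-character structure accession",
    "resolution": "resolution in Angstrom, empty when not applicable",
    "r_factor": "crystallographic R (working set)",
    "r_free": "cross-validation R",
    "method": "experimental method from the header",
    "deposition_date": "ISO-8601 deposition date",
    "density_support": "pass-through per-complex density-support score; -1 = not computable"
  },
  "activity_block": {
    "target_accession": "bioactivity registry target (CHEMBL<integer>)",
    "target_type": "registry target classification",
    "assay_id": "assay identifier",
    "activity_type": "measured quantity (IC50, Ki, ...)",
    "value": "activity value",
    "units": "activity units",
    "pchembl": "negative log10 molar activity",
    "document_date": "ISO-8601 publication date of the source document",
    "data_validity_comment": "registry validity annotation, empty when clean",
    "identity": "percent sequence identity of the protein match",
    "coverage": "percent of the structure-chain sequence covered",
    "cov_id": "coverage-weighted identity (0-1)",
    "d_query": "relative alignment/query length discrepancy",
    "d_hit": "relative alignment/hit length discrepancy",
    "quality": "GOLD / SILVER / BRONZE / NONE protein-match tier",
    "molecule_level": "five-level molecule match grade (binding mode only)",
    "n_site_mutations": "mutations within the binding site (binding mode only)",
    "molecule_inchikey": "InChIKey of the registry molecule (binding mode only)",
    "variant_used": "true when an assay variant sequence replaced the component",
    "from_seqadv": "true when the match used a SEQADV-adjusted sequence",
    "best_alignment": "true for the best-scoring alignment of its complex"
  },
  "indicators": {
    "merge_ligand_structure": "both / ligand_only / structure_only",
    "merge_activity": "present / absent"
  }
}
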