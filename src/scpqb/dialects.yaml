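# Column maps for supported report dialects.
#
# Each dialect maps canonical column names to the export's column names.
# "intensity_columns" dialects are wide (one column per quant level) and are
# melted into long form on read; the "native" dialect is already long.
native:
  separator: "\t"
  columns:
    run_id: run_id
    load_pg: load_pg
    replicate: replicate
    peptide_id: peptide_id
    protein_id: protein_id
    quant_level: quant_level
    intensity: intensity
    id_source: id_source
    library_origin: library_origin
  mandatory: [run_id, peptide_id, protein_id, quant_level, intensity]

spectronaut-like:
  separator: "\t"
  columns:
    run_id: R.FileName
    load_pg: R.Condition
    replicate: R.Replicate
    peptide_id: EG.ModifiedSequence
    protein_id: PG.ProteinGroups
    id_source: EG.IdentificationType
  intensity_columns:
    MS1: FG.MS1Quantity
    MS2: FG.MS2Quantity
  id_source_values:
    "By MS1": direct
    "By MS2": direct
    "By Matching": propagated
  mandatory: [run_id, peptide_id, protein_id]

diann-like:
  separator: "\t"
  columns:
    run_id: Run
    peptide_id: Modified.Sequence
    protein_id: Protein.Group
  intensity_columns:
    MS1: Ms1.Area
    MS2: Precursor.Quantity
  mandatory: [run_id, peptide_id, protein_id]
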