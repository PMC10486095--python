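# Example replicate-pair configuration for `genehmm eval --replicates`.
#
# Pairs of epigenomes in the 127-reference-epigenome panel that profile the
# same cell type in different individuals, and so act as biological
# replicates for the confusion-matrix / reproducibility analyses.  Edit to
# match your own panel; entries must equal the cell-type column labels of
# the assignment table.
- ["Rectal Mucosa Donor 29", "Rectal Mucosa Donor 31"]
- ["Foreskin Fibroblast Primary Cells skin01", "Foreskin Fibroblast Primary Cells skin02"]
- ["Foreskin Melanocyte Primary Cells skin01", "Foreskin Melanocyte Primary Cells skin03"]
- ["Foreskin Keratinocyte Primary Cells skin02", "Foreskin Keratinocyte Primary Cells skin03"]
- ["Skeletal Muscle Female", "Skeletal Muscle Male"]
- ["Primary hematopoietic stem cells G-CSF-mobilized Male", "Primary hematopoietic stem cells G-CSF-mobilized Female"]
- ["Fetal Brain Female", "Fetal Brain Male"]
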