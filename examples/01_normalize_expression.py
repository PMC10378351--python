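"""FPKM -> TPM normalization of a small expression table.

Builds a 3-gene, 2-sample FPKM matrix and rescales each sample column so it
sums to one million. After conversion the columns are directly comparable
between samples, which the pairwise subtraction downstream relies on.
"""

import numpy as np

import survimage as sv

fpkm = sv.ExpressionMatrix(
    gene_ids=["ENSG_A", "ENSG_B", "ENSG_C"],
    sample_ids=["patient1", "patient2"],
    values=np.array([[10.0, 1.0], [30.0, 1.0], [60.0, 2.0]]),
    unit="FPKM",
)
tpm = sv.fpkm_to_tpm(fpkm)

print("FPKM columns:")
print(fpkm.values)
print("TPM columns (each sums to 1,000,000):")
print(tpm.values)
print("column sums:", tpm.values.sum(axis=0))
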