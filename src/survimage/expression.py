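"""Expression matrices and FPKM→TPM normalization.

Bulk RNA-seq expression is handled as a dense genes × samples matrix with a
fixed, explicit gene order and a unit tag.  The only normalization offered is
the FPKM→TPM conversion: because FPKM already divides by transcript length,
TPM is obtained by rescaling each sample column to sum to one million,

    TPM[i, j] = FPKM[i, j] / sum_i FPKM[i, j] * 1e6.

Gene order is never reordered by any operation here; downstream pairwise
subtraction relies on every sample sharing one consistent gene arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionError",
    "read_expression",
    "write_expression",
    "fpkm_to_tpm",
    "TPM_TOTAL",
]

#: Fixed per-sample total that defines the TPM unit.
TPM_TOTAL = 1_000_000.0

UNITS = ("FPKM", "TPM")

#: Relative tolerance on the per-sample TPM column sum.
TPM_RTOL = 1e-6


class ExpressionError(ValueError):
    """Raised for malformed or invariant-violating expression data."""


@dataclass
class ExpressionMatrix:
    """Dense genes × samples expression matrix with a unit tag.

    Parameters
    ----------
    gene_ids
        Ordered gene identifiers (rows). The order is authoritative and is
        preserved by every operation in this package.
    sample_ids
        Ordered sample identifiers (columns).
    values
        Non-negative finite float array of shape ``(len(gene_ids),
        len(sample_ids))``.
    unit
        ``"FPKM"`` or ``"TPM"``. A TPM matrix must have every column summing
        to one million within relative tolerance.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.unit not in UNITS:
            raise ExpressionError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.ndim != 2:
            raise ExpressionError("values must be a 2-D genes x samples array")
        g, s = self.values.shape
        if g != len(self.gene_ids) or s != len(self.sample_ids):
            raise ExpressionError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.gene_ids)} genes, {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ExpressionError("expression values must be finite")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ExpressionError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.unit == "TPM":
            sums = self.values.sum(axis=0)
            bad = np.abs(sums - TPM_TOTAL) > TPM_RTOL * TPM_TOTAL
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise ExpressionError(
                    f"TPM column {self.sample_ids[j]!r} sums to {sums[j]:.6g}, "
                    f"expected {TPM_TOTAL:g}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        """Return a copy of one sample's expression vector in gene order."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None
        return self.values[:, j].copy()

    def subset(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Column subset (and reorder) by sample id; gene order unchanged."""
        idx = []
        for sid in sample_ids:
            try:
                idx.append(self.sample_ids.index(sid))
            except ValueError:
                raise KeyError(f"sample {sid!r} not in matrix") from None
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx].copy(),
            unit=self.unit,
        )


def read_expression(path, unit: str) -> ExpressionMatrix:
    """Read a wide TSV (gene id column + one numeric column per sample).

    Gzip input is auto-detected from a ``.gz`` suffix. Row order in the file
    is the gene order of the returned matrix. A malformed numeric cell raises
    :class:`ExpressionError` naming the offending gene and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ExpressionError(f"duplicate gene id {dup!r} in {path}")
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ExpressionError(
                f"malformed numeric cell at gene {gene!r}, sample {col!r} in {path}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy()][0]
            raise ExpressionError(f"missing value at gene {gene!r}, sample {col!r}")
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
        unit=unit,
    )


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write the matrix as a wide TSV (gzip if the path ends in ``.gz``)."""
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample column so it sums to one million.

    Raises
    ------
    ExpressionError
        If the input is not FPKM, or a sample column sums to zero (no
        transcript abundance to renormalize).
    """
    if m.unit != "FPKM":
        raise ExpressionError(f"fpkm_to_tpm expects FPKM input, got {m.unit}")
    sums = m.values.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        j = int(np.flatnonzero(zero)[0])
        raise ExpressionError(
            f"sample {m.sample_ids[j]!r} has all-zero expression; cannot normalize"
        )
    tpm = m.values / sums[np.newaxis, :] * TPM_TOTAL
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=tpm,
        unit="TPM",
    )
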