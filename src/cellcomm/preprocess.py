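"""Library-size normalisation and low-expression filtering.

Counts are converted to counts-per-million (CPM); log transforms use
log2(x + 1) so zeros stay at zero.  Filtering keeps genes expressed above a
CPM floor in a minimum number of samples and is idempotent.
"""

from __future__ import annotations

import numpy as np

from .io import ExpressionMatrix, FormatError


def _require_unit(mat: ExpressionMatrix, unit: str, op: str) -> None:
    if mat.unit != unit:
        raise FormatError(f"{op} expects unit={unit!r}, got {mat.unit!r}")


def cpm_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to one million total counts."""
    _require_unit(mat, "counts", "cpm_normalize")
    colsums = mat.values.sum(axis=0)
    if np.any(colsums <= 0):
        bad = mat.sample_ids[int(np.argmax(colsums <= 0))]
        raise FormatError(f"zero library size for sample {bad!r}")
    values = mat.values / colsums * 1e6
    return ExpressionMatrix(list(mat.gene_ids), list(mat.sample_ids), values, unit="cpm")


def log_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1); monotone, maps 0 to 0."""
    _require_unit(mat, "cpm", "log_transform")
    return ExpressionMatrix(
        list(mat.gene_ids), list(mat.sample_ids), np.log2(mat.values + 1.0), unit="logcpm"
    )


def filter_low_expression(
    mat: ExpressionMatrix, min_cpm: float = 1.0, min_samples: int = 2
) -> ExpressionMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    Gene order is preserved; the sample set is unchanged.  Raises if nothing
    survives (an empty matrix would silently poison every downstream stage).
    """
    _require_unit(mat, "cpm", "filter_low_expression")
    if min_samples > mat.n_samples:
        raise FormatError(
            f"min_samples={min_samples} exceeds the {mat.n_samples} available samples"
        )
    keep = (mat.values >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise FormatError("no gene survives the low-expression filter")
    genes = [g for g, k in zip(mat.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(mat.sample_ids), mat.values[keep, :].copy(), unit="cpm")
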