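"""Per-modality Jaccard similarity between drugs' binary feature profiles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import DataValidationError, FeatureMatrix

__all__ = ["SimilarityMatrix", "jaccard", "similarity_matrix", "write_similarity_tsv"]


@dataclass
class SimilarityMatrix:
    """Symmetric m x m matrix of pairwise Jaccard similarities for one modality."""

    modality_name: str
    drug_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        m = len(self.drug_ids)
        if self.values.shape != (m, m):
            raise DataValidationError(
                f"similarity matrix for {self.modality_name!r}: shape "
                f"{self.values.shape} != ({m}, {m})"
            )
        if not np.array_equal(self.values, self.values.T):
            raise DataValidationError(f"{self.modality_name!r}: matrix is not symmetric")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise DataValidationError(f"{self.modality_name!r}: entries outside [0, 1]")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard similarity |X∩Y| / (|X|+|Y|−|X∩Y|) of two binary rows.

    X and Y are the index sets where the rows are 1. The undefined 0/0 case
    (both rows all-zero) is returned as 0.0: absence of any feature evidence
    is not treated as similarity.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    inter = float(np.sum((x != 0) & (y != 0)))
    union = float(np.sum((x != 0) | (y != 0)))
    return inter / union if union > 0 else 0.0


def similarity_matrix(fm: FeatureMatrix) -> SimilarityMatrix:
    """All-pairs Jaccard matrix of a feature matrix's rows.

    Computed from exact integer intersection/union counts (X·Xᵀ over float64,
    exact for any realistic feature count), so entries match the per-pair
    set-based definition bit-for-bit. Drugs with empty rows get 0 everywhere,
    including the diagonal (the 0/0 convention of :func:`jaccard`).
    """
    x = fm.values.astype(np.float64)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    # exact symmetry: numerator and denominator are both symmetric integer
    # matrices, but enforce it to be safe against BLAS summation order
    vals = np.maximum(vals, vals.T)
    return SimilarityMatrix(fm.modality_name, list(fm.drug_ids), vals)


def write_similarity_tsv(sm: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sm.values, columns=sm.drug_ids)
    df.insert(0, "drug_id", sm.drug_ids)
    df.to_csv(path, sep="\t", index=False)
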