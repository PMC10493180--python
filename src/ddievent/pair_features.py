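"""Concatenate per-modality similarity matrices and encode drug pairs.

The drug feature table is the horizontal concatenation of the p similarity
matrices (m x p*m). A pair (i, j) is encoded from rows i and j of that table:
elementwise sum (the default, order-invariant), concatenation, or elementwise
product.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import DataValidationError
from .similarity import SimilarityMatrix

__all__ = ["DrugFeatureTable", "concat_similarities", "encode_pair", "encode_pairs", "PAIR_MODES"]

PAIR_MODES = ("sum", "concat", "dot")


@dataclass
class DrugFeatureTable:
    """m x (p*m) table; one block of m columns per modality, in order."""

    drug_ids: list[str]
    block_spans: dict[str, tuple[int, int]]  # modality -> [start, stop) columns
    values: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.drug_ids)
        p = len(self.block_spans)
        if self.values.shape != (m, p * m):
            raise DataValidationError(
                f"feature table shape {self.values.shape} != ({m}, {p * m})"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def modality_names(self) -> list[str]:
        return list(self.block_spans)

    def block(self, modality_name: str) -> np.ndarray:
        start, stop = self.block_spans[modality_name]
        return self.values[:, start:stop]

    def drop_block(self, modality_name: str) -> np.ndarray:
        """Table values with one modality's column block removed."""
        if modality_name not in self.block_spans:
            raise KeyError(f"no modality named {modality_name!r}")
        start, stop = self.block_spans[modality_name]
        return np.hstack([self.values[:, :start], self.values[:, stop:]])


def concat_similarities(mats: list[SimilarityMatrix]) -> DrugFeatureTable:
    """Horizontally concatenate similarity matrices in the given order."""
    if not mats:
        raise DataValidationError("need at least one similarity matrix")
    ref = mats[0].drug_ids
    for sm in mats[1:]:
        if sm.drug_ids != ref:
            raise DataValidationError(
                f"modality {sm.modality_name!r} disagrees on drug IDs/order"
            )
    m = len(ref)
    spans: dict[str, tuple[int, int]] = {}
    for k, sm in enumerate(mats):
        if sm.modality_name in spans:
            raise DataValidationError(f"duplicate modality {sm.modality_name!r}")
        spans[sm.modality_name] = (k * m, (k + 1) * m)
    values = np.hstack([sm.values for sm in mats])
    return DrugFeatureTable(list(ref), spans, values)


def encode_pairs(
    rows: np.ndarray, ii: np.ndarray, jj: np.ndarray, mode: str = "sum"
) -> np.ndarray:
    """Vectorized pair encoding for index arrays ``ii``, ``jj`` over ``rows``."""
    if mode not in PAIR_MODES:
        raise ValueError(f"unknown pair encoding mode {mode!r}; choose from {PAIR_MODES}")
    ii = np.asarray(ii)
    jj = np.asarray(jj)
    if np.any(ii == jj):
        raise DataValidationError("self-pairs (i == j) cannot be encoded")
    if mode == "sum":
        return rows[ii] + rows[jj]
    if mode == "dot":
        return rows[ii] * rows[jj]
    return np.hstack([rows[ii], rows[jj]])


def encode_pair(table: DrugFeatureTable | np.ndarray, i: int, j: int, mode: str = "sum") -> np.ndarray:
    """Encode one drug pair from the feature table (or a raw row matrix)."""
    rows = table.values if isinstance(table, DrugFeatureTable) else np.asarray(table)
    if not (0 <= i < rows.shape[0] and 0 <= j < rows.shape[0]):
        raise DataValidationError(f"pair index out of range: ({i}, {j})")
    return encode_pairs(rows, np.array([i]), np.array([j]), mode)[0]


def write_table_tsv(table: DrugFeatureTable, path: str | Path) -> None:
    cols = [
        f"{name}:{table.drug_ids[c - start]}"
        for name, (start, stop) in table.block_spans.items()
        for c in range(start, stop)
    ]
    df = pd.DataFrame(table.values, columns=cols)
    df.insert(0, "drug_id", table.drug_ids)
    df.to_csv(path, sep="\t", index=False)
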