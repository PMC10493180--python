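"""Readers, writers and validation for drug feature matrices and DDI event tables.

All on-disk artifacts are tab-separated UTF-8 text with a header row. Feature
matrices carry a leading ``drug_id`` column followed by one column per binary
feature; DDI tables are three columns ``drug_a``, ``drug_b``, ``event``. A
bundle directory additionally holds a YAML manifest naming the modality files
(in order), the DDI file, and the expected shape counts used for validation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DataValidationError",
    "FeatureMatrix",
    "PairDataset",
    "DatasetBundle",
    "load_feature_matrix",
    "load_ddi_table",
    "write_bundle",
    "load_bundle",
]

MANIFEST_NAME = "manifest.yaml"
DDI_FILE_NAME = "ddis.tsv"


class DataValidationError(ValueError):
    """Raised when an input file or in-memory structure violates a contract."""


def _check_unique(items: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            raise DataValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class FeatureMatrix:
    """One modality's binary drugs x features incidence matrix.

    ``values[i, j] == 1`` iff drug ``drug_ids[i]`` has feature ``columns[j]``.
    """

    modality_name: str
    drug_ids: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        m, c = len(self.drug_ids), len(self.columns)
        if c == 0:
            raise DataValidationError(
                f"modality {self.modality_name!r}: needs at least one feature column"
            )
        if self.values.shape != (m, c):
            raise DataValidationError(
                f"modality {self.modality_name!r}: values shape {self.values.shape} "
                f"does not match {m} drugs x {c} columns"
            )
        _check_unique(self.drug_ids, f"drug ID in modality {self.modality_name!r}")
        _check_unique(self.columns, f"feature column in modality {self.modality_name!r}")
        bad = (self.values != 0) & (self.values != 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise DataValidationError(
                f"modality {self.modality_name!r}: non-binary entry "
                f"{self.values[i, j]!r} at drug {self.drug_ids[i]!r}, "
                f"column {self.columns[j]!r}"
            )
        self.values = self.values.astype(np.int8, copy=False)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_features(self) -> int:
        return len(self.columns)


@dataclass
class PairDataset:
    """Labeled drug-pair records over a shared event vocabulary.

    Each record is ``(i, j, e)``: row indices of the two drugs and the event
    index. Pairs are unordered and unique — the single-label formulation.
    """

    drug_ids: list[str]
    records: list[tuple[int, int, int]]
    event_labels: list[str]

    def __post_init__(self) -> None:
        _check_unique(self.drug_ids, "drug ID")
        _check_unique(self.event_labels, "event label")
        m, n = len(self.drug_ids), len(self.event_labels)
        seen: dict[tuple[int, int], int] = {}
        used = np.zeros(n, dtype=bool)
        for i, j, e in self.records:
            if i == j:
                raise DataValidationError(f"self-pair ({self.drug_ids[i]!r}) is not allowed")
            if not (0 <= i < m and 0 <= j < m):
                raise DataValidationError(f"record ({i}, {j}, {e}): drug index out of range")
            if not 0 <= e < n:
                raise DataValidationError(f"record ({i}, {j}, {e}): event index out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise DataValidationError(
                    f"duplicate pair ({self.drug_ids[i]!r}, {self.drug_ids[j]!r})"
                )
            seen[key] = e
            used[e] = True
        if not used.all():
            unused = [self.event_labels[k] for k in np.flatnonzero(~used)]
            raise DataValidationError(f"event labels with no records: {unused}")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_events(self) -> int:
        return len(self.event_labels)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def y(self) -> np.ndarray:
        """Event index per record, as an int array."""
        return np.array([e for _, _, e in self.records], dtype=np.int64)

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        ii = np.array([i for i, _, _ in self.records], dtype=np.int64)
        jj = np.array([j for _, j, _ in self.records], dtype=np.int64)
        return ii, jj


@dataclass
class DatasetBundle:
    """All modality matrices plus the pair dataset, on one shared drug order."""

    feature_matrices: list[FeatureMatrix]
    pairs: PairDataset

    def __post_init__(self) -> None:
        if len(self.feature_matrices) < 1:
            raise DataValidationError("a bundle needs at least one feature matrix")
        ref = self.feature_matrices[0].drug_ids
        for fm in self.feature_matrices[1:]:
            if fm.drug_ids != ref:
                raise DataValidationError(
                    f"modality {fm.modality_name!r} disagrees on drug IDs/order"
                )
        if self.pairs.drug_ids != ref:
            raise DataValidationError("pair dataset disagrees on drug IDs/order")
        names = [fm.modality_name for fm in self.feature_matrices]
        _check_unique(names, "modality name")

    @property
    def drug_ids(self) -> list[str]:
        return self.feature_matrices[0].drug_ids

    @property
    def modality_names(self) -> list[str]:
        return [fm.modality_name for fm in self.feature_matrices]

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_modalities(self) -> int:
        return len(self.feature_matrices)

    def modality(self, name: str) -> FeatureMatrix:
        for fm in self.feature_matrices:
            if fm.modality_name == name:
                return fm
        raise KeyError(f"no modality named {name!r}")


def load_feature_matrix(path: str | Path, modality_name: str) -> FeatureMatrix:
    """Read one modality's binary matrix from a TSV with a ``drug_id`` column.

    Row order from the file is preserved. Any cell other than 0/1 is a hard
    error naming the offending drug and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or df.columns[0] != "drug_id":
        raise DataValidationError(
            f"{path}: expected a 'drug_id' first column plus >=1 feature column"
        )
    drug_ids = df["drug_id"].tolist()
    columns = df.columns[1:].tolist()
    raw = df.iloc[:, 1:].to_numpy()
    values = np.zeros(raw.shape, dtype=np.int8)
    ok = (raw == "0") | (raw == "1")
    if not ok.all():
        i, j = map(int, np.argwhere(~ok)[0])
        raise DataValidationError(
            f"{path}: non-binary cell {raw[i, j]!r} at drug {drug_ids[i]!r}, "
            f"column {columns[j]!r}"
        )
    values[raw == "1"] = 1
    return FeatureMatrix(modality_name, drug_ids, columns, values)


def load_ddi_table(path: str | Path, drug_ids: list[str]) -> PairDataset:
    """Read a (drug_a, drug_b, event) TSV and index it against ``drug_ids``.

    Event labels receive contiguous indices in order of first appearance.
    Unknown drugs and duplicate unordered pairs are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["drug_a", "drug_b", "event"]
    if df.columns.tolist() != expected:
        raise DataValidationError(f"{path}: expected columns {expected}, got {df.columns.tolist()}")
    index = {d: k for k, d in enumerate(drug_ids)}
    event_index: dict[str, int] = {}
    records: list[tuple[int, int, int]] = []
    seen: dict[tuple[int, int], tuple[str, str, str]] = {}
    for a, b, ev in df.itertuples(index=False):
        for d in (a, b):
            if d not in index:
                raise DataValidationError(f"{path}: unknown drug {d!r} (not in drug ID list)")
        i, j = index[a], index[b]
        if i == j:
            raise DataValidationError(f"{path}: self-pair {a!r}")
        key = (min(i, j), max(i, j))
        if key in seen:
            prev = seen[key]
            if prev[2] != ev:
                raise DataValidationError(
                    f"{path}: pair ({a!r}, {b!r}) appears twice with conflicting "
                    f"events {prev[2]!r} vs {ev!r}"
                )
            raise DataValidationError(f"{path}: duplicate pair ({a!r}, {b!r})")
        seen[key] = (a, b, ev)
        if ev not in event_index:
            event_index[ev] = len(event_index)
        records.append((i, j, event_index[ev]))
    return PairDataset(list(drug_ids), records, list(event_index))


def _feature_file_name(modality_name: str) -> str:
    return f"features_{modality_name}.tsv"


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fm.values, columns=fm.columns)
    df.insert(0, "drug_id", fm.drug_ids)
    df.to_csv(path, sep="\t", index=False)


def write_ddi_table(pairs: PairDataset, path: str | Path) -> None:
    rows = [
        (pairs.drug_ids[i], pairs.drug_ids[j], pairs.event_labels[e])
        for i, j, e in pairs.records
    ]
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "event"]).to_csv(
        path, sep="\t", index=False
    )


def write_bundle(bundle: DatasetBundle, out_dir: str | Path) -> list[Path]:
    """Write one TSV per modality, the DDI table, and a manifest.

    Returns the list of written paths. ``load_bundle`` on the directory
    reproduces the bundle exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fm in bundle.feature_matrices:
        p = out_dir / _feature_file_name(fm.modality_name)
        write_feature_matrix(fm, p)
        written.append(p)
    ddi_path = out_dir / DDI_FILE_NAME
    write_ddi_table(bundle.pairs, ddi_path)
    written.append(ddi_path)
    manifest = {
        "modalities": [
            {"name": fm.modality_name, "file": _feature_file_name(fm.modality_name)}
            for fm in bundle.feature_matrices
        ],
        "ddi_file": DDI_FILE_NAME,
        "n_drugs": bundle.n_drugs,
        "n_modalities": bundle.n_modalities,
        "n_events": bundle.pairs.n_events,
    }
    mpath = out_dir / MANIFEST_NAME
    with open(mpath, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    written.append(mpath)
    return written


def load_bundle(bundle_dir: str | Path) -> DatasetBundle:
    """Load a bundle directory written by :func:`write_bundle`.

    The manifest's expected counts are validated against the loaded files; a
    drug missing from any modality file is a hard error (no silent zero-fill).
    """
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / MANIFEST_NAME, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    mats = [
        load_feature_matrix(bundle_dir / entry["file"], entry["name"])
        for entry in manifest["modalities"]
    ]
    ref = mats[0].drug_ids
    for fm in mats[1:]:
        missing = set(ref) - set(fm.drug_ids)
        if missing:
            raise DataValidationError(
                f"modality {fm.modality_name!r} is missing drugs: {sorted(missing)[:5]}"
            )
    pairs = load_ddi_table(bundle_dir / manifest["ddi_file"], ref)
    bundle = DatasetBundle(mats, pairs)
    checks = [
        ("n_drugs", bundle.n_drugs),
        ("n_modalities", bundle.n_modalities),
        ("n_events", pairs.n_events),
    ]
    for key, got in checks:
        if manifest.get(key) is not None and manifest[key] != got:
            raise DataValidationError(
                f"manifest expects {key}={manifest[key]}, files give {got}"
            )
    return bundle


def bundle_dir_hash(bundle_dir: str | Path) -> str:
    """SHA-256 over the manifest and data files, for run provenance."""
    bundle_dir = Path(bundle_dir)
    h = hashlib.sha256()
    for p in sorted(bundle_dir.iterdir()):
        if p.suffix in {".tsv", ".yaml"}:
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
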