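"""Reading, validation, summarisation and splitting of labelled molecule tables.

A dataset is a list of molecules, each with a unique identifier, a SMILES
string and a binary toxicity label (1 = DITP toxicant, 0 = non-toxicant).
Rows whose SMILES cannot be parsed are rejected at read time and reported
with their row numbers; they never enter a :class:`LabeledDataset`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MoleculeRecord",
    "LabeledDataset",
    "RejectedRow",
    "DatasetError",
    "read_dataset",
    "stratified_split",
    "dataset_summary",
    "write_dataset",
]


class DatasetError(ValueError):
    """Raised for malformed dataset files or invariant violations."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: unique id, SMILES, binary label (1 = toxicant)."""

    id: str
    smiles: str
    label: int

    def __post_init__(self) -> None:
        if not self.id:
            raise DatasetError("molecule id must be a non-empty string")
        if self.label not in (0, 1):
            raise DatasetError(
                f"label for {self.id!r} must be 0 or 1, got {self.label!r}"
            )


@dataclass(frozen=True)
class RejectedRow:
    """A data row refused at read time, with its 1-based row number."""

    row_number: int
    id: str
    smiles: str
    reason: str


@dataclass
class LabeledDataset:
    """An ordered collection of :class:`MoleculeRecord` with unique ids.

    ``rejected`` carries the read-time rejection report when the dataset
    came from :func:`read_dataset`; it is empty for constructed datasets.
    """

    records: list[MoleculeRecord]
    rejected: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate molecule id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def class_counts(self) -> dict[int, int]:
        y = self.labels
        return {1: int((y == 1).sum()), 0: int((y == 0).sum())}

    @property
    def class_proportions(self) -> dict[int, float]:
        """Fraction of each class (the P_k entering the entropy of the labels)."""
        n = len(self)
        if n == 0:
            raise DatasetError("empty dataset has no class proportions")
        c = self.class_counts
        return {k: v / n for k, v in c.items()}

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])


def _parseable(smiles: str) -> bool:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles) is not None


_DEFAULT_COLUMNS = {"id": "id", "smiles": "smiles", "label": "label"}


def read_dataset(
    path,
    format: str = "csv",
    column_map: dict | None = None,
    delimiter: str = ",",
    validate_smiles: bool = True,
) -> LabeledDataset:
    """Read a labelled molecule table from CSV or SMI.

    Parameters
    ----------
    path : str or Path
        Input file. CSV needs a header row; SMI is whitespace-separated
        ``SMILES id label``.
    column_map : dict, optional
        Maps the logical names ``id``, ``smiles``, ``label`` to the file's
        column names. An optional ``label_values`` entry maps textual label
        values to 0/1 (no silent coercion of text labels otherwise).
    validate_smiles : bool
        When true (default), rows with unparseable SMILES are rejected and
        listed in ``dataset.rejected`` with their row numbers.
    """
    cmap = dict(_DEFAULT_COLUMNS)
    label_values: dict | None = None
    if column_map:
        label_values = column_map.get("label_values")
        cmap.update(
            {k: v for k, v in column_map.items() if k in _DEFAULT_COLUMNS}
        )

    rows: list[tuple[int, str, str, str]] = []  # (row_number, id, smiles, raw label)
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delimiter)
            header = reader.fieldnames or []
            for logical, col in cmap.items():
                if col not in header:
                    raise DatasetError(
                        f"column {col!r} (mapped from {logical!r}) missing; "
                        f"file has {header}"
                    )
            for i, row in enumerate(reader, start=2):  # header is row 1
                rows.append((i, row[cmap["id"]], row[cmap["smiles"]], row[cmap["label"]]))
    elif format == "smi":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 3:
                    raise DatasetError(
                        f"row {i}: SMI format needs 'SMILES id label', got {line!r}"
                    )
                rows.append((i, parts[1], parts[0], parts[2]))
    else:
        raise DatasetError(f"unknown format {format!r} (expected 'csv' or 'smi')")

    records: list[MoleculeRecord] = []
    rejected: list[RejectedRow] = []
    seen: set[str] = set()
    for row_number, mol_id, smiles, raw_label in rows:
        if label_values is not None and raw_label in label_values:
            label = label_values[raw_label]
        else:
            try:
                label = int(raw_label)
            except (TypeError, ValueError):
                raise DatasetError(
                    f"row {row_number}: label {raw_label!r} is not binary; "
                    "supply column_map['label_values'] for textual labels"
                ) from None
        if label not in (0, 1):
            raise DatasetError(f"row {row_number}: label must be 0 or 1, got {label}")
        if mol_id in seen:
            raise DatasetError(f"row {row_number}: duplicate id {mol_id!r}")
        seen.add(mol_id)
        if validate_smiles and not _parseable(smiles):
            rejected.append(
                RejectedRow(row_number, mol_id, smiles, "unparseable SMILES")
            )
            continue
        records.append(MoleculeRecord(mol_id, smiles, label))

    return LabeledDataset(records, rejected=rejected)


def write_dataset(ds: LabeledDataset, path, delimiter: str = ",") -> None:
    """Write the CSV schema :func:`read_dataset` reads back."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["id", "smiles", "label"])
        for rec in ds.records:
            writer.writerow([rec.id, rec.smiles, rec.label])


def _largest_remainder_counts(
    class_sizes: dict[int, int], train_fraction: float
) -> dict[int, int]:
    """Hamilton (largest-remainder) apportionment of training seats per class.

    Total seats are round(train_fraction * n); each class gets the floor of
    its quota and leftover seats go to the largest fractional remainders
    (ties broken toward the positive class, then by label, for determinism).
    """
    n = sum(class_sizes.values())
    seats = int(round(train_fraction * n))
    quotas = {k: train_fraction * v for k, v in class_sizes.items()}
    alloc = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = seats - sum(alloc.values())
    order = sorted(
        class_sizes, key=lambda k: (quotas[k] - alloc[k], k), reverse=True
    )
    for k in order[:leftover]:
        alloc[k] += 1
    return alloc


def stratified_split(
    ds: LabeledDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    per_class_counts: dict[int, int] | None = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random stratified partition into training and external sets.

    Per-class training counts follow the largest-remainder rule on
    ``train_fraction * n_class`` unless ``per_class_counts`` overrides them
    explicitly (e.g. to reproduce a published split). The same seed gives
    the identical partition.
    """
    if not 0 < train_fraction < 1:
        raise DatasetError("train_fraction must lie strictly between 0 and 1")
    sizes = {k: v for k, v in ds.class_counts.items() if v > 0}
    if len(sizes) < 2:
        raise DatasetError("stratified split needs both classes present")

    if per_class_counts is not None:
        for k, c in per_class_counts.items():
            if not 0 <= c <= sizes.get(k, 0):
                raise DatasetError(
                    f"per_class_counts[{k}]={c} exceeds class size {sizes.get(k, 0)}"
                )
        counts = dict(per_class_counts)
    else:
        counts = _largest_remainder_counts(sizes, train_fraction)
    if any(counts.get(k, 0) == 0 for k in sizes):
        raise DatasetError("a class would receive zero training members")

    rng = np.random.default_rng(seed)
    y = ds.labels
    train_idx: list[int] = []
    for k in sorted(sizes):
        members = np.flatnonzero(y == k)
        perm = rng.permutation(len(members))
        train_idx.extend(members[perm[: counts[k]]].tolist())
    train_idx = sorted(train_idx)
    ext_idx = sorted(set(range(len(ds))) - set(train_idx))
    return ds.subset(train_idx), ds.subset(ext_idx)


def dataset_summary(ds: LabeledDataset, compute_properties: bool = True) -> dict:
    """Per-class counts plus per-molecule basic physicochemical properties.

    ``single_class_warning`` is set when only one label is present (such a
    dataset cannot be modelled). Properties are computed through
    :func:`ditptox.featurization.basic_properties` when SMILES are available.
    """
    if len(ds) == 0:
        raise DatasetError("cannot summarise an empty dataset")
    counts = ds.class_counts
    summary: dict = {
        "n": len(ds),
        "counts": {"pos": counts[1], "neg": counts[0]},
        "class_proportions": {str(k): v for k, v in ds.class_proportions.items()},
        "single_class_warning": min(counts.values()) == 0,
        "n_rejected": len(ds.rejected),
    }
    if compute_properties:
        from .featurization import basic_properties

        props = basic_properties(ds)
        summary["properties"] = [
            {"id": rec.id, **p.as_dict()} for rec, p in zip(ds.records, props)
        ]
    return summary


def summary_to_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
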