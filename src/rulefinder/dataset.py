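"""Dataset container and I/O for molecular-modifier screening tables.

A dataset is an ordered collection of modifier records: one carboxylic-acid
modifier per row with its SMILES, the experimental descriptors measured for
the modified catalyst (Fe-loading, modifier/SBU substitution ratio, Fe/Hf
ratio), the reaction yield in percent, and optionally a turnover number and
a binary high/low activity label derived from the yield.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ModifierRecord",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "binarize_by_median",
    "validate_dataset",
    "MedianLabelBinarizer",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
]

REQUIRED_COLUMNS = ("id", "smiles", "yield_percent", "fe_loading", "modifier_sbu", "fe_hf")
OPTIONAL_COLUMNS = ("name", "ton", "label")

HIGH = "high"
LOW = "low"


class SchemaError(ValueError):
    """The input table is missing a required column."""


class ValidationError(ValueError):
    """A record violates a dataset invariant (bad SMILES, duplicate id, ...)."""


@dataclass(frozen=True)
class ModifierRecord:
    """One molecular modifier and its measured reaction outcome.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    smiles : str
        SMILES of the (neutral, explicit-H-free) carboxylic acid modifier.
    yield_percent : float
        Reaction yield in percent, >= 0.
    fe_loading : float
        Catalyst Fe amount relative to substrate (arbitrary units).
    modifier_sbu : float
        Measured modifier-per-cluster substitution ratio.
    fe_hf : float
        Fe/Hf atomic ratio of the loaded catalyst.
    name : str, optional
        Human-readable name.
    ton : float, optional
        Turnover number.
    label : {"high", "low"}, optional
        Binary activity class, usually filled by median binarization.
    """

    id: str
    smiles: str
    yield_percent: float
    fe_loading: float
    modifier_sbu: float
    fe_hf: float
    name: str | None = None
    ton: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (HIGH, LOW):
            raise ValidationError(f"record {self.id!r}: label must be 'high'/'low', got {self.label!r}")


@dataclass(frozen=True)
class Dataset:
    """Ordered, immutable collection of :class:`ModifierRecord`."""

    records: tuple[ModifierRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ModifierRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "name": r.name,
                    "smiles": r.smiles,
                    "yield_percent": r.yield_percent,
                    "fe_loading": r.fe_loading,
                    "modifier_sbu": r.modifier_sbu,
                    "fe_hf": r.fe_hf,
                    "ton": r.ton,
                    "label": r.label,
                }
            )
        return pd.DataFrame(rows)


def _check_smiles(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


def read_dataset(path: str | Path, *, validate_smiles: bool = True) -> Dataset:
    """Read a modifier table from CSV (UTF-8, comma separated, dot decimal).

    Required columns: ``id, smiles, yield_percent, fe_loading, modifier_sbu,
    fe_hf``; optional: ``name, ton, label``. Row order is preserved.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If a SMILES does not parse (names the offending row id) or ids repeat.
    """
    df = pd.read_csv(path, dtype={"id": str, "smiles": str, "name": str, "label": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    records = []
    for _, row in df.iterrows():
        rid = str(row["id"])
        smi = str(row["smiles"])
        if validate_smiles and not _check_smiles(smi):
            raise ValidationError(f"record {rid!r}: SMILES does not parse: {smi!r}")
        rec = ModifierRecord(
            id=rid,
            smiles=smi,
            yield_percent=float(row["yield_percent"]),
            fe_loading=float(row["fe_loading"]),
            modifier_sbu=float(row["modifier_sbu"]),
            fe_hf=float(row["fe_hf"]),
            name=None if "name" not in df.columns or pd.isna(row.get("name")) else str(row["name"]),
            ton=None if "ton" not in df.columns or pd.isna(row.get("ton")) else float(row["ton"]),
            label=None if "label" not in df.columns or pd.isna(row.get("label")) else str(row["label"]),
        )
        records.append(rec)
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"duplicated ids: {sorted(dupes)}")
    return Dataset(tuple(records))


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset back to CSV; inverse of :func:`read_dataset`."""
    ds.to_frame().to_csv(path, index=False)


def binarize_by_median(ds: Dataset) -> Dataset:
    """Assign high/low labels by the median yield.

    A record is labelled ``high`` iff its yield is strictly greater than the
    median of all yields (the standard middle / mean-of-middle-two order
    statistic); ties at the median go to ``low``. With distinct yields this
    leaves the class sizes within one of each other.
    """
    if ds.n == 0:
        raise ValidationError("cannot binarize an empty dataset")
    yields = np.asarray([r.yield_percent for r in ds.records], dtype=float)
    med = float(np.median(yields))
    labeled = tuple(replace(r, label=HIGH if r.yield_percent > med else LOW) for r in ds.records)
    return Dataset(labeled)


def labels_to_int(labels: Sequence[str]) -> np.ndarray:
    """Encode high -> 1, low -> 0."""
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab == HIGH:
            out[i] = 1
        elif lab == LOW:
            out[i] = 0
        else:
            raise ValidationError(f"unlabeled or invalid label at position {i}: {lab!r}")
    return out


def validate_dataset(ds: Dataset) -> list[str]:
    """Return diagnostics (duplicate ids, non-finite numerics, bad SMILES).

    Returns an empty list iff the dataset is clean. Never raises.
    """
    diags: list[str] = []
    seen: set[str] = set()
    for r in ds.records:
        if r.id in seen:
            diags.append(f"duplicate id: {r.id!r}")
        seen.add(r.id)
        for field_name in ("yield_percent", "fe_loading", "modifier_sbu", "fe_hf"):
            v = getattr(r, field_name)
            if v is None or not math.isfinite(v):
                diags.append(f"record {r.id!r}: non-finite {field_name}: {v!r}")
        if not _check_smiles(r.smiles):
            diags.append(f"record {r.id!r}: unparsable SMILES: {r.smiles!r}")
    return diags


class MedianLabelBinarizer(BaseEstimator, TransformerMixin):
    """Median-threshold label binarizer with the sklearn transformer API.

    ``fit`` learns the median of the training yields; ``transform`` maps a
    vector of yields to integer classes (1 = strictly above the fitted
    median, 0 otherwise). The threshold is exposed as ``median_``.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).ravel()
        if X.size == 0:
            raise ValueError("empty input")
        self.median_ = float(np.median(X))
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "median_"):
            raise ValueError("MedianLabelBinarizer is not fitted")
        X = np.asarray(X, dtype=float).ravel()
        return (X > self.median_).astype(int)
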