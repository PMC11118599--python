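"""Readers, writers and run configuration.

CSV is the interchange format for tables, values and ground truth; bulk
per-iteration similarity records go to HDF5.  Every CLI run can be replayed
from its saved resolved configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dvgs import DataValues, ValuationConfig
from .models import LossSpec
from .synthetic import LabeledTable, ReplicateExpressionSet

__all__ = [
    "read_labeled_table",
    "write_labeled_table",
    "write_values",
    "read_values",
    "write_truth",
    "read_truth",
    "write_expression_set",
    "write_per_iteration",
    "RunConfig",
]


def read_labeled_table(path, label_column: str | None = None) -> LabeledTable:
    """Read a samples-by-features CSV into a :class:`LabeledTable`.

    A ``sample_id`` column, when present, supplies sample identities;
    otherwise they are positional.  Label values are coded as contiguous
    integers in lexicographic order of their string form, with the code map
    retained in ``generator_params``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        bad = int(np.where(df.isna().any(axis=1))[0][0])
        raise ValueError(f"{path}: missing or ragged value at data row {bad}")
    ids = (
        df.pop("sample_id").astype(str).tolist()
        if "sample_id" in df.columns
        else [str(i) for i in range(len(df))]
    )
    label_map = None
    y = np.zeros(len(df), dtype=int)
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"{path}: label column {label_column!r} not found")
        raw = df.pop(label_column).astype(str)
        classes = sorted(raw.unique())
        label_map = {c: i for i, c in enumerate(classes)}
        y = raw.map(label_map).to_numpy()
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = int(np.where(coerced.isna())[0][0])
            raise ValueError(f"{path}: non-numeric feature value in column {col!r}, data row {bad}")
    X = df.to_numpy(dtype=float)
    return LabeledTable(
        X=X, y=y, sample_ids=ids,
        generator_params={"path": str(path), "label_column": label_column,
                          "label_map": label_map, "feature_columns": list(df.columns)},
    )


def write_labeled_table(table: LabeledTable, path, label_column: str = "label") -> None:
    path = Path(path)
    df = pd.DataFrame(table.X, columns=[f"f{j}" for j in range(table.X.shape[1])])
    df.insert(0, "sample_id", table.sample_ids)
    df[label_column] = table.y
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(table.generator_params, indent=2))


def write_values(values: DataValues, path, sample_ids=None) -> None:
    """Write values as CSV (sample_id, value, method, n_runs[, converged]).

    Floats are written with shortest round-trip representation, so a read
    back recovers them bit-for-bit.
    """
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(values.values))]
    df = pd.DataFrame({
        "sample_id": list(ids),
        "value": values.values,
        "method": values.method,
        "n_runs": values.n_runs,
    })
    if values.converged is not None:
        df["converged"] = values.converged
    df.to_csv(path, index=False)


def read_values(path) -> DataValues:
    df = pd.read_csv(path, float_precision="round_trip")
    return DataValues(
        values=df["value"].to_numpy(dtype=float),
        method=str(df["method"].iloc[0]) if len(df) else "unknown",
        n_runs=int(df["n_runs"].iloc[0]) if len(df) else 1,
        converged=bool(df["converged"].iloc[0]) if "converged" in df.columns and len(df) else None,
    )


def write_truth(path, sample_ids, mask=None, rates=None) -> None:
    """Ground-truth CSV: a corruption mask and/or noise-rate column."""
    df = pd.DataFrame({"sample_id": list(sample_ids)})
    if mask is not None:
        df["mask"] = np.asarray(getattr(mask, "mask", mask)).astype(int)
    if rates is not None:
        df["rate"] = np.asarray(getattr(rates, "rates", rates), dtype=float)
    df.to_csv(path, index=False)


def read_truth(path):
    df = pd.read_csv(path)
    mask = df["mask"].to_numpy(dtype=int) if "mask" in df.columns else None
    rates = df["rate"].to_numpy(dtype=float) if "rate" in df.columns else None
    return mask, rates


def write_expression_set(es: ReplicateExpressionSet, prefix) -> None:
    """Write level-4 and level-5 matrices plus the group map and sidecar."""
    prefix = Path(prefix)
    genes = [f"g{j}" for j in range(es.level4.shape[1])]
    l4 = pd.DataFrame(es.level4, columns=genes)
    l4.insert(0, "replicate_id", [f"r{i:05d}" for i in range(len(es.level4))])
    l4.insert(1, "group", es.group_of)
    l4.to_csv(prefix.with_name(prefix.name + "_level4.csv"), index=False)
    l5 = pd.DataFrame(es.level5, columns=genes)
    l5.insert(0, "group", es.group_ids)
    l5.to_csv(prefix.with_name(prefix.name + "_level5.csv"), index=False)
    prefix.with_name(prefix.name + "_params.json").write_text(
        json.dumps(es.generator_params, indent=2)
    )


def write_per_iteration(values: DataValues, path) -> None:
    """Store the per-iteration similarity array (source x recorded x runs)
    in HDF5; these arrays can be large, so CSV is not used."""
    import h5py

    if values.per_iteration is None:
        raise ValueError("values carry no per-iteration record")
    with h5py.File(path, "w") as f:
        f.create_dataset("similarities", data=values.per_iteration)
        f.attrs["method"] = values.method
        f.attrs["n_runs"] = values.n_runs


@dataclass
class RunConfig:
    """Fully serialisable description of a valuation run."""

    method: str = "dvgs"
    task: str = "classification"
    source_path: str | None = None
    target_path: str | None = None
    label_column: str | None = "label"
    hidden_dim: int = 100
    latent_dim: int = 32
    valuation: ValuationConfig = field(default_factory=ValuationConfig)
    out_path: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["valuation"]["loss"] = {
            "name": self.valuation.loss.name,
            "class_weights": (
                None if self.valuation.loss.class_weights is None
                else list(map(float, self.valuation.loss.class_weights))
            ),
        }
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        vc = dict(d.pop("valuation", {}))
        loss = vc.pop("loss", None)
        if isinstance(loss, dict):
            cw = loss.get("class_weights")
            vc["loss"] = LossSpec(loss.get("name", "cross_entropy"),
                                  None if cw is None else np.asarray(cw, dtype=float))
        elif isinstance(loss, str):
            vc["loss"] = LossSpec(loss)
        return cls(valuation=ValuationConfig(**vc), **d)
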