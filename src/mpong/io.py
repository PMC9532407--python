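"""File round-tripping with schema validation.

Tables travel as CSV with a schema tag comment on the first line
(``# mpong-schema: <name> v<version>``); parameters and model specs as JSON
with a ``"schema"`` key; tensors (frames, hidden states, model weights) as
HDF5. Floats are written at full precision (repr round-trip).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "save_tensors",
    "load_tensors",
    "save_model",
    "load_model",
]

SCHEMA_PREFIX = "# mpong-schema:"

#: known table schemas -> required columns
TABLE_SCHEMAS = {
    "conditions v1": ["id", "x0", "y0", "dx0", "dy0", "t_occ", "t_end",
                      "n_bounces", "y_final"],
    "trials v1": ["condition_id", "repetition", "paddle_y"],
    "error_vector v1": ["condition_id", "error"],
    "zoo_manifest v1": None,  # free-form wide table
}


class SchemaError(ValueError):
    """Schema tag or required column mismatch on read."""


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table schema {schema!r}")
    required = TABLE_SCHEMAS[schema]
    if required is not None:
        missing = set(required) - set(df.columns)
        if missing:
            raise SchemaError(f"missing columns for {schema!r}: {sorted(missing)}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX} {schema}\n")
        df.to_csv(fh, index=False, float_format=None)  # full repr precision


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith(SCHEMA_PREFIX):
            raise SchemaError(f"{path} has no schema tag")
        found = first[len(SCHEMA_PREFIX):].strip()
        if found != schema:
            raise SchemaError(f"{path}: expected schema {schema!r}, found {found!r}")
        df = pd.read_csv(fh, float_precision="round_trip")
    required = TABLE_SCHEMAS.get(schema)
    if required is not None:
        missing = set(required) - set(df.columns)
        if missing:
            raise SchemaError(f"{path} missing columns: {sorted(missing)}")
    return df


def write_json(obj: dict, path: str | Path, schema: str) -> None:
    payload = {"schema": schema, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path, schema: str) -> dict:
    payload = json.loads(Path(path).read_text())
    found = payload.pop("schema", None)
    if found != schema:
        raise SchemaError(f"{path}: expected schema {schema!r}, found {found!r}")
    return payload


def save_tensors(arrays: dict[str, np.ndarray], path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = "tensors v1"
        for name, arr in arrays.items():
            fh.create_dataset(name, data=np.asarray(arr, dtype=np.float32))


def load_tensors(path: str | Path) -> dict[str, np.ndarray]:
    out = {}
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("schema") != "tensors v1":
            raise SchemaError(f"{path}: not a tensors v1 file")
        for name in fh:
            out[name] = fh[name][...]
    return out


def save_encoder(enc, path: str | Path, input_scale: float = 1.0) -> None:
    """Fitted encoder (projection basis + mean) to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = "encoder v1"
        fh.attrs["kind"] = enc.kind
        fh.attrs["n_components"] = enc.n_components
        fh.attrs["downsample"] = enc.downsample
        fh.attrs["input_scale"] = input_scale
        fh.create_dataset("components", data=enc.components)
        fh.create_dataset("mean", data=enc.mean)
        fh.create_dataset(
            "explained_variance_ratio", data=enc.explained_variance_ratio
        )


def load_encoder(path: str | Path):
    """Rebuild a transform-capable encoder from its saved basis.

    Returns (encoder, input_scale). The rebuilt object supports
    ``transform`` (and everything derived from the basis) but not further
    incremental fitting.
    """
    from sklearn.decomposition import IncrementalPCA

    from .encoders import FrameEncoder

    with h5py.File(path, "r") as fh:
        if fh.attrs.get("schema") != "encoder v1":
            raise SchemaError(f"{path}: not an encoder v1 file")
        enc = FrameEncoder(
            kind=str(fh.attrs["kind"]),
            n_components=int(fh.attrs["n_components"]),
            downsample=int(fh.attrs["downsample"]),
        )
        ipca = IncrementalPCA(n_components=enc.n_components)
        ipca.components_ = fh["components"][...]
        ipca.mean_ = fh["mean"][...]
        ipca.explained_variance_ratio_ = fh["explained_variance_ratio"][...]
        enc._ipca = ipca
        return enc, float(fh.attrs["input_scale"])


def save_model(model, path: str | Path) -> None:
    """Model weights to HDF5 with the spec as a JSON sidecar attribute."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = "rnn_model v1"
        fh.attrs["spec"] = json.dumps(model.spec.to_dict())
        for name, arr in model.params().items():
            fh.create_dataset(name, data=arr)


def load_model(path: str | Path):
    from .rnn_zoo import ModelSpec, RNNModel

    with h5py.File(path, "r") as fh:
        if fh.attrs.get("schema") != "rnn_model v1":
            raise SchemaError(f"{path}: not an rnn_model v1 file")
        spec_dict = json.loads(fh.attrs["spec"])
        spec_dict["dyn_reg_weights"] = tuple(spec_dict["dyn_reg_weights"])
        spec = ModelSpec(**spec_dict)
        params = {name: fh[name][...] for name in fh}
    return RNNModel(spec=spec, **params)
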