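"""Delimited-text and structured-text I/O with reproducibility metadata.

Every table written by the pipeline carries a commented metadata header
(``# key: value`` lines) holding the seeds and a hash of the run config, so
outputs are self-describing and byte-identical under identical configs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml


def meta_header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                float_format: str = "%.6f") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(meta_header(meta))
        df.to_csv(fh, index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_yaml(obj: dict, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = dict(obj)
    if meta:
        doc["_meta"] = dict(meta)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return doc


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
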