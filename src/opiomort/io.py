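"""Delimited-text output with a config-hash audit line.

Every pipeline output table starts with a ``# config_hash: …`` comment so a
result file can always be traced to the exact run configuration; readers
skip comment lines.
"""

from __future__ import annotations

import hashlib

import pandas as pd
import yaml


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(config_dict, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
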