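"""Readers for the plain-text study-input formats written by the generator."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from skbio import TreeNode

from .energetics import DLWRecord

_DLW_META = {"subject_id", "timepoint"}


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)

def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_gas_trace(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_dlw(path: str | Path) -> dict[str, DLWRecord]:
    """DLW CSV -> {"<subject>_<timepoint>": DLWRecord}."""
    df = pd.read_csv(path)
    records = {}
    for _, row in df.iterrows():
        key = f"{row['subject_id']}_{row['timepoint']}"
        fields = {k: v for k, v in row.items() if k not in _DLW_META}
        records[key] = DLWRecord(**fields)
    return records


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Species-by-sample TSV -> samples x species relative-abundance frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def read_tree(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))
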