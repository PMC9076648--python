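"""TSV readers and writers shared by all pipeline stages.

Every matrix is written as TSV with the row-id in the first column, so
all outputs are plain text and round-trip through the same functions.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.12g"


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_peak_list(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_peak_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"mz", "intensity", "sn"} - set(df.columns)
    if missing:
        raise ValueError(f"peak list {path} missing columns {sorted(missing)}")
    return df


def read_peak_dir(directory) -> dict[str, pd.DataFrame]:
    """Read every ``*.tsv`` peak list in a directory; the stem is the
    sample id."""
    out = {}
    for path in sorted(Path(directory).glob("*.tsv")):
        out[path.stem] = read_peak_list(path)
    return out
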