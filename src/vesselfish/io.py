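"""File formats: TIFF round stacks, transcript CSV, transform JSON.

Round stacks are written one TIFF per (round, channel) with the
filename pattern ``R{round}_C{channel}.tif`` (1-based in filenames,
0-based in memory).  All coordinates in tables are 0-based pixels with
z in plane indices.
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .decoding import TRANSCRIPT_COLUMNS

__all__ = [
    "write_roundstacks",
    "read_roundstacks",
    "write_transcripts",
    "read_transcripts",
    "file_sha256",
]

_STACK_RE = re.compile(r"^R(\d+)_C(\d+)\.tif$")


def write_roundstacks(stacks: dict[tuple[int, int], np.ndarray], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for (r, c), stack in sorted(stacks.items()):
        path = directory / f"R{r + 1}_C{c + 1}.tif"
        tifffile.imwrite(path, np.asarray(stack, dtype=np.float32), photometric="minisblack")
        paths.append(path)
    return paths


def read_roundstacks(directory) -> dict[tuple[int, int], np.ndarray]:
    directory = Path(directory)
    stacks = {}
    for path in sorted(directory.iterdir()):
        m = _STACK_RE.match(path.name)
        if m:
            stacks[(int(m.group(1)) - 1, int(m.group(2)) - 1)] = tifffile.imread(path)
    if not stacks:
        raise FileNotFoundError(f"no R*_C*.tif stacks under {directory}")
    return stacks


def write_transcripts(table: pd.DataFrame, path) -> None:
    table[TRANSCRIPT_COLUMNS].to_csv(path, index=False)


def read_transcripts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRANSCRIPT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transcript table missing columns: {sorted(missing)}")
    return df


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
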