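"""Shared delimited-text reading with exact float round-trip."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def sniff_sep(path) -> str:
    """Detect comma vs. tab from the first non-empty line."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "\t" if line.count("\t") >= line.count(",") else ","
    raise ValueError(f"{path}: empty file")


def read_delimited(path, **kwargs) -> pd.DataFrame:
    """pandas.read_csv with delimiter sniffing and correctly-rounded floats.

    The default pandas float parser loses the last ulp, which breaks
    write-then-read determinism checks; ``float_precision='round_trip'``
    restores exactness.
    """
    path = Path(path)
    return pd.read_csv(path, sep=sniff_sep(path),
                       float_precision="round_trip", **kwargs)
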