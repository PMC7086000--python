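"""Gray-matter parcellation: the node set of the structural connectome.

A parcellation is an ordered list of region names with hemisphere labels;
row/column order of every matrix and volume table in the package follows it.
Internal indexing is 0-based; files always carry region names so external
1-based conventions never leak in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

HEMISPHERES = ("left", "right", "midline")


@dataclass(frozen=True)
class Parcellation:
    """Ordered set of brain regions.

    Parameters
    ----------
    region_names : tuple of str
        Unique region labels; position defines the 0-based region index.
    hemispheres : tuple of str
        One of ``left``, ``right`` or ``midline`` per region.
    """

    region_names: tuple
    hemispheres: tuple = field(default=())

    def __post_init__(self):
        names = tuple(self.region_names)
        hemis = tuple(self.hemispheres) if self.hemispheres else ("midline",) * len(names)
        if len(names) < 2:
            raise ValueError("parcellation needs at least 2 regions")
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        if len(hemis) != len(names):
            raise ValueError("hemisphere list length mismatch")
        bad = sorted(set(hemis) - set(HEMISPHERES))
        if bad:
            raise ValueError(f"unknown hemisphere labels: {bad}")
        object.__setattr__(self, "region_names", names)
        object.__setattr__(self, "hemispheres", hemis)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def index_of(self, name: str) -> int:
        return self.region_names.index(name)

    @classmethod
    def generic(cls, n_regions: int) -> "Parcellation":
        """Anonymous bilateral parcellation used by the synthetic generator."""
        names, hemis = [], []
        for i in range(n_regions):
            side = "lh" if i % 2 == 0 else "rh"
            names.append(f"{side}_region_{i // 2:03d}")
            hemis.append("left" if side == "lh" else "right")
        return cls(tuple(names), tuple(hemis))

    @classmethod
    def read(cls, path) -> "Parcellation":
        """Read a two-column delimited file (region_name, hemisphere).

        Row order defines the index order. Comma or tab delimited,
        auto-detected; no header.
        """
        from ._io import read_delimited
        df = read_delimited(path, header=None, comment="#", skip_blank_lines=True)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (region_name, hemisphere)")
        return cls(tuple(df.iloc[:, 0].astype(str)), tuple(df.iloc[:, 1].astype(str)))

    def write(self, path) -> None:
        pd.DataFrame({"region": self.region_names, "hemisphere": self.hemispheres}) \
            .to_csv(Path(path), sep="\t", header=False, index=False)
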