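"""Amino-acid descriptor scales and composition classes.

Ten published descriptor families — Cruciani properties (PP, 3), Kidera
factors (KF, 10), Z-scales (Z, 5), FASGAI (F, 6), T-scales (T, 5), VHSE (8),
ProtFP (8), ST-scales (ST, 8), BLOSUM indices (BLOSUM, 10) and MS-WHIM
(MSWHIM, 3) — give 66 real-valued components per residue. They are bundled as
a plain-text table and loaded once per process.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from ._residues import AA_SET, CLASS_NAMES, STANDARD_AA

FAMILY_SIZES = {
    "PP": 3, "KF": 10, "Z": 5, "F": 6, "T": 5,
    "VHSE": 8, "ProtFP": 8, "ST": 8, "BLOSUM": 10, "MSWHIM": 3,
}
N_COMPONENTS = 66


@dataclass(frozen=True)
class DescriptorTable:
    """66 descriptor components for the 20 standard residues.

    ``values`` is indexed by residue with one column per component; component
    names follow the ``<family><k>`` convention used in the field ("KF2",
    "VHSE6", "PP1", ...).
    """

    values: pd.DataFrame

    @property
    def components(self) -> list[str]:
        return list(self.values.columns)

    def lookup(self, residue: str, component: str) -> float:
        if component not in self.values.columns:
            raise KeyError(f"unknown descriptor component {component!r}")
        if residue not in AA_SET:
            raise ValueError(f"non-standard residue {residue!r}")
        return float(self.values.at[residue, component])

    def matrix(self) -> np.ndarray:
        """(20, 66) array ordered by :data:`STANDARD_AA` rows."""
        return self.values.loc[list(STANDARD_AA)].to_numpy(dtype=float)


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("neodl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="residue")


@lru_cache(maxsize=1)
def load_descriptor_table() -> DescriptorTable:
    df = _read_bundled("aa_descriptors.tsv")
    expected = [
        f"{fam}{i}" for fam, n in FAMILY_SIZES.items() for i in range(1, n + 1)
    ]
    if list(df.columns) != expected:
        raise RuntimeError("bundled descriptor table does not match the pinned layout")
    if sorted(df.index) != sorted(STANDARD_AA):
        raise RuntimeError("bundled descriptor table must cover the 20 standard residues")
    if not np.isfinite(df.to_numpy()).all():
        raise RuntimeError("bundled descriptor table contains non-finite values")
    return DescriptorTable(values=df)


@lru_cache(maxsize=1)
def load_class_table() -> pd.DataFrame:
    """Binary membership of each residue in the 9 composition classes."""
    df = _read_bundled("aa_classes.tsv")
    if tuple(df.columns) != CLASS_NAMES:
        raise RuntimeError("bundled class table does not match the pinned class list")
    return df.loc[list(STANDARD_AA)].astype(int)
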