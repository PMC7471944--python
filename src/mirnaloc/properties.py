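"""Dinucleotide physico-chemical property table and the DiPro encoder.

Eleven RNA dinucleotide properties — twist, rise, shift, tilt, slide, roll,
stacking energy, hydrophilicity, enthalpy, entropy and free energy — are
tabulated per dinucleotide; hydrophilicity, enthalpy, entropy and free energy
each come in two published determinations, giving 15 property columns over
the 16 dinucleotides AA..UU.  The DiPro encoding maps a sequence to the mean
of each property over its overlapping dinucleotides (15 features).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from mirnaloc.sequence_io import RnaSequence, dinucleotides

DINUCLEOTIDES = tuple(a + b for a, b in itertools.product("ACGU", repeat=2))

PROPERTY_NAMES = (
    "twist",
    "rise",
    "shift",
    "tilt",
    "slide",
    "roll",
    "stacking_energy",
    "hydrophilicity_1",
    "hydrophilicity_2",
    "enthalpy_1",
    "enthalpy_2",
    "entropy_1",
    "entropy_2",
    "free_energy_1",
    "free_energy_2",
)

_ASSET = "rna_dinucleotide_properties.tsv"


@dataclass(frozen=True)
class PropertyTable:
    """16 dinucleotides x 15 named property values, raw or standardized.

    The standardized view rescales each property to mean 0 and standard
    deviation 1 over the 16 dinucleotides; it is what the PseDNC correlation
    consumes, while the DiPro encoder averages raw values.
    """

    values: pd.DataFrame  # index: dinucleotide, columns: property names
    standardized: bool = False

    def __post_init__(self) -> None:
        if list(self.values.index) != list(DINUCLEOTIDES):
            raise ValueError(
                "property table must have exactly the 16 dinucleotide rows "
                "AA..UU in lexicographic order"
            )
        if self.values.shape[1] != 15:
            raise ValueError(
                f"property table must have 15 columns, got {self.values.shape[1]}"
            )
        if self.values.isna().any().any():
            raise ValueError("property table contains missing values")

    @property
    def property_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def base_property_names(self) -> tuple[str, ...]:
        """The 11 distinct names after collapsing the _1/_2 variants."""
        seen: dict[str, None] = {}
        for name in self.values.columns:
            base = name[:-2] if name.endswith(("_1", "_2")) else name
            seen.setdefault(base, None)
        return tuple(seen)

    def row(self, dinucleotide: str) -> np.ndarray:
        if dinucleotide not in self.values.index:
            raise KeyError(f"unknown dinucleotide {dinucleotide!r}")
        return self.values.loc[dinucleotide].to_numpy()


def load_default_table() -> PropertyTable:
    """Load the embedded RNA dinucleotide property table (raw view).

    The asset ships with the package; see the header of the TSV for sources
    and the documented _1/_2 mapping of duplicate properties.
    """
    ref = resources.files("mirnaloc.data").joinpath(_ASSET)
    with resources.as_file(ref) as path:
        return load_table(path)


def load_table(path: str | Path) -> PropertyTable:
    """Load a property table from TSV (16 rows x 15 named columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    try:
        df = df.loc[list(DINUCLEOTIDES)]
    except KeyError as exc:
        raise ValueError(f"property table at {path} is missing dinucleotide rows: {exc}")
    return PropertyTable(values=df.astype(float), standardized=False)


def write_table(table: PropertyTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="dinucleotide")


def standardize(table: PropertyTable) -> PropertyTable:
    """Z-score each property over its 16 dinucleotide values.

    Uses the population standard deviation (divisor 16).  Idempotent up to
    floating point; a zero-variance property is an error.
    """
    values = table.values
    sd = values.std(axis=0, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance property column(s): {flat}")
    z = (values - values.mean(axis=0)) / sd
    return PropertyTable(values=z, standardized=True)


def dipro_encode(seq: RnaSequence, table: PropertyTable) -> pd.Series:
    """DiPro feature vector: per-property mean over the sequence's dinucleotides.

    Returns a Series of 15 values named by property.  Averages the raw table;
    standardization belongs only in the PseDNC correlation.
    """
    dins = dinucleotides(seq)
    mat = table.values.loc[dins].to_numpy()
    return pd.Series(mat.mean(axis=0), index=table.values.columns, name=seq.id)
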