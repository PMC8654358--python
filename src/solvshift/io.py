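"""Quantification-table and design-file I/O.

The canonical on-disk dialect is tab-separated text with a header row
(comma is accepted on read via sniffing).  A quantification table has one
row per protein: a ``protein`` identifier column, a ``peptides`` count
column, and one abundance column per TMT channel (summed reporter
signal-to-noise, non-negative).  The companion design file maps each
channel to its experimental role: ``channel, condition, replicate,
gradient, unit``.  Gradient units are declared (``%AEA`` or ``degC``),
never inferred; for pooled PISA samples the gradient cell is left empty
and the unit is ``pooled``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["QuantTable", "read_quant_table", "read_design", "write_quant_table"]

DESIGN_COLUMNS = ["channel", "condition", "replicate", "gradient", "unit"]


def _read_delimited(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep)


@dataclass
class QuantTable:
    """Protein x channel abundance matrix with peptide counts and a design.

    ``data`` is indexed by protein identifier with one float column per
    channel; ``peptides`` is the per-protein peptide count; ``design`` maps
    channels to (condition, replicate, gradient, unit).  ``flags`` records
    proteins whose rows failed validation (kept, never silently dropped).
    """

    data: pd.DataFrame
    peptides: pd.Series
    design: pd.DataFrame
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.design = self.design.reset_index(drop=True)
        if self.design["channel"].duplicated().any():
            dups = self.design["channel"][self.design["channel"].duplicated()]
            raise ValueError(f"duplicate channel labels in design: {sorted(set(dups))}")
        missing = [c for c in self.data.columns if c not in set(self.design["channel"])]
        if missing:
            raise ValueError(f"abundance columns not mapped in design: {missing}")
        extra = [c for c in self.design["channel"] if c not in self.data.columns]
        if extra:
            raise ValueError(f"design channels absent from table: {extra}")
        if self.data.index.duplicated().any():
            dups = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise ValueError(f"duplicate protein identifiers: {dups}")
        neg = (self.data < 0).any(axis=1)
        for prot in self.data.index[neg]:
            self.flags.setdefault(str(prot), "negative abundance")
        self.data = self.data.mask(self.data < 0)
        self.peptides = self.peptides.reindex(self.data.index)

    # -- structure -------------------------------------------------------
    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    def experiments(self) -> list[tuple[str, str]]:
        """(condition, replicate) pairs, in design order."""
        seen: list[tuple[str, str]] = []
        for _, row in self.design.iterrows():
            key = (str(row["condition"]), str(row["replicate"]))
            if key not in seen:
                seen.append(key)
        return seen

    def channels(self, condition: str, replicate: str) -> pd.DataFrame:
        """Design rows for one experiment, ordered by gradient value."""
        sel = self.design[
            (self.design["condition"].astype(str) == str(condition))
            & (self.design["replicate"].astype(str) == str(replicate))
        ]
        if "gradient" in sel and sel["gradient"].notna().any():
            sel = sel.sort_values("gradient")
        return sel.reset_index(drop=True)

    def gradient(self, condition: str, replicate: str) -> np.ndarray:
        return self.channels(condition, replicate)["gradient"].to_numpy(float)

    def abundances(self, condition: str, replicate: str) -> pd.DataFrame:
        """Protein x gradient-ordered channel block for one experiment."""
        order = self.channels(condition, replicate)["channel"].tolist()
        return self.data[order]


def read_design(path) -> pd.DataFrame:
    design = _read_delimited(path)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design file {path} lacks columns: {missing}")
    design = design[DESIGN_COLUMNS].copy()
    design["channel"] = design["channel"].astype(str)
    design["gradient"] = pd.to_numeric(design["gradient"], errors="coerce")
    return design


def read_quant_table(path, design_path) -> QuantTable:
    """Read and validate a quantification table against its design file.

    Unparseable abundance cells become missing and flag the protein; rows
    are never dropped here.  A design/column mismatch or duplicated protein
    identifiers raise with the offending names.
    """
    design = read_design(design_path)
    raw = _read_delimited(path)
    if "protein" not in raw.columns:
        raise ValueError(f"{path}: missing 'protein' column")
    raw = raw.set_index("protein")
    if "peptides" in raw.columns:
        peptides = pd.to_numeric(raw["peptides"], errors="coerce")
    else:
        peptides = pd.Series(np.nan, index=raw.index, name="peptides")
    chan_cols = [c for c in raw.columns if c != "peptides"]

    data = raw[chan_cols].apply(pd.to_numeric, errors="coerce")
    flags: dict[str, str] = {}
    bad = data.isna() & raw[chan_cols].notna()
    for prot in data.index[bad.any(axis=1)]:
        flags[str(prot)] = "unparseable abundance"
    return QuantTable(data=data, peptides=peptides, design=design, flags=flags)


def write_quant_table(table: QuantTable, path, design_path) -> None:
    out = table.data.copy()
    out.insert(0, "peptides", table.peptides)
    out.to_csv(path, sep="\t", index_label="protein")
    table.design.to_csv(design_path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Generic delimited-table reader (TSV canonical, CSV accepted)."""
    return _read_delimited(path)
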