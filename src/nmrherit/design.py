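"""Experimental design: mapping of field plots to lines, environments,
trials and malting batches.

An *environment* is a location x year combination; trials are nested within
environments and malting batches group plots processed together in the lab.
The design defines every incidence matrix of the variance-component models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("plot", "line", "location", "year", "trial", "batch")


@dataclass
class PlotDesign:
    """One row per plot; columns plot, line, location, year, trial, batch."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.table["plot"].duplicated().any():
            raise ValueError("duplicate plot ids in design")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_plots(self) -> int:
        return len(self.table)

    @property
    def plot_ids(self) -> np.ndarray:
        return self.table["plot"].to_numpy()

    @property
    def line_ids(self) -> np.ndarray:
        return self.table["line"].to_numpy()

    def environment(self) -> pd.Series:
        """Environment id = location x year."""
        t = self.table
        return t["location"].astype(str) + ":" + t["year"].astype(str)

    def cell(self) -> pd.Series:
        """Fixed-effect cell id = location x year x trial."""
        return self.environment() + ":" + self.table["trial"].astype(str)

    def n_environments(self) -> int:
        return self.environment().nunique()

    def mean_replicates(self) -> float:
        return self.n_plots / self.table["line"].nunique()

    def subset(self, row_mask: np.ndarray) -> "PlotDesign":
        return PlotDesign(self.table.loc[row_mask].reset_index(drop=True))


def read_design_tsv(path) -> tuple[PlotDesign, pd.DataFrame]:
    """Read a design(+traits) TSV; trait columns are everything beyond the
    required design columns.  Returns the design and a plot-indexed trait
    table (possibly empty)."""
    df = pd.read_csv(path, sep="\t")
    design = PlotDesign(df[list(REQUIRED_COLUMNS)].copy())
    trait_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    traits = df[["plot"] + trait_cols].set_index("plot") if trait_cols else pd.DataFrame(
        index=df["plot"]
    )
    return design, traits


def write_design_tsv(design: PlotDesign, path, traits: pd.DataFrame | None = None) -> None:
    out = design.table.copy()
    if traits is not None:
        out = out.merge(traits, left_on="plot", right_index=True, how="left")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
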