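"""Species-level trait ingestion and genus-level aggregation.

The comparative analyses run on three genus-level characteristics derived
from a species-level table: species richness (the number of constituent
species), mean range size and mean abundance, each also carried on the
log10 scale, which is the scale every downstream analysis uses.

A genus table is a :class:`pandas.DataFrame` indexed by genus with columns

    species_richness, mean_range_size, mean_abundance,
    log10_species_richness, log10_mean_range_size, log10_mean_abundance

Missing range or abundance cells are NaN, never zero: a genus has a mean
abundance only when at least one constituent species has an estimate, and
analyses of that trait simply drop the genera without one (per-trait
matching, not listwise deletion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError, TableParseError
from .phylo_core import Phylogeny, prune_to_taxa

__all__ = [
    "SpeciesRecord",
    "RAW_TRAITS",
    "LOG_TRAITS",
    "load_species_table",
    "aggregate_to_genus",
    "log10_transform",
    "match_tree_and_traits",
    "read_genus_table",
    "write_genus_table",
]

RAW_TRAITS = ("species_richness", "mean_range_size", "mean_abundance")
LOG_TRAITS = tuple(f"log10_{t}" for t in RAW_TRAITS)


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: its genus, name, and (optionally) range size and abundance."""

    genus: str
    species: str
    range_size: float | None = None
    abundance: float | None = None

    def __post_init__(self):
        if not self.genus or not self.species:
            raise TableParseError("genus and species names must be non-empty")
        for field in ("range_size", "abundance"):
            v = getattr(self, field)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise TableParseError(
                    f"{field} must be a non-negative number, got {v!r} "
                    f"for {self.genus} {self.species}"
                )


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def load_species_table(path) -> list[SpeciesRecord]:
    """Read a delimited species table (columns genus, species, range_size,
    abundance; the two trait columns may have empty cells)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"genus", "species"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        vals = {}
        for col in ("range_size", "abundance"):
            if col not in df.columns or pd.isna(row[col]):
                vals[col] = None
            else:
                try:
                    vals[col] = float(row[col])
                except (TypeError, ValueError) as exc:
                    raise TableParseError(
                        f"non-numeric {col} at row {idx + 2}: {row[col]!r}"
                    ) from exc
        try:
            records.append(
                SpeciesRecord(str(row["genus"]), str(row["species"]), **vals)
            )
        except TableParseError as exc:
            raise TableParseError(f"row {idx + 2}: {exc}") from exc
    return records


def aggregate_to_genus(records: Iterable[SpeciesRecord]) -> pd.DataFrame:
    """Genus-level characteristics: richness is the species count; the mean
    range size and abundance average over species with a value (a genus
    lacking any abundance estimate gets NaN, and drops out of abundance
    analyses only)."""
    records = list(records)
    if not records:
        raise ValueError("no species records to aggregate")
    df = pd.DataFrame(
        {
            "genus": [r.genus for r in records],
            "range_size": [np.nan if r.range_size is None else r.range_size for r in records],
            "abundance": [np.nan if r.abundance is None else r.abundance for r in records],
        }
    )
    grouped = df.groupby("genus", sort=True)
    out = pd.DataFrame(
        {
            "species_richness": grouped.size(),
            "mean_range_size": grouped["range_size"].mean(),
            "mean_abundance": grouped["abundance"].mean(),
        }
    )
    out.index.name = "genus"
    return log10_transform(out)


def log10_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Populate the log10 columns; NaN stays NaN, non-positive values raise."""
    out = table.copy()
    for raw, logcol in zip(RAW_TRAITS, LOG_TRAITS):
        if raw not in out.columns:
            continue
        vals = out[raw].astype(float)
        bad = vals[(vals <= 0) & vals.notna()]
        if len(bad):
            raise ValueError(
                f"cannot log10-transform non-positive {raw} for genus "
                f"{bad.index[0]!r} (value {bad.iloc[0]})"
            )
        out[logcol] = np.log10(vals)
    return out


def match_tree_and_traits(
    tree: Phylogeny, table: pd.DataFrame, trait: str
) -> tuple[Phylogeny, np.ndarray]:
    """Prune the tree to the genera with data for ``trait`` and return the
    trait vector in the pruned tree's tip order."""
    if trait not in table.columns:
        raise SchemaError(f"trait column {trait!r} not in the genus table")
    with_data = set(table.index[table[trait].notna()])
    shared = [l for l in tree.tip_labels if l in with_data]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} genera shared between tree and {trait!r} data; need >= 3"
        )
    if len(shared) == tree.n_tips:
        pruned = tree
    else:
        pruned = prune_to_taxa(tree, shared)
    x = table.loc[pruned.tip_labels, trait].to_numpy(dtype=float)
    return pruned, x


def read_genus_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "genus" not in df.columns:
        raise SchemaError("genus table needs a 'genus' column")
    return df.set_index("genus")


def write_genus_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep=_sep_for(path), float_format="%.10g")
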