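"""Tabular input/output for OTU tables, water-chemistry metadata and network files.

All on-disk formats are tab-separated UTF-8 text with "." as the decimal
separator.  OTU tables have OTU ids in the first column, sample ids in the
header row, and an optional trailing ``taxonomy`` column holding
semicolon-delimited lineage strings.  Water-chemistry tables follow the layout
of a field campaign summary table (one row per sample), where concentrations
below the instrument detection limit are written ``<x`` and parsed into
:class:`BelowDetection` markers that keep the limit for downstream policy
decisions rather than substituting a number at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "BelowDetection",
    "WaterChemistryRecord",
    "read_otu_table",
    "write_otu_table",
    "read_metadata_table",
    "write_network_files",
]


@dataclass
class OtuTable:
    """An integer count matrix of OTUs (rows) by samples (columns).

    Parameters
    ----------
    otu_ids : sequence of str
        Row identifiers, unique, in file order.
    sample_ids : sequence of str
        Column identifiers, unique, in file order.
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative integer read counts.
    taxonomy : mapping of str to str, optional
        Lineage string (``domain;phylum;class;order;family;genus``) per OTU.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        self.sample_ids = list(self.sample_ids)
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at OTU {self.otu_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.otu_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def lineage(self, otu_id: str) -> str | None:
        if self.taxonomy is None:
            return None
        return self.taxonomy.get(otu_id)

    def select_otus(self, keep: Sequence[str]) -> "OtuTable":
        """Return a new table restricted to ``keep`` (order preserved from self)."""
        keep_set = set(keep)
        idx = [i for i, o in enumerate(self.otu_ids) if o in keep_set]
        taxonomy = None
        if self.taxonomy is not None:
            taxonomy = {o: self.taxonomy[o] for o in (self.otu_ids[i] for i in idx) if o in self.taxonomy}
        return OtuTable(
            [self.otu_ids[i] for i in idx], list(self.sample_ids), self.counts[idx], taxonomy
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class BelowDetection:
    """A concentration below the instrument detection limit, keeping the limit."""

    limit: float

    def __post_init__(self) -> None:
        if not (self.limit > 0):
            raise ValueError(f"detection limit must be positive, got {self.limit}")


Concentration = float | BelowDetection


@dataclass
class WaterChemistryRecord:
    """One sample's physico-chemical and biological measurements.

    Concentrations (mg/L) may be :class:`BelowDetection` markers.  Densities
    are in the field-sheet units: bacterial density in 1e8 cells/L, algal
    density in 1e7 cells/L.
    """

    sample_id: str
    T: float | None = None
    DO: float | None = None
    pH: float | None = None
    turbidity: float | None = None
    suspended_particles: float | None = None
    NO3_N: Concentration | None = None
    NO2_N: Concentration | None = None
    NH4_N: Concentration | None = None
    TN: Concentration | None = None
    PO4_P: Concentration | None = None
    COD: Concentration | None = None
    bacterial_density: float | None = None
    algal_density: float | None = None

    def __post_init__(self) -> None:
        for name in _CONCENTRATION_FIELDS:
            v = getattr(self, name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"{name} negative for sample {self.sample_id!r}: {v}")


_CONCENTRATION_FIELDS = (
    "NO3_N", "NO2_N", "NH4_N", "TN", "PO4_P", "COD",
)

# Header aliases accepted in metadata files (case-insensitive, "-"/"_" folded).
_METADATA_ALIASES = {
    "sample": "sample_id",
    "sampleid": "sample_id",
    "t": "T",
    "temperature": "T",
    "do": "DO",
    "dissolvedoxygen": "DO",
    "ph": "pH",
    "tur": "turbidity",
    "turbidity": "turbidity",
    "sp": "suspended_particles",
    "suspendedparticles": "suspended_particles",
    "no3n": "NO3_N",
    "no2n": "NO2_N",
    "nh4n": "NH4_N",
    "tn": "TN",
    "totalnitrogen": "TN",
    "po4p": "PO4_P",
    "cod": "COD",
    "bac": "bacterial_density",
    "bacterialdensity": "bacterial_density",
    "algae": "algal_density",
    "algaldensity": "algal_density",
}
# Derived columns silently ignored on read (recomputed by this package).
_METADATA_IGNORED = {"ei"}
_NUMERIC_ONLY_FIELDS = {
    "T", "DO", "pH", "turbidity", "suspended_particles",
    "bacterial_density", "algal_density",
}


def _canonical_header(name: str) -> str | None:
    key = "".join(ch for ch in name.lower() if ch.isalnum())
    if key in _METADATA_IGNORED:
        return None
    if key not in _METADATA_ALIASES:
        raise ValueError(f"unrecognized metadata column {name!r}")
    return _METADATA_ALIASES[key]


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a tab-separated OTU count table, validating every cell.

    The first column holds OTU ids, the header row sample ids; an optional
    final ``taxonomy`` column holds lineage strings.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False, na_values=[])
    taxonomy = None
    if len(df.columns) and df.columns[-1].lower() == "taxonomy":
        taxonomy = dict(zip(df.index, df.iloc[:, -1]))
        df = df.iloc[:, :-1]
    counts = np.empty(df.shape, dtype=np.int64)
    for i, otu in enumerate(df.index):
        for j, sample in enumerate(df.columns):
            cell = df.iat[i, j].strip()
            try:
                value = int(cell)
            except ValueError:
                raise ValueError(
                    f"non-integer cell {cell!r} at OTU {otu!r}, sample {sample!r}"
                ) from None
            if value < 0:
                raise ValueError(f"negative count {value} at OTU {otu!r}, sample {sample!r}")
            counts[i, j] = value
    return OtuTable(list(df.index), list(df.columns), counts, taxonomy)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write a table in the dialect accepted by :func:`read_otu_table`."""
    df = table.to_frame()
    if table.taxonomy is not None:
        df = df.copy()
        df["taxonomy"] = [table.taxonomy.get(o, "") for o in table.otu_ids]
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def _parse_concentration(cell: str, sample: str, variable: str) -> Concentration:
    cell = cell.strip()
    if not cell:
        raise ValueError(f"empty cell for sample {sample!r}, variable {variable!r}")
    if cell.startswith("<"):
        try:
            limit = float(cell[1:])
        except ValueError:
            raise ValueError(
                f"unparseable below-detection cell {cell!r} for sample {sample!r}, "
                f"variable {variable!r}"
            ) from None
        return BelowDetection(limit)
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"unparseable cell {cell!r} for sample {sample!r}, variable {variable!r}"
        ) from None


def read_metadata_table(path: str | Path) -> list[WaterChemistryRecord]:
    """Read a water-chemistry metadata table into one record per sample.

    Cells of the form ``<x`` become :class:`BelowDetection` markers carrying
    the limit ``x``; numeric cells become floats; empty cells are an error.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str,
                     keep_default_na=False, na_values=[])
    fields: list[str | None] = [_canonical_header(c) for c in df.columns]
    if "sample_id" not in fields:
        raise ValueError("metadata table has no sample id column")
    records = []
    for _, row in df.iterrows():
        kwargs: dict[str, object] = {}
        for raw_name, field_name in zip(df.columns, fields):
            if field_name is None:
                continue
            cell = str(row[raw_name]).strip()
            if field_name == "sample_id":
                kwargs["sample_id"] = cell
                continue
            sample = str(row[df.columns[fields.index("sample_id")]])
            value = _parse_concentration(cell, sample, raw_name)
            if field_name in _NUMERIC_ONLY_FIELDS and isinstance(value, BelowDetection):
                raise ValueError(
                    f"below-detection marker not allowed for {raw_name!r} "
                    f"(sample {sample!r})"
                )
            kwargs[field_name] = value
        records.append(WaterChemistryRecord(**kwargs))
    return records


def write_network_files(net, roles, edge_path: str | Path, node_path: str | Path) -> None:
    """Write Cytoscape-style edge and node attribute tables for a network.

    ``roles`` is a sequence of NodeRoleRecord covering every node; ordering in
    both files is lexicographic by id so reruns are byte-identical.
    """
    role_by_id = {r.otu_id: r for r in roles}
    missing = [n for n in net.graph.nodes if n not in role_by_id]
    if missing:
        raise ValueError(f"role record missing for nodes: {sorted(missing)[:5]}")
    edge_rows = []
    for u, v, data in net.graph.edges(data=True):
        a, b = sorted((u, v))
        edge_rows.append((a, b, data["correlation"], data["sign"]))
    edge_rows.sort()
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tcorrelation\tsign\n")
        for a, b, r, sign in edge_rows:
            fh.write(f"{a}\t{b}\t{r:.6f}\t{sign}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tmodule\tdegree\tZi\tPi\trole\ttaxonomy\n")
        for otu_id in sorted(net.graph.nodes):
            rec = role_by_id[otu_id]
            lineage = ""
            if getattr(net, "taxonomy", None):
                lineage = net.taxonomy.get(otu_id, "")
            fh.write(
                f"{otu_id}\t{rec.module_id}\t{rec.degree}\t{rec.zi:.4f}\t"
                f"{rec.pi:.4f}\t{rec.role}\t{lineage}\n"
            )
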