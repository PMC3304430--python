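"""Readers, writers and validation for the tabular formats the pipeline touches.

All chip-level data move as plain TSV (probe/probe-set identifiers in the
first column, sample identifiers in the header); gene sets as GMT; sample
sheets, cytokine panels, qPCR and growth tables as CSV.  Everything is
validated on read and written back with a header line in UTF-8.  Binary
Affymetrix CEL/CDF parsing is deliberately out of scope: the analysis
operates on intensities, and TSV keeps the pipeline dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

HUMAN = "human"
MOUSE = "mouse"
SPECIES = (HUMAN, MOUSE)

RNA_SOURCES = ("human_only", "mouse_only", "xenograft")
GROUPS = ("untreated", "treated")


class FormatError(ValueError):
    """A file violated the format contract; the message names the offender."""


def _check_species(species: str) -> str:
    if species not in SPECIES:
        raise FormatError(f"unknown chip species {species!r}; expected one of {SPECIES}")
    return species


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ProbeIntensityMatrix:
    """Linear-scale probe x sample fluorescence intensities for one chip species.

    Invariants: strictly positive values, unique probe and sample identifiers.
    """

    chip_species: str
    values: pd.DataFrame  # probes x samples, float, linear scale

    def __post_init__(self) -> None:
        _check_species(self.chip_species)
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate probe_id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric intensity values")
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite intensity at probe {idx[r]!r}, sample {self.values.columns[c]!r}"
            )
        if np.any(arr <= 0):
            r, c = np.argwhere(arr <= 0)[0]
            raise FormatError(
                f"non-positive intensity at probe {idx[r]!r}, sample {self.values.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProbesetMap:
    """probe -> probe set (many-to-one) and probe set -> gene symbol annotation.

    A probe set without a gene symbol represents an uncharacterised EST.
    """

    chip_species: str
    probe_to_set: Mapping[str, str]
    set_to_symbol: Mapping[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_species(self.chip_species)
        self.probe_to_set = dict(self.probe_to_set)
        self.set_to_symbol = dict(self.set_to_symbol)
        if not self.probe_to_set:
            raise FormatError("probe-set map is empty")

    @property
    def probeset_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ps in self.probe_to_set.values():
            seen.setdefault(ps, None)
        return list(seen)

    def probes_of(self, probeset_id: str) -> list[str]:
        return [p for p, s in self.probe_to_set.items() if s == probeset_id]

    def symbol_of(self, probeset_id: str) -> str | None:
        return self.set_to_symbol.get(probeset_id)


@dataclass
class SampleSheet:
    """Per-sample design: chip species, RNA source and treatment group.

    The (chip_species, rna_source) pairs are limited to the four control
    configurations (own- and other-species RNA on each chip) plus xenograft
    samples; only xenograft samples carry a treatment group.
    """

    table: pd.DataFrame  # columns: sample_id, chip_species, rna_source, group, replicate

    REQUIRED = ("sample_id", "chip_species", "rna_source", "group", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        for i, row in t.iterrows():
            if row["chip_species"] not in SPECIES:
                raise FormatError(f"row {i}: unknown chip_species {row['chip_species']!r}")
            if row["rna_source"] not in RNA_SOURCES:
                raise FormatError(f"row {i}: unknown rna_source {row['rna_source']!r}")
            group = row["group"]
            if row["rna_source"] == "xenograft":
                if group not in GROUPS:
                    raise FormatError(
                        f"row {i}: xenograft sample {row['sample_id']!r} needs a "
                        f"group in {GROUPS}, got {group!r}"
                    )
            elif not (group is None or (isinstance(group, float) and np.isnan(group)) or group == ""):
                raise FormatError(
                    f"row {i}: control sample {row['sample_id']!r} must not carry a group"
                )

    def xenograft_samples(self, chip_species: str) -> pd.DataFrame:
        t = self.table
        return t[(t["chip_species"] == chip_species) & (t["rna_source"] == "xenograft")]

    def control_samples(self, chip_species: str, rna_source: str) -> pd.DataFrame:
        t = self.table
        return t[(t["chip_species"] == chip_species) & (t["rna_source"] == rna_source)]

    def groups(self, chip_species: str) -> dict[str, list[str]]:
        """Sample ids per treatment group for one chip's xenograft arrays."""
        xeno = self.xenograft_samples(chip_species)
        return {g: list(xeno.loc[xeno["group"] == g, "sample_id"]) for g in GROUPS}


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. NF-kB / TNF / IL-6 / IFN-beta target sets)."""

    sets: dict[str, frozenset[str]]
    species: str | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(canonical_symbol(s, self.species) for s in members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def canonical_symbol(symbol: str, species: str | None = None) -> str:
    """Canonical gene-symbol case: upper for human, Capitalised-lower for mouse.

    With no species given, symbols are upper-cased (collection-level matching
    is done through the OrthologMap, never by case alone).
    """
    s = symbol.strip()
    if species == MOUSE:
        return s[:1].upper() + s[1:].lower()
    return s.upper()


@dataclass
class OrthologMap:
    """Unique, symmetric human<->mouse gene-symbol pairing."""

    pairs: list[tuple[str, str]]  # (human_symbol, mouse_symbol)

    def __post_init__(self) -> None:
        h2m: dict[str, str] = {}
        m2h: dict[str, str] = {}
        for hu, mo in self.pairs:
            hu = canonical_symbol(hu, HUMAN)
            mo = canonical_symbol(mo, MOUSE)
            if hu in h2m or mo in m2h:
                raise FormatError(f"duplicate ortholog pairing for ({hu!r}, {mo!r})")
            h2m[hu] = mo
            m2h[mo] = hu
        self._h2m = h2m
        self._m2h = m2h
        self.pairs = [(h, m) for h, m in h2m.items()]

    def to_mouse(self, human_symbol: str) -> str | None:
        return self._h2m.get(canonical_symbol(human_symbol, HUMAN))

    def to_human(self, mouse_symbol: str) -> str | None:
        return self._m2h.get(canonical_symbol(mouse_symbol, MOUSE))

    def ortholog(self, symbol: str, species: str) -> str | None:
        """Symbol of the ortholog in the *other* species, or None."""
        return self.to_mouse(symbol) if species == HUMAN else self.to_human(symbol)

    def __len__(self) -> int:
        return len(self._h2m)


# ---------------------------------------------------------------------------
# Intensity matrices
# ---------------------------------------------------------------------------

def read_intensity_matrix(path: str | Path, chip_species: str) -> ProbeIntensityMatrix:
    """Read a tab-delimited probe x sample intensity matrix.

    First column holds probe ids, the header row sample ids; the body must be
    strictly positive numbers.  Row and column order are preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # malformed TSV
        raise FormatError(f"{path}: cannot parse as TSV intensity matrix: {exc}") from exc
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(f"{path}: non-numeric intensity at probe {row!r}, sample {col!r}")
    try:
        return ProbeIntensityMatrix(chip_species, df.astype(float))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_intensity_matrix(m: ProbeIntensityMatrix, path: str | Path) -> None:
    m.values.to_csv(Path(path), sep="\t", index_label="probe_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# Probe-set maps and ortholog maps
# ---------------------------------------------------------------------------

def read_probeset_map(path: str | Path, chip_species: str) -> ProbesetMap:
    """Read a probe map TSV with columns probe_id, probeset_id, gene_symbol.

    gene_symbol may be blank for uncharacterised ESTs.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("probe_id", "probeset_id", "gene_symbol")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: probe map missing columns {missing}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"{path}: probe {dup!r} maps to more than one probe set")
    probe_to_set = dict(zip(df["probe_id"], df["probeset_id"]))
    set_to_symbol: dict[str, str | None] = {}
    for ps, sym in zip(df["probeset_id"], df["gene_symbol"]):
        sym = sym or None
        prev = set_to_symbol.get(ps, sym)
        if prev != sym:
            raise FormatError(f"{path}: probe set {ps!r} has conflicting gene symbols")
        set_to_symbol[ps] = sym
    return ProbesetMap(chip_species, probe_to_set, set_to_symbol)


def write_probeset_map(pm: ProbesetMap, path: str | Path) -> None:
    rows = [
        (probe, ps, pm.set_to_symbol.get(ps) or "")
        for probe, ps in pm.probe_to_set.items()
    ]
    pd.DataFrame(rows, columns=["probe_id", "probeset_id", "gene_symbol"]).to_csv(
        Path(path), sep="\t", index=False
    )


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of (human_symbol, mouse_symbol) pairs."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("human_symbol", "mouse_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: ortholog map missing column {col!r}")
    return OrthologMap(list(zip(df["human_symbol"], df["mouse_symbol"])))


def write_ortholog_map(om: OrthologMap, path: str | Path) -> None:
    pd.DataFrame(om.pairs, columns=["human_symbol", "mouse_symbol"]).to_csv(
        Path(path), sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, species: str | None = None) -> GeneSetCollection:
    """Read a standard GMT file: name, description, then member symbols per line."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 symbol"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = frozenset(s for s in fields[2:] if s)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no symbols")
            sets[name] = members
    return GeneSetCollection(sets, species=species)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read and validate a CSV sample sheet."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str}, keep_default_na=False)
    if "group" in df.columns:
        df["group"] = df["group"].replace("", None)
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    try:
        return SampleSheet(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.table.copy()
    out["group"] = out["group"].fillna("")
    out.to_csv(Path(path), index=False)


__all__ = [
    "FormatError",
    "GeneSetCollection",
    "OrthologMap",
    "ProbeIntensityMatrix",
    "ProbesetMap",
    "SampleSheet",
    "canonical_symbol",
    "read_gmt",
    "read_intensity_matrix",
    "read_ortholog_map",
    "read_probeset_map",
    "read_sample_sheet",
    "write_gmt",
    "write_intensity_matrix",
    "write_ortholog_map",
    "write_probeset_map",
    "write_sample_sheet",
    "HUMAN",
    "MOUSE",
    "SPECIES",
]
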