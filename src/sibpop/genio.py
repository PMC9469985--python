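"""Genotype/coordinate I/O and the core data model.

Genotypes are diploid codominant calls (microsatellite-style): for each
(individual, locus) an unordered pair of positive integer allele codes, with 0
reserved for missing. Supported interchange formats are GENEPOP (2- and
3-digit dialects), the STRUCTURE matrix format (two-rows-per-individual or
one-row with paired columns), and plain CSV tables. Coordinates live in a
:class:`GeoTable`; internally every module works on a planar km grid, and
lon/lat inputs are projected with a Lambert azimuthal equal-area projection
centered on the sample centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = 0

_EARTH_RADIUS_KM = 6371.0088


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class Locus:
    """A single codominant locus: a name and the set of observed allele codes."""

    name: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.alleles):
            raise ValueError(f"locus {self.name}: allele codes must be positive (0 is the missing code)")


class GenotypeTable:
    """Individuals x loci diploid allele calls with missing-data support.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers, in order.
    locus_names : sequence of str
        Unique locus names, in order.
    calls : ndarray of shape (n, L, 2), int
        Allele codes; 0 marks a missing allele. A call must be either
        both-missing or both-present.
    group_label : optional sequence of str
        Per-individual grouping (e.g. lek or state), carried through I/O.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        locus_names: Sequence[str],
        calls: np.ndarray,
        group_label: Sequence[str] | None = None,
    ) -> None:
        individuals = list(map(str, individuals))
        if len(set(individuals)) != len(individuals):
            raise ValueError("individual IDs must be unique")
        locus_names = list(map(str, locus_names))
        if len(set(locus_names)) != len(locus_names):
            raise ValueError("locus names must be unique")
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(individuals), len(locus_names), 2):
            raise ValueError(f"calls shape {calls.shape} != {(len(individuals), len(locus_names), 2)}")
        if calls.min(initial=0) < 0:
            raise ValueError("allele codes must be non-negative")
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(f"half-missing call at individual {individuals[i]!r}, locus {locus_names[l]!r}")
        self.individuals = individuals
        self.locus_names = locus_names
        self.calls = calls
        self.group_label = list(group_label) if group_label is not None else None
        if self.group_label is not None and len(self.group_label) != len(individuals):
            raise ValueError("group_label length mismatch")

    # -- basic protocol ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def loci(self) -> list[Locus]:
        return [
            Locus(name, tuple(sorted(set(self.calls[:, j, :].ravel()) - {MISSING})))
            for j, name in enumerate(self.locus_names)
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        a = np.sort(self.calls, axis=2)
        b = np.sort(other.calls, axis=2)
        return (
            self.individuals == other.individuals
            and self.locus_names == other.locus_names
            and np.array_equal(a, b)
        )

    def __repr__(self) -> str:
        return f"GenotypeTable(n={self.n}, loci={self.n_loci})"

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def subset(self, ids: Iterable[str]) -> "GenotypeTable":
        """Return a new table restricted to ``ids`` (order as given)."""
        index = {ind: i for i, ind in enumerate(self.individuals)}
        rows = [index[i] for i in ids]
        return GenotypeTable(
            [self.individuals[r] for r in rows],
            self.locus_names,
            self.calls[rows],
            [self.group_label[r] for r in rows] if self.group_label is not None else None,
        )

    def flag_high_missing(self, threshold: float = 0.5) -> list[str]:
        """IDs of individuals whose missing-call fraction exceeds ``threshold``."""
        frac = self.missing_mask().mean(axis=1)
        return [ind for ind, f in zip(self.individuals, frac) if f > threshold]


@dataclass
class GeoTable:
    """Per-individual coordinates: planar km (``mode='km'``) or degrees (``mode='lonlat'``)."""

    individuals: list[str]
    x: np.ndarray
    y: np.ndarray
    mode: str = "km"

    def __post_init__(self) -> None:
        self.individuals = list(map(str, self.individuals))
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.mode not in ("km", "lonlat"):
            raise ValueError(f"unknown coordinate mode {self.mode!r}")
        if len(self.individuals) != self.x.size or self.x.size != self.y.size:
            raise ValueError("coordinate arrays must match the ID list")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual IDs in coordinates")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates contain NaN/inf")

    def to_km(self) -> "GeoTable":
        """Project to the internal planar-km convention (equal-area, centroid-centered)."""
        if self.mode == "km":
            return self
        x, y = _laea_forward(self.x, self.y)
        return GeoTable(self.individuals, x, y, mode="km")

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _laea_forward(lon_deg: np.ndarray, lat_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lambert azimuthal equal-area, spherical, centered on the data centroid; output km."""
    lon = np.radians(lon_deg)
    lat = np.radians(lat_deg)
    lon0 = float(np.mean(lon))
    lat0 = float(np.mean(lat))
    denom = 1.0 + np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
    k = np.sqrt(2.0 / denom)
    x = _EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - lon0)
    y = _EARTH_RADIUS_KM * k * (np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0))
    return x, y


@dataclass
class Dataset:
    """A genotype table joined with planar-km coordinates, order-aligned."""

    genotypes: GenotypeTable
    geo: GeoTable
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.genotypes.individuals != self.geo.individuals:
            raise ValueError("Dataset requires order-aligned genotype and coordinate IDs")
        if self.geo.mode != "km":
            raise ValueError("Dataset coordinates must be planar km; call GeoTable.to_km() first")

    @property
    def n(self) -> int:
        return self.genotypes.n

    def coords(self) -> np.ndarray:
        return self.geo.coords()

    def subset(self, ids: Iterable[str]) -> "Dataset":
        ids = list(ids)
        index = {ind: i for i, ind in enumerate(self.geo.individuals)}
        rows = [index[i] for i in ids]
        geo = GeoTable(ids, self.geo.x[rows], self.geo.y[rows], mode="km")
        truth = None
        if self.truth is not None:
            truth = self.truth.loc[ids]
        return Dataset(self.genotypes.subset(ids), geo, truth)


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

def read_genepop(path: str | Path, coord_source: str | Path | None = None):
    """Read a GENEPOP file (2- or 3-digit allele encoding, auto-detected).

    POP blocks become ``group_label`` values ``POP1, POP2, ...``. "00"/"000"
    codes are decoded as missing. Returns a :class:`GenotypeTable`, or a
    ``(GenotypeTable, GeoTable)`` pair when ``coord_source`` (a CSV of
    ``ind,x,y``) is given.
    """
    lines = Path(path).read_text().splitlines()
    raw = [ln.rstrip() for ln in lines]
    if not raw:
        raise FormatError(f"{path}: empty file")
    # title line is free text and skipped
    i = 1
    locus_names: list[str] = []
    while i < len(raw):
        ln = raw[i].strip()
        if ln.upper() == "POP":
            break
        if ln:
            # locus names may be one per line or comma-separated on one line
            locus_names.extend(s.strip() for s in ln.split(",") if s.strip())
        i += 1
    if i == len(raw):
        raise FormatError(f"{path}: no POP block found")
    individuals: list[str] = []
    groups: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop_idx = 0
    for lineno in range(i, len(raw)):
        ln = raw[lineno].strip()
        if not ln:
            continue
        if ln.upper() == "POP":
            pop_idx += 1
            continue
        if "," not in ln:
            raise FormatError(f"{path}:{lineno + 1}: expected 'id , genotypes' line")
        ind, geno = ln.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise FormatError(
                f"{path}:{lineno + 1}: ragged genotype row for {ind.strip()!r} "
                f"({len(tokens)} loci, expected {len(locus_names)})"
            )
        for tok in tokens:
            if len(tok) not in (4, 6):
                raise FormatError(f"{path}:{lineno + 1}: unknown allele width in token {tok!r}")
            w = len(tok) // 2
            if width is None:
                width = w
            elif width != w:
                raise FormatError(f"{path}:{lineno + 1}: mixed allele widths")
        assert width is not None
        calls = []
        for tok in tokens:
            a1, a2 = int(tok[:width]), int(tok[width:])
            if (a1 == 0) != (a2 == 0):
                # GENEPOP allows partially-typed codes; treat as fully missing
                a1 = a2 = 0
            calls.append((a1, a2))
        individuals.append(ind.strip())
        groups.append(f"POP{pop_idx}")
        rows.append(calls)
    table = GenotypeTable(individuals, locus_names, np.array(rows, dtype=np.int64), groups)
    if coord_source is not None:
        geo = read_coords_csv(coord_source)
        return table, geo
    return table


def write_genepop(table: GenotypeTable, path: str | Path, groups: Sequence[str] | None = None, title: str = "sibpop export") -> None:
    """Write GENEPOP; 3-digit encoding when any allele code > 99, else 2-digit.

    ``groups`` (defaulting to ``table.group_label``, else one block) partitions
    individuals into POP blocks, emitted in first-appearance order. Output is
    byte-stable for a fixed input.
    """
    max_code = int(table.calls.max(initial=0))
    if max_code > 999:
        raise ValueError(f"allele code {max_code} exceeds GENEPOP 3-digit encoding")
    width = 3 if max_code > 99 else 2
    if groups is None:
        groups = table.group_label if table.group_label is not None else ["POP1"] * table.n
    if len(groups) != table.n:
        raise ValueError("groups length mismatch")
    order: list[str] = []
    for g in groups:
        if g not in order:
            order.append(g)
    out = [title]
    out.extend(table.locus_names)
    for g in order:
        out.append("POP")
        for i, ind in enumerate(table.individuals):
            if groups[i] != g:
                continue
            toks = [f"{a1:0{width}d}{a2:0{width}d}" for a1, a2 in table.calls[i]]
            out.append(f"{ind} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE matrix format
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path,
    one_row_per_individual: bool = False,
    missing_code: int = -9,
    locus_names: Sequence[str] | None = None,
    header: bool = False,
) -> GenotypeTable:
    """Read a STRUCTURE-format matrix (whitespace-delimited).

    Two-rows-per-individual layout: each pair of consecutive rows carries the
    two allele copies of one individual, one column per locus. One-row layout:
    paired columns (locus1_a, locus1_b, locus2_a, ...). ``missing_code``
    (default -9) marks missing alleles. An optional ``header`` line carries
    locus names.
    """
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if header:
        hdr, lines = lines[0], lines[1:]
        if locus_names is None:
            locus_names = hdr
    if not lines:
        raise FormatError(f"{path}: no data rows")

    def decode(v: str) -> int:
        a = int(v)
        return MISSING if a == missing_code else a

    if one_row_per_individual:
        n_alleles = len(lines[0]) - 1
        if n_alleles % 2:
            raise FormatError(f"{path}: odd number of allele columns ({n_alleles})")
        n_loci = n_alleles // 2
        individuals, rows = [], []
        for ln in lines:
            if len(ln) - 1 != n_alleles:
                raise FormatError(f"{path}: ragged row for {ln[0]!r}")
            individuals.append(ln[0])
            vals = [decode(v) for v in ln[1:]]
            rows.append([(vals[2 * j], vals[2 * j + 1]) for j in range(n_loci)])
    else:
        if len(lines) % 2:
            raise FormatError(f"{path}: odd number of allele rows ({len(lines)})")
        n_loci = len(lines[0]) - 1
        individuals, rows = [], []
        for r1, r2 in zip(lines[0::2], lines[1::2]):
            if r1[0] != r2[0]:
                raise FormatError(f"{path}: unpaired rows {r1[0]!r} / {r2[0]!r}")
            if len(r1) != len(r2) or len(r1) - 1 != n_loci:
                raise FormatError(f"{path}: ragged rows for {r1[0]!r}")
            individuals.append(r1[0])
            rows.append([(decode(a), decode(b)) for a, b in zip(r1[1:], r2[1:])])
    calls = np.array(rows, dtype=np.int64)
    # enforce both-or-neither missing
    part = (calls == MISSING).sum(axis=2) == 1
    calls[part] = MISSING
    names = list(locus_names) if locus_names is not None else [f"locus{j + 1}" for j in range(calls.shape[1])]
    return GenotypeTable(individuals, names, calls)


def write_structure(table: GenotypeTable, path: str | Path, one_row_per_individual: bool = False, missing_code: int = -9) -> None:
    calls = table.calls.copy()
    calls[calls == MISSING] = missing_code
    out = []
    if one_row_per_individual:
        for i, ind in enumerate(table.individuals):
            out.append(" ".join([ind] + [str(v) for pair in calls[i] for v in pair]))
    else:
        for i, ind in enumerate(table.individuals):
            out.append(" ".join([ind] + [str(calls[i, j, 0]) for j in range(table.n_loci)]))
            out.append(" ".join([ind] + [str(calls[i, j, 1]) for j in range(table.n_loci)]))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_genotype_csv(path: str | Path) -> GenotypeTable:
    """CSV with columns ``ind, <locus>_A1, <locus>_A2, ...``; 0/empty = missing."""
    df = pd.read_csv(path, dtype={0: str}).fillna(0)
    ind_col = df.columns[0]
    allele_cols = list(df.columns[1:])
    if len(allele_cols) % 2:
        raise FormatError(f"{path}: odd number of allele columns")
    names = []
    for j in range(0, len(allele_cols), 2):
        base = allele_cols[j].rsplit("_", 1)[0]
        names.append(base)
    calls = df[allele_cols].to_numpy(dtype=np.int64).reshape(len(df), -1, 2)
    part = (calls == MISSING).sum(axis=2) == 1
    calls[part] = MISSING
    return GenotypeTable(df[ind_col].tolist(), names, calls)


def write_genotype_csv(table: GenotypeTable, path: str | Path) -> None:
    cols = {"ind": table.individuals}
    for j, name in enumerate(table.locus_names):
        cols[f"{name}_A1"] = table.calls[:, j, 0]
        cols[f"{name}_A2"] = table.calls[:, j, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_coords_csv(path: str | Path, mode: str = "km") -> GeoTable:
    """CSV with columns ``ind, x, y`` (or ``ind, lon, lat`` with mode='lonlat')."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need at least 3 columns (ind, x, y)")
    return GeoTable(df.iloc[:, 0].tolist(), df.iloc[:, 1].to_numpy(float), df.iloc[:, 2].to_numpy(float), mode=mode)


def write_coords_csv(geo: GeoTable, path: str | Path) -> None:
    pd.DataFrame({"ind": geo.individuals, "x": geo.x, "y": geo.y}).to_csv(path, index=False)


def attach_coords(table: GenotypeTable, geo: GeoTable, on_missing: str = "error") -> Dataset:
    """Join genotypes with coordinates into an order-aligned :class:`Dataset`.

    lon/lat coordinates are projected to planar km. Coordinates for
    non-genotyped individuals are ignored (logged). Genotyped individuals
    without coordinates raise (``on_missing='error'``) or are dropped
    (``on_missing='drop'``).
    """
    geo = geo.to_km()
    have = dict(zip(geo.individuals, range(len(geo.individuals))))
    missing = [i for i in table.individuals if i not in have]
    if missing:
        if on_missing == "error":
            raise ValueError(f"individuals without coordinates: {missing}")
        log.info("dropping %d individuals without coordinates", len(missing))
        table = table.subset([i for i in table.individuals if i in have])
    extra = set(geo.individuals) - set(table.individuals)
    if extra:
        log.info("ignoring %d coordinate rows without genotypes", len(extra))
    rows = [have[i] for i in table.individuals]
    aligned = GeoTable(table.individuals, geo.x[rows], geo.y[rows], mode="km")
    return Dataset(table, aligned)
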