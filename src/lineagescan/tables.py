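"""Readers and writers for the pipeline's TSV dialect.

Dialect: tab-separated, UTF-8; metadata lines start with ``##`` as
``## key=value``; the single column-header line starts with ``#``;
missing values are written as ``.``.  Loaders validate every row and
report the offending line number instead of silently skipping.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AMINO_ACIDS",
    "DSSP_CODES",
    "BranchRecord",
    "SiteRecord",
    "AnnotationMap",
    "TableError",
    "load_branches",
    "load_annotations",
    "load_sites",
    "load_max_asa",
    "write_table",
    "read_table",
    "default_max_asa",
]

log = logging.getLogger("lineagescan")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
DSSP_CODES = frozenset("HGIEBTSC")
MISSING = "."


class TableError(ValueError):
    """Raised for structurally invalid table files; names the line."""


@dataclass(frozen=True)
class BranchRecord:
    """One gene-tree branch with its evolutionary-rate estimates."""

    family_id: str
    branch_id: str
    parent_id: str
    child_id: str
    length: float
    dn: float | None
    ds: float | None
    dnds: float | None
    substituted_sites: tuple[int, ...] = ()


@dataclass(frozen=True)
class SiteRecord:
    """One structure-aligned protein site."""

    family_id: str
    site_index: int
    residue: str
    asa_A2: float
    dssp: str
    flags: frozenset[str] = frozenset()


@dataclass
class AnnotationMap:
    """Family id -> pathway-id set and domain-id set; empty = unmapped."""

    pathways: dict[str, set[str]] = field(default_factory=dict)
    domains: dict[str, set[str]] = field(default_factory=dict)

    def terms(self, kind: str) -> dict[str, set[str]]:
        if kind == "pathway":
            return self.pathways
        if kind == "domain":
            return self.domains
        raise ValueError(f"unknown annotation kind {kind!r}")

    def universe(self, kind: str) -> set[str]:
        out: set[str] = set()
        for s in self.terms(kind).values():
            out |= s
        return out

    def add(self, family_id: str, kind: str, term_id: str) -> None:
        self.terms(kind).setdefault(family_id, set()).add(term_id)
        # keep both maps keyed by the same family ids
        other = "domain" if kind == "pathway" else "pathway"
        self.terms(other).setdefault(family_id, set())


# ---------------------------------------------------------------------------
# generic dialect plumbing


def _parse_header(path: Path) -> tuple[list[str], dict[str, str], int]:
    """Return (columns, metadata, number of lines consumed)."""
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##"):
                body = line[2:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if line.startswith("#"):
                cols = line[1:].split("\t")
                return [c.strip() for c in cols], meta, lineno
            raise TableError(f"{path}:{lineno}: expected '#'-prefixed header")
    raise TableError(f"{path}: no header line found")


def read_table(path: str | Path) -> tuple[list[dict[str, str]], dict[str, str]]:
    """Read a dialect TSV into a list of column-keyed string rows."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols, meta, header_line = _parse_header(path)
    rows: list[dict[str, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, raw in enumerate(reader, start=1):
            if lineno <= header_line or not raw or raw[0].startswith("#"):
                continue
            if all(not cell.strip() for cell in raw):
                continue
            if len(raw) != len(cols):
                raise TableError(
                    f"{path}:{lineno}: expected {len(cols)} columns, got {len(raw)}"
                )
            rows.append(dict(zip(cols, raw)))
    return rows, meta


def write_table(
    path: str | Path,
    columns: Sequence[str],
    rows: Iterable[Sequence],
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write rows in the dialect; ``None`` cells become ``.``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"## {key}={value}\n")
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            cells = [MISSING if v is None else str(v) for v in row]
            fh.write("\t".join(cells) + "\n")


def _need(row: dict[str, str], col: str, path: Path, lineno: str) -> str:
    if col not in row:
        raise TableError(f"{path}: missing required column {col!r}")
    return row[col].strip()


def _as_float(value: str, what: str, where: str, minimum: float | None = 0.0):
    if value == MISSING or value == "":
        return None
    try:
        x = float(value)
    except ValueError:
        raise TableError(f"{where}: non-numeric {what} {value!r}") from None
    if minimum is not None and x < minimum:
        raise TableError(f"{where}: {what} must be >= {minimum}, got {x}")
    return x


# ---------------------------------------------------------------------------
# concrete loaders


def load_branches(path: str | Path) -> list[BranchRecord]:
    """Load ``branches.tsv`` (per-branch lengths, dN, dS, dN/dS, sites)."""
    path = Path(path)
    rows, _ = read_table(path)
    records: list[BranchRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=1):
        where = f"{path}: data row {i}"
        family = _need(row, "family_id", path, where)
        branch = _need(row, "branch_id", path, where)
        key = (family, branch)
        if key in seen:
            raise TableError(f"{where}: duplicate branch {key}")
        seen.add(key)
        sites_raw = _need(row, "substituted_sites", path, where)
        sites: tuple[int, ...] = ()
        if sites_raw not in (MISSING, ""):
            try:
                sites = tuple(int(s) for s in sites_raw.split(","))
            except ValueError:
                raise TableError(
                    f"{where}: bad substituted_sites list {sites_raw!r}"
                ) from None
            if any(s < 1 for s in sites):
                raise TableError(f"{where}: site indices are 1-based, got {sites}")
        length = _as_float(_need(row, "length", path, where), "length", where)
        if length is None:
            raise TableError(f"{where}: branch length is required")
        records.append(
            BranchRecord(
                family_id=family,
                branch_id=branch,
                parent_id=_need(row, "parent_id", path, where),
                child_id=_need(row, "child_id", path, where),
                length=length,
                dn=_as_float(_need(row, "dN", path, where), "dN", where),
                ds=_as_float(_need(row, "dS", path, where), "dS", where),
                dnds=_as_float(_need(row, "dnds", path, where), "dnds", where),
                substituted_sites=sites,
            )
        )
    if not records:
        log.warning("branch table %s is empty", path)
    return records


def load_annotations(path: str | Path) -> AnnotationMap:
    """Load ``annotations.tsv`` (family_id, kind, term_id)."""
    path = Path(path)
    rows, _ = read_table(path)
    amap = AnnotationMap()
    for i, row in enumerate(rows, start=1):
        where = f"{path}: data row {i}"
        kind = _need(row, "kind", path, where)
        if kind not in ("pathway", "domain"):
            raise TableError(f"{where}: kind must be pathway or domain, got {kind!r}")
        amap.add(_need(row, "family_id", path, where), kind,
                 _need(row, "term_id", path, where))
    return amap


def load_sites(path: str | Path) -> list[SiteRecord]:
    """Load ``sites.tsv``; enforces residue/DSSP alphabets and uniqueness."""
    path = Path(path)
    rows, _ = read_table(path)
    records: list[SiteRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(rows, start=1):
        where = f"{path}: data row {i}"
        family = _need(row, "family_id", path, where)
        try:
            site_index = int(_need(row, "site_index", path, where))
        except ValueError:
            raise TableError(f"{where}: non-integer site_index") from None
        if site_index < 1:
            raise TableError(f"{where}: site_index is 1-based, got {site_index}")
        key = (family, site_index)
        if key in seen:
            raise TableError(f"{where}: duplicate (family, site) {key}")
        seen.add(key)
        dssp = _need(row, "dssp", path, where)
        if dssp not in DSSP_CODES:
            raise TableError(f"{where}: unknown DSSP code {dssp!r}")
        residue = _need(row, "residue", path, where)
        asa = _as_float(_need(row, "asa_A2", path, where), "asa_A2", where)
        if asa is None:
            raise TableError(f"{where}: asa_A2 is required")
        flags_raw = _need(row, "flags", path, where)
        flags = frozenset(
            f for f in flags_raw.split(",") if f and f != MISSING
        )
        records.append(
            SiteRecord(
                family_id=family,
                site_index=site_index,
                residue=residue,
                asa_A2=asa,
                dssp=dssp,
                flags=flags,
            )
        )
    if not records:
        log.warning("site table %s is empty", path)
    return records


def load_max_asa(path: str | Path) -> dict[str, float]:
    """Load the residue -> maximum accessible surface area lookup."""
    path = Path(path)
    rows, _ = read_table(path)
    table: dict[str, float] = {}
    for i, row in enumerate(rows, start=1):
        where = f"{path}: data row {i}"
        residue = _need(row, "residue", path, where)
        if residue in table:
            raise TableError(f"{where}: duplicate residue {residue!r}")
        value = _as_float(_need(row, "max_asa_A2", path, where), "max_asa_A2", where)
        if value is None or value <= 0:
            raise TableError(f"{where}: max_asa_A2 must be positive")
        table[residue] = value
    if not table:
        raise TableError(f"{path}: empty max-ASA table")
    return table


# Theoretical maximum accessible surface areas (Å²) per residue from the
# Tien et al. (2013) compilation; used to turn absolute DSSP accessibility
# into relative solvent accessibility.
_TIEN_2013_THEORETICAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


def default_max_asa() -> dict[str, float]:
    """Tien et al. theoretical max-ASA values for the 20 standard residues."""
    return dict(_TIEN_2013_THEORETICAL)
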