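"""Readers and writers for every external file format the toolkit touches.

Formats owned by this module:

* protein sequence databases in FASTA (UniProt header dialect and plain headers),
* peptide identification tables (delimited text, canonical columns
  ``peptide``/``protein``/``start``/``end``),
* expression tables (``accession``, ``value``\\[, ``aux``]),
* subcellular-location tables (``accession``, ``compartments``\\[, ``aux``]),
* organism tables (``accession``, ``organism``).

Every reader/writer pair satisfies ``read(write(x)) == x``. Parsing is
insensitive to trailing whitespace, CRLF line endings and blank lines, and
every dropped or collapsed row is accounted for in a :class:`LoadReport`.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("ligandkit")

#: The 20 canonical amino acids.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Residues accepted in sequences: canonical plus ambiguity/rare codes.
EXTENDED_AA = CANONICAL_AA + "XUBZ"
_LEGAL_RESIDUES = frozenset(EXTENDED_AA)

#: Reserved token for an accession whose organism of origin is not known.
UNKNOWN_ORGANISM = "unknown"

# OS= runs until the next two-capital-letter "XX=" token (UniProt convention).
_OS_RE = re.compile(r"\bOS=(.*?)(?=\s+[A-Z]{2}=|$)")
_UNIPROT_HEADER_RE = re.compile(r"^(\w+)\|([^|\s]+)\|(\S+)(?:\s+(.*))?$")


class ParseError(ValueError):
    """A file violated the format this module expects."""


@dataclass(frozen=True)
class FastaEntry:
    """One protein record of a sequence database."""

    sequence: str
    entry_name: str
    organism: str = UNKNOWN_ORGANISM
    description: str = ""


@dataclass
class SequenceDB:
    """Accession-keyed protein sequence database.

    Accessions are unique; sequences are non-empty, uppercase, and drawn
    from the 20-letter alphabet plus X/U/B/Z. Lookup of a missing accession
    raises :class:`KeyError` rather than returning an empty result.
    """

    entries: dict[str, FastaEntry] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, accession: str) -> FastaEntry:
        try:
            return self.entries[accession]
        except KeyError:
            raise KeyError(
                f"accession {accession!r} not present in sequence database "
                f"{self.source or '<in-memory>'}"
            ) from None

    def sequence(self, accession: str) -> str:
        return self[accession].sequence

    def __eq__(self, other) -> bool:  # source path is provenance, not content
        if not isinstance(other, SequenceDB):
            return NotImplemented
        return self.entries == other.entries


@dataclass(frozen=True)
class IdentificationRow:
    """One normalized identification hit: a peptide assigned to a protein."""

    peptide: str
    accession: str
    start: Optional[int] = None
    end: Optional[int] = None


@dataclass
class LoadReport:
    """Row bookkeeping for a table load: input = emitted + dropped + collapsed."""

    n_input: int = 0
    n_emitted: int = 0
    n_dropped: int = 0
    n_collapsed: int = 0

    def __post_init__(self) -> None:
        assert self.n_input == self.n_emitted + self.n_dropped + self.n_collapsed


@dataclass
class IdentificationTable:
    """Uniform internal representation of a peptide identification run."""

    rows: list[IdentificationRow]
    source_name: str = ""
    report: LoadReport | None = None

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IdentificationTable):
            return NotImplemented
        return sorted(self.rows, key=_row_key) == sorted(other.rows, key=_row_key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.peptide, r.accession, r.start, r.end) for r in self.rows],
            columns=["peptide", "protein", "start", "end"],
        )


@dataclass
class ExpressionProfile:
    """Accession → non-negative expression value (e.g. TPM), with a
    core/auxiliary flag per accession (default ``core``)."""

    values: dict[str, float] = field(default_factory=dict)
    aux_flag: dict[str, str] = field(default_factory=dict)

    def flag(self, accession: str) -> str:
        return self.aux_flag.get(accession, "core")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CellularLocationMap:
    """Accession → ordered list of subcellular compartment names.

    An empty list means the location is unknown.
    """

    locations: dict[str, list[str]] = field(default_factory=dict)
    aux_flag: dict[str, str] = field(default_factory=dict)

    def flag(self, accession: str) -> str:
        return self.aux_flag.get(accession, "core")

    def __len__(self) -> int:
        return len(self.locations)


def _row_key(r: IdentificationRow):
    return (r.peptide, r.accession, -1 if r.start is None else r.start)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, str, str, str]:
    """Split a FASTA header (without ``>``) into accession/entry/organism/desc."""
    m = _UNIPROT_HEADER_RE.match(header)
    if m:
        accession = m.group(2)
        entry_name = m.group(3)
        rest = (m.group(4) or "").strip()
    else:
        parts = header.split(None, 1)
        accession = parts[0]
        entry_name = accession
        rest = parts[1].strip() if len(parts) > 1 else ""
    os_match = _OS_RE.search(rest)
    if os_match:
        organism = os_match.group(1).strip()
        description = rest[: os_match.start()].strip()
    else:
        organism = UNKNOWN_ORGANISM
        description = re.split(r"\s+[A-Z]{2}=", rest)[0].strip()
    return accession, entry_name, organism, description


def read_fasta(path: str | Path) -> SequenceDB:
    """Read a protein FASTA file into a :class:`SequenceDB`.

    Headers in the UniProt dialect ``>db|ACC|ENTRY desc OS=... OX=...`` yield
    the accession from the second pipe field and the organism from the ``OS=``
    value (terminated by the next ``XX=`` token or end of line). Plain headers
    yield the first whitespace-delimited token as accession and an unknown
    organism. Sequence lines are concatenated and uppercased.

    Raises
    ------
    ParseError
        On sequence data before the first header (with line number), a
        duplicate accession, an empty sequence, or an illegal residue
        character.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise ParseError(
                f"{path}:{lineno}: sequence data before the first '>' header"
            )
        break

    db = SequenceDB(source=str(path))
    with _stdio.StringIO(text) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            accession, entry_name, organism, description = _parse_header(
                record.description
            )
            sequence = str(record.seq).upper()
            if not sequence:
                raise ParseError(f"{path}: record {accession!r} has an empty sequence")
            bad = set(sequence) - _LEGAL_RESIDUES
            if bad:
                raise ParseError(
                    f"{path}: record {accession!r} contains illegal residue "
                    f"character(s) {sorted(bad)!r}"
                )
            if accession in db.entries:
                raise ParseError(f"{path}: duplicate accession {accession!r}")
            db.entries[accession] = FastaEntry(
                sequence=sequence,
                entry_name=entry_name,
                organism=organism,
                description=description,
            )
    if not db.entries:
        raise ParseError(f"{path}: no FASTA records found")
    return db


def write_fasta(db: SequenceDB, path: str | Path, width: int = 60) -> None:
    """Write a :class:`SequenceDB` back to FASTA.

    Entries with a known organism (or an entry name distinct from the
    accession) are written in the UniProt dialect so that
    ``read_fasta(write_fasta(db)) == db``.
    """
    path = Path(path)
    with path.open("w") as fh:
        for accession, entry in db.entries.items():
            if entry.organism != UNKNOWN_ORGANISM or entry.entry_name != accession:
                header = f">sp|{accession}|{entry.entry_name}"
                if entry.description:
                    header += f" {entry.description}"
                if entry.organism != UNKNOWN_ORGANISM:
                    header += f" OS={entry.organism}"
            else:
                header = f">{accession}"
                if entry.description:
                    header += f" {entry.description}"
            fh.write(header + "\n")
            seq = entry.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Identification tables
# ---------------------------------------------------------------------------

# modification annotations: parenthesised or bracketed substrings, e.g.
# "PEPT(+79.97)IDE" or "PEPT[Phospho]IDE"
_MOD_RE = re.compile(r"\(.*?\)|\[.*?\]")
# flanking-residue dialect "K.PEPTIDE.R" / "-.PEPTIDE.R"
_FLANK_RE = re.compile(r"^(?:[A-Z\-]\.)?(.*?)(?:\.[A-Z\-])?$")


def normalize_peptide(raw: str) -> str:
    """Strip modification annotations and flanking-residue markers, uppercase.

    ``"K.PEPT(+79.97)IDE.R"`` becomes ``"PEPTIDE"``. The result may still
    contain characters outside the residue alphabet; callers decide whether
    to drop such rows.
    """
    s = raw.strip()
    m = _FLANK_RE.match(s)
    if m:
        s = m.group(1)
    s = _MOD_RE.sub("", s)
    return s.upper()


_DEFAULT_COLUMN_MAP = {
    "peptide": "peptide",
    "protein": "protein",
    "start": "start",
    "end": "end",
}


def read_identification_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str = "\t",
    one_based: bool = False,
    source_name: str | None = None,
) -> IdentificationTable:
    """Read a delimited peptide identification table.

    Parameters
    ----------
    column_map
        Role → column-name mapping; must cover at least ``peptide`` and
        ``protein``. ``start``/``end`` roles are optional. No header sniffing
        is attempted.
    sep
        Field delimiter; TAB is canonical, pass ``","`` for CSV exports.
    one_based
        If true, ``start`` columns are 1-based inclusive and are converted to
        the internal 0-based half-open convention on load.

    Rows are normalized (peptides uppercased, modification annotations
    stripped), peptides with residues outside the alphabet after stripping
    are dropped with a warning, and duplicate ``(peptide, accession, start)``
    triples are collapsed. The attached :class:`LoadReport` accounts for
    every input row.
    """
    path = Path(path)
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    for role in ("peptide", "protein"):
        if cmap[role] not in df.columns:
            raise ParseError(
                f"{path}: required column {cmap[role]!r} (role {role!r}) missing; "
                f"available columns: {list(df.columns)}"
            )
    has_coords = cmap["start"] in df.columns and cmap["end"] in df.columns

    n_input = len(df)
    n_dropped = 0
    seen: set[tuple[str, str, Optional[int]]] = set()
    rows: list[IdentificationRow] = []
    for _, rec in df.iterrows():
        raw_pep = rec[cmap["peptide"]]
        raw_acc = rec[cmap["protein"]]
        if pd.isna(raw_pep) or pd.isna(raw_acc):
            n_dropped += 1
            continue
        peptide = normalize_peptide(str(raw_pep))
        accession = str(raw_acc).strip()
        if not peptide or set(peptide) - _LEGAL_RESIDUES:
            logger.warning(
                "%s: dropping peptide %r (illegal residues after normalization)",
                path,
                raw_pep,
            )
            n_dropped += 1
            continue
        start = end = None
        if has_coords:
            s_raw, e_raw = rec[cmap["start"]], rec[cmap["end"]]
            if not pd.isna(s_raw) and not pd.isna(e_raw) and str(s_raw).strip() and str(e_raw).strip():
                start = int(float(s_raw))
                end = int(float(e_raw))
                if one_based:
                    start -= 1  # 1-based inclusive -> 0-based half-open
                if not (0 <= start < end):
                    raise ParseError(
                        f"{path}: row ({peptide!r}, {accession!r}) has invalid "
                        f"coordinates start={start}, end={end}"
                    )
                if end - start != len(peptide):
                    raise ParseError(
                        f"{path}: row ({peptide!r}, {accession!r}) coordinate span "
                        f"{end - start} does not match peptide length {len(peptide)}"
                    )
        key = (peptide, accession, start)
        if key in seen:
            continue
        seen.add(key)
        rows.append(IdentificationRow(peptide, accession, start, end))

    n_collapsed = n_input - n_dropped - len(rows)
    if n_collapsed:
        logger.info("%s: collapsed %d duplicate identification rows", path, n_collapsed)
    if not rows:
        raise ParseError(f"{path}: identification table empty after normalization")
    return IdentificationTable(
        rows=rows,
        source_name=source_name if source_name is not None else path.stem,
        report=LoadReport(
            n_input=n_input,
            n_emitted=len(rows),
            n_dropped=n_dropped,
            n_collapsed=n_collapsed,
        ),
    )


def write_identification_table(table: IdentificationTable, path: str | Path) -> None:
    """Write a table as TSV with canonical columns peptide/protein/start/end.

    Absent coordinates serialize as empty fields; the written file reads back
    equal to ``table``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("peptide\tprotein\tstart\tend\n")
        for r in table.rows:
            s = "" if r.start is None else str(r.start)
            e = "" if r.end is None else str(r.end)
            fh.write(f"{r.peptide}\t{r.accession}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Expression / location / organism tables
# ---------------------------------------------------------------------------

def _read_tsv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise ParseError(
                f"{path}: required column {col!r} missing; available: {list(df.columns)}"
            )
    return df


def _aux(rec, df) -> str:
    if "aux" in df.columns and not pd.isna(rec.get("aux")) and str(rec["aux"]).strip():
        flag = str(rec["aux"]).strip().lower()
        if flag not in ("core", "auxiliary"):
            raise ParseError(f"invalid aux flag {flag!r} (expected core/auxiliary)")
        return flag
    return "core"


def read_expression_table(path: str | Path) -> ExpressionProfile:
    """Read a TSV expression table (columns ``accession``, ``value``\\[, ``aux``])."""
    path = Path(path)
    df = _read_tsv(path, ("accession", "value"))
    profile = ExpressionProfile()
    for _, rec in df.iterrows():
        accession = str(rec["accession"]).strip()
        try:
            value = float(rec["value"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric expression value {rec['value']!r} for {accession!r}"
            ) from None
        if not (value >= 0) or value != value or value == float("inf"):
            raise ParseError(
                f"{path}: expression value for {accession!r} must be finite and >= 0, "
                f"got {value!r}"
            )
        if accession in profile.values and profile.values[accession] != value:
            raise ParseError(
                f"{path}: duplicate accession {accession!r} with conflicting values"
            )
        profile.values[accession] = value
        profile.aux_flag[accession] = _aux(rec, df)
    if not profile.values:
        raise ParseError(f"{path}: empty expression table")
    return profile


def write_expression_table(profile: ExpressionProfile, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("accession\tvalue\taux\n")
        for accession, value in profile.values.items():
            # repr is the shortest exact decimal form, so round-trips are lossless
            fh.write(f"{accession}\t{value!r}\t{profile.flag(accession)}\n")


def read_location_table(path: str | Path) -> CellularLocationMap:
    """Read a TSV location table (columns ``accession``, ``compartments``\\[, ``aux``]).

    ``compartments`` is a semicolon-separated list; an empty field means the
    subcellular location is unknown and yields an empty list.
    """
    path = Path(path)
    df = _read_tsv(path, ("accession", "compartments"))
    locmap = CellularLocationMap()
    for _, rec in df.iterrows():
        accession = str(rec["accession"]).strip()
        raw = rec["compartments"]
        if pd.isna(raw) or not str(raw).strip():
            compartments: list[str] = []
        else:
            compartments = [c.strip() for c in str(raw).split(";") if c.strip()]
        if accession in locmap.locations and locmap.locations[accession] != compartments:
            raise ParseError(
                f"{path}: duplicate accession {accession!r} with conflicting compartments"
            )
        locmap.locations[accession] = compartments
        locmap.aux_flag[accession] = _aux(rec, df)
    if not locmap.locations:
        raise ParseError(f"{path}: empty location table")
    return locmap


def write_location_table(locmap: CellularLocationMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("accession\tcompartments\taux\n")
        for accession, compartments in locmap.locations.items():
            fh.write(f"{accession}\t{';'.join(compartments)}\t{locmap.flag(accession)}\n")


def read_organism_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping accession → organism name."""
    path = Path(path)
    df = _read_tsv(path, ("accession", "organism"))
    mapping: dict[str, str] = {}
    for _, rec in df.iterrows():
        accession = str(rec["accession"]).strip()
        organism = str(rec["organism"]).strip() if not pd.isna(rec["organism"]) else UNKNOWN_ORGANISM
        if accession in mapping and mapping[accession] != organism:
            raise ParseError(
                f"{path}: duplicate accession {accession!r} with conflicting organisms"
            )
        mapping[accession] = organism or UNKNOWN_ORGANISM
    if not mapping:
        raise ParseError(f"{path}: empty organism table")
    return mapping


def write_organism_table(mapping: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("accession\torganism\n")
        for accession, organism in mapping.items():
            fh.write(f"{accession}\t{organism}\n")
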