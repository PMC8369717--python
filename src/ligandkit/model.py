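"""Object model for immunopeptidomics experiments.

An :class:`Experiment` binds one identification run to its sequence database
and optional tissue/HLA/metadata layers. Peptide→protein assignments form a
bipartite graph: edges run only from peptides to the proteins they occur in,
never between peptides or between proteins. Proteins carried by an
experiment are the *inferred* proteins — those with at least one identified
peptide mapping to them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .io import (
    ExpressionProfile,
    CellularLocationMap,
    IdentificationRow,
    IdentificationTable,
    SequenceDB,
    write_identification_table,
)

logger = logging.getLogger("ligandkit")


@dataclass(frozen=True)
class Protein:
    """A database protein: accession plus full amino-acid sequence."""

    accession: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


#: One peptide→protein edge: (accession, start, end), 0-based half-open.
Mapping_ = tuple[str, int, int]


@dataclass
class Peptide:
    """An identified peptide and its occurrence intervals in parent proteins.

    A peptide may map to several proteins (shared peptides) and to several
    sites within one protein (repeats); every mapping satisfies
    ``protein.sequence[start:end] == peptide.sequence``.
    """

    sequence: str
    mappings: list[Mapping_] = field(default_factory=list)

    def accessions(self) -> set[str]:
        return {acc for acc, _, _ in self.mappings}

    def mappings_to(self, accession: str) -> list[tuple[int, int]]:
        return [(s, e) for acc, s, e in self.mappings if acc == accession]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Peptide):
            return NotImplemented
        return self.sequence == other.sequence and sorted(self.mappings) == sorted(
            other.mappings
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HLASet:
    """The HLA alleles of a sample; allele names are stored verbatim."""

    alleles: list[str]
    hla_class: str = "mixed"  # one of I, II, mixed

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("HLASet requires at least one allele")
        if self.hla_class not in ("I", "II", "mixed"):
            raise ValueError(f"hla_class must be I, II or mixed, got {self.hla_class!r}")


@dataclass
class Tissue:
    """A tissue with optional expression and subcellular-location layers."""

    name: str
    expression: Optional[ExpressionProfile] = None
    location: Optional[CellularLocationMap] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("Tissue name must be non-empty")


@dataclass
class Experiment:
    """One identification run bound to its sequence context.

    Invariants: every peptide has at least one mapping; every mapped
    accession is present in :attr:`proteins`; :attr:`proteins` holds exactly
    the accessions with at least one surviving peptide.
    """

    name: str
    peptides: dict[str, Peptide]
    proteins: dict[str, Protein]
    tissue: Optional[Tissue] = None
    hla: Optional[HLASet] = None
    metadata: dict[str, str] = field(default_factory=dict)
    drop_report: dict[str, int] = field(default_factory=dict)

    def peptide_sequences(self) -> set[str]:
        return set(self.peptides)

    def protein_accessions(self) -> set[str]:
        return set(self.proteins)

    @property
    def n_peptides(self) -> int:
        """Number of distinct peptide sequences."""
        return len(self.peptides)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Experiment):
            return NotImplemented
        return (
            self.name == other.name
            and self.peptides == other.peptides
            and self.proteins == other.proteins
        )

    def to_table(self) -> IdentificationTable:
        """Serialize to the canonical identification table, one row per mapping."""
        rows = [
            IdentificationRow(pep.sequence, acc, start, end)
            for pep in self.peptides.values()
            for acc, start, end in sorted(pep.mappings)
        ]
        rows.sort(key=lambda r: (r.peptide, r.accession, r.start))
        return IdentificationTable(rows=rows, source_name=self.name)

    def save(self, table_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the canonical TSV plus a JSON sidecar with sample metadata."""
        write_identification_table(self.to_table(), table_path)
        if sidecar_path is not None:
            sidecar = {
                "name": self.name,
                "tissue": self.tissue.name if self.tissue else None,
                "hla_alleles": self.hla.alleles if self.hla else None,
                "hla_class": self.hla.hla_class if self.hla else None,
                "metadata": self.metadata,
            }
            Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")


@dataclass
class ExperimentSet:
    """An ordered, name-keyed collection of experiments."""

    experiments: dict[str, Experiment]

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError("ExperimentSet requires at least one experiment")
        for name, exp in self.experiments.items():
            if name != exp.name:
                raise ValueError(f"key {name!r} does not match experiment name {exp.name!r}")

    @classmethod
    def from_experiments(cls, experiments: Iterable[Experiment]) -> "ExperimentSet":
        exps = list(experiments)
        names = [e.name for e in exps]
        if len(set(names)) != len(names):
            raise ValueError("experiment names must be unique")
        return cls({e.name: e for e in exps})

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments.values())

    def __getitem__(self, name: str) -> Experiment:
        return self.experiments[name]

    @property
    def names(self) -> list[str]:
        return list(self.experiments)


# ---------------------------------------------------------------------------
# Peptide→protein mapping
# ---------------------------------------------------------------------------

def map_peptide_to_protein(peptide: str, protein_sequence: str) -> list[tuple[int, int]]:
    """Find all exact-substring occurrences of a peptide in a protein.

    Returns 0-based half-open intervals in ascending start order; overlapping
    occurrences are all reported. An empty list is a valid no-match result.
    """
    if not peptide or not protein_sequence:
        raise ValueError("peptide and protein sequence must be non-empty")
    hits: list[tuple[int, int]] = []
    start = protein_sequence.find(peptide)
    while start != -1:
        hits.append((start, start + len(peptide)))
        start = protein_sequence.find(peptide, start + 1)
    return hits


def build_experiment(
    table: IdentificationTable,
    db: SequenceDB,
    name: str,
    tissue: Optional[Tissue] = None,
    hla: Optional[HLASet] = None,
    metadata: Optional[Mapping[str, str]] = None,
) -> Experiment:
    """Construct an :class:`Experiment` from an identification table and database.

    Rows carrying start/end coordinates are validated against the named
    protein sequence; rows without coordinates fall back to exhaustive
    substring search (:func:`map_peptide_to_protein`). Rows whose accession
    is missing from the database, or whose peptide does not occur in the
    named protein, are dropped with a logged warning and counted in the
    experiment's ``drop_report``.

    Raises
    ------
    ValueError
        If zero peptides survive.
    """
    peptides: dict[str, Peptide] = {}
    dropped_missing_acc = 0
    dropped_no_match = 0
    for row in table.rows:
        if row.accession not in db:
            logger.warning(
                "%s: accession %r not in sequence database; row dropped", name, row.accession
            )
            dropped_missing_acc += 1
            continue
        seq = db.sequence(row.accession)
        if row.start is not None and row.end is not None:
            if seq[row.start : row.end] == row.peptide:
                intervals = [(row.start, row.end)]
            else:
                # stated coordinates disagree with the sequence: fall back to search
                intervals = map_peptide_to_protein(row.peptide, seq)
        else:
            intervals = map_peptide_to_protein(row.peptide, seq)
        if not intervals:
            logger.warning(
                "%s: peptide %r does not occur in %r; row dropped",
                name,
                row.peptide,
                row.accession,
            )
            dropped_no_match += 1
            continue
        pep = peptides.setdefault(row.peptide, Peptide(sequence=row.peptide))
        for start, end in intervals:
            m = (row.accession, start, end)
            if m not in pep.mappings:
                pep.mappings.append(m)

    if not peptides:
        raise ValueError(f"experiment {name!r}: no peptides survived mapping")

    for pep in peptides.values():
        pep.mappings.sort()
    accessions = sorted({acc for pep in peptides.values() for acc in pep.accessions()})
    proteins = {acc: Protein(acc, db.sequence(acc)) for acc in accessions}
    return Experiment(
        name=name,
        peptides={seq: peptides[seq] for seq in sorted(peptides)},
        proteins=proteins,
        tissue=tissue,
        hla=hla,
        metadata=dict(metadata or {}),
        drop_report={
            "missing_accession": dropped_missing_acc,
            "no_match": dropped_no_match,
        },
    )


# ---------------------------------------------------------------------------
# Set algebra and grouping over experiment collections
# ---------------------------------------------------------------------------

def peptides_in_all(expset: ExperimentSet) -> set[str]:
    """Peptide sequences identified in every experiment of the set."""
    it = iter(expset)
    common = set(next(it).peptide_sequences())
    for exp in it:
        common &= exp.peptide_sequences()
    return common


def peptides_union(expset: ExperimentSet) -> set[str]:
    """Peptide sequences identified in at least one experiment."""
    out: set[str] = set()
    for exp in expset:
        out |= exp.peptide_sequences()
    return out


def proteins_in_all(expset: ExperimentSet) -> set[str]:
    """Protein accessions inferred in every experiment of the set."""
    it = iter(expset)
    common = set(next(it).protein_accessions())
    for exp in it:
        common &= exp.protein_accessions()
    return common


def proteins_union(expset: ExperimentSet) -> set[str]:
    """Protein accessions inferred in at least one experiment."""
    out: set[str] = set()
    for exp in expset:
        out |= exp.protein_accessions()
    return out


def group_by_metadata(expset: ExperimentSet, key: str) -> dict[str, ExperimentSet]:
    """Partition a set of experiments by a metadata value.

    ``key="tissue"`` is built in and groups by tissue name; any other key is
    looked up in each experiment's metadata map. Every experiment lands in
    exactly one group.
    """
    groups: dict[str, list[Experiment]] = {}
    for exp in expset:
        if key == "tissue":
            if exp.tissue is None:
                raise KeyError(f"experiment {exp.name!r} has no tissue")
            value = exp.tissue.name
        else:
            if key not in exp.metadata:
                raise KeyError(f"metadata key {key!r} missing in experiment {exp.name!r}")
            value = exp.metadata[key]
        groups.setdefault(value, []).append(exp)
    return {
        value: ExperimentSet.from_experiments(exps) for value, exps in groups.items()
    }


# ---------------------------------------------------------------------------
# Per-experiment summaries
# ---------------------------------------------------------------------------

def peptides_per_protein(exp: Experiment) -> dict[str, int]:
    """Distinct-peptide support per inferred protein.

    A peptide shared between proteins counts once for each of them; repeated
    occurrences within one protein count once (distinct-sequence semantics).
    """
    counts = {acc: 0 for acc in exp.proteins}
    for pep in exp.peptides.values():
        for acc in pep.accessions():
            counts[acc] += 1
    return counts


def top_n_proteins(exp: Experiment, n: int) -> list[tuple[str, int]]:
    """The n most-presented proteins as (accession, peptide count).

    Sorted by count descending; ties broken by accession ascending. If ``n``
    exceeds the number of inferred proteins, all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = peptides_per_protein(exp)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]
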