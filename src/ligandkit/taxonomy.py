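"""Organism-of-origin annotation of the identified peptidome.

In infection or vaccine settings the sequence database mixes host and
pathogen proteomes; an :class:`OrganismDB` maps each accession to its
organism (parsed from UniProt ``OS=`` header fields or supplied as a table)
so the peptidome can be partitioned, counted, and filtered by organism.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import (
    SequenceDB,
    UNKNOWN_ORGANISM,
    read_organism_table,
    write_organism_table,
)
from .model import Experiment, Peptide

logger = logging.getLogger("ligandkit")


@dataclass
class OrganismDB:
    """Total accession → organism map; unmapped accessions are ``"unknown"``."""

    org_of: dict[str, str] = field(default_factory=dict)

    def organism(self, accession: str) -> str:
        return self.org_of.get(accession, UNKNOWN_ORGANISM)

    def __len__(self) -> int:
        return len(self.org_of)

    def to_tsv(self, path: str | Path) -> None:
        write_organism_table(self.org_of, path)


def build_organism_db(source: SequenceDB | Mapping[str, str] | str | Path) -> OrganismDB:
    """Build an organism map from a sequence database, a mapping, or a table file.

    From a :class:`~ligandkit.io.SequenceDB` the organism is the parsed
    ``OS=`` field (``"unknown"`` when the header carried none); from a
    mapping or a two-column TSV the values are taken verbatim (trimmed).
    Conflicting duplicate rows in a table raise.
    """
    if isinstance(source, SequenceDB):
        if not source.entries:
            raise ValueError("sequence database is empty")
        return OrganismDB(
            org_of={acc: entry.organism for acc, entry in source.entries.items()}
        )
    if isinstance(source, (str, Path)):
        return OrganismDB(org_of=read_organism_table(source))
    mapping = {str(k): str(v).strip() or UNKNOWN_ORGANISM for k, v in dict(source).items()}
    if not mapping:
        raise ValueError("organism mapping is empty")
    return OrganismDB(org_of=mapping)


def count_per_organism(exp: Experiment, odb: OrganismDB) -> dict[str, tuple[int, int]]:
    """Protein and distinct-peptide counts per organism.

    Each inferred protein counts under its organism; each distinct peptide
    counts under every organism among its mapped proteins, so a peptide
    shared across organisms appears in each (the number of such ambiguous
    peptides is logged).
    """
    protein_orgs = {acc: odb.organism(acc) for acc in exp.proteins}
    counts: dict[str, tuple[int, int]] = {}
    organisms = sorted(set(protein_orgs.values()))
    n_ambiguous = 0
    pep_orgs: dict[str, set[str]] = {}
    for seq, pep in exp.peptides.items():
        orgs = {protein_orgs[acc] for acc in pep.accessions()}
        pep_orgs[seq] = orgs
        if len(orgs) > 1:
            n_ambiguous += 1
    if n_ambiguous:
        logger.info(
            "%s: %d peptides map to proteins of multiple organisms (counted in each)",
            exp.name,
            n_ambiguous,
        )
    for organism in organisms:
        n_prot = sum(1 for org in protein_orgs.values() if org == organism)
        n_pep = sum(1 for orgs in pep_orgs.values() if organism in orgs)
        counts[organism] = (n_prot, n_pep)
    return counts


def organism_counts_frame(counts: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    return pd.DataFrame(
        [(org, n_prot, n_pep) for org, (n_prot, n_pep) in counts.items()],
        columns=["organism", "n_proteins", "n_peptides"],
    )


def filter_by_organism(
    exp: Experiment, odb: OrganismDB, keep: Iterable[str]
) -> Experiment:
    """New experiment retaining only peptides mapped to kept-organism proteins.

    A peptide is retained if *any* of its mapped proteins belongs to a kept
    organism (inclusive rule — dropping host/pathogen-shared peptides
    silently would bias the analysis; the ambiguity count is logged).
    Mappings to non-kept proteins are removed, proteins left without
    peptides are removed, and the input experiment is unchanged.
    """
    keep_set = set(keep)
    if not keep_set:
        raise ValueError("keep set must be non-empty")
    kept_accessions = {
        acc for acc in exp.proteins if odb.organism(acc) in keep_set
    }
    new_peptides: dict[str, Peptide] = {}
    n_ambiguous = 0
    for seq, pep in exp.peptides.items():
        kept_mappings = [
            (acc, s, e) for acc, s, e in pep.mappings if acc in kept_accessions
        ]
        if not kept_mappings:
            continue
        if len(kept_mappings) != len(pep.mappings):
            n_ambiguous += 1
        new_peptides[seq] = Peptide(sequence=seq, mappings=sorted(kept_mappings))
    if not new_peptides:
        raise ValueError(
            f"filter keep={sorted(keep_set)!r} removed every peptide of {exp.name!r}"
        )
    if n_ambiguous:
        logger.info(
            "%s: %d retained peptides also mapped to removed organisms",
            exp.name,
            n_ambiguous,
        )
    surviving = {acc for pep in new_peptides.values() for acc in pep.accessions()}
    return Experiment(
        name=exp.name,
        peptides=new_peptides,
        proteins={acc: exp.proteins[acc] for acc in sorted(surviving)},
        tissue=exp.tissue,
        hla=exp.hla,
        metadata=dict(exp.metadata),
        drop_report=dict(exp.drop_report),
    )
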