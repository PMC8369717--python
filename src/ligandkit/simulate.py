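"""Seeded synthetic-data generator with machine-readable ground truth.

Generates proteomes (uniform-residue sequences with UniProt-dialect
headers), identification tables, expression profiles, and location maps so
that every analysis module can be exercised without any external download.
The identification generator emulates the nested peptide ladders typical of
HLA class II data — no tryptic digestion constrains the peptide termini, so
peptides cluster as overlapping families sharing a 9-residue binding core
with ragged 0–4 residue extensions on both sides — alongside uniformly
placed singleton peptides.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream per
call; the same seed reproduces byte-identical outputs. Every generator
returns the planted ground truth (mappings, per-protein coverage computed by
an independent naive scan, organism partition, expression shift) as a
:class:`GroundTruth` that serializes to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import (
    CANONICAL_AA,
    CellularLocationMap,
    ExpressionProfile,
    IdentificationRow,
    IdentificationTable,
    FastaEntry,
    SequenceDB,
)

#: Binding-core length of the ladder model (HLA class II).
LADDER_CORE_LENGTH = 9
#: Maximum ragged extension on each side of the core.
LADDER_MAX_EXTENSION = 4

_DEFAULT_COMPARTMENTS = (
    "Cytosol",
    "Nucleus",
    "Plasma membrane",
    "Mitochondria",
    "Endoplasmic reticulum",
    "Golgi apparatus",
    "Lysosome",
    "Secreted",
)


@dataclass
class GroundTruth:
    """Planted truth of a simulation run; regenerable byte-identically from seed."""

    seed: int
    organisms: dict[str, str] = field(default_factory=dict)
    mappings: list[tuple[str, str, int, int]] = field(default_factory=list)
    coverage: dict[str, list[int]] = field(default_factory=dict)
    presented: list[str] = field(default_factory=list)
    log2_shift: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "organisms": self.organisms,
                    "mappings": [list(m) for m in self.mappings],
                    "coverage": self.coverage,
                    "presented": self.presented,
                    "log2_shift": self.log2_shift,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            seed=raw["seed"],
            organisms=raw["organisms"],
            mappings=[tuple(m) for m in raw["mappings"]],
            coverage=raw["coverage"],
            presented=raw["presented"],
            log2_shift=raw["log2_shift"],
        )


def _largest_remainder_allocation(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Integer allocation of n items to categories, exact for round fractions."""
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"organism fractions must sum to 1, got {total}")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("organism fractions must be non-negative")
    quotas = {k: n * f for k, f in fractions.items()}
    alloc = {k: int(np.floor(q)) for k, q in quotas.items()}
    remainder = n - sum(alloc.values())
    by_frac = sorted(quotas, key=lambda k: (-(quotas[k] - alloc[k]), k))
    for k in by_frac[:remainder]:
        alloc[k] += 1
    return alloc


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (100, 400),
    organisms: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> tuple[SequenceDB, GroundTruth]:
    """Generate a synthetic proteome with planted organism labels.

    Sequences are i.i.d. uniform over the 20 canonical residues with lengths
    uniform in ``length_range``; organism counts follow the given fractions
    exactly (largest-remainder allocation). Headers use the UniProt dialect
    with ``OS=`` set per planted organism.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length_range {length_range!r}")
    if organisms is None:
        organisms = {"Homo sapiens": 1.0}
    alloc = _largest_remainder_allocation(n_proteins, organisms)
    labels = [org for org in sorted(alloc) for _ in range(alloc[org])]

    rng = np.random.default_rng(seed)
    residues = np.array(list(CANONICAL_AA))
    db = SequenceDB(source=f"synthetic(seed={seed})")
    truth = GroundTruth(seed=seed)
    for i in range(n_proteins):
        accession = f"P{i + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        sequence = "".join(rng.choice(residues, size=length))
        organism = labels[i]
        db.entries[accession] = FastaEntry(
            sequence=sequence,
            entry_name=f"{accession}_SYN",
            organism=organism,
            description=f"Synthetic protein {i + 1}",
        )
        truth.organisms[accession] = organism
    return db, truth


def _naive_coverage(db: SequenceDB, peptides: Sequence[str]) -> dict[str, list[int]]:
    """Ground-truth coverage by naive per-cell scan, independent of the model code.

    For every distinct peptide, every exact occurrence in every database
    protein increments each covered cell by one.
    """
    arrays = {acc: [0] * len(entry.sequence) for acc, entry in db.entries.items()}
    for peptide in sorted(set(peptides)):
        k = len(peptide)
        for acc, entry in db.entries.items():
            seq = entry.sequence
            for start in range(len(seq) - k + 1):
                if seq[start : start + k] == peptide:
                    for pos in range(start, start + k):
                        arrays[acc][pos] += 1
    return {acc: vals for acc, vals in arrays.items() if any(vals)}


def simulate_experiment(
    db: SequenceDB,
    n_peptides: int,
    length_range: tuple[int, int] = (LADDER_CORE_LENGTH, LADDER_CORE_LENGTH + 2 * LADDER_MAX_EXTENSION),
    hotspot_fraction: float = 0.5,
    peptides_per_hotspot: int = 10,
    protein_fraction: float = 0.5,
    seed: int = 0,
    source_name: str = "synthetic",
) -> tuple[IdentificationTable, GroundTruth]:
    """Generate a synthetic identification run over a proteome.

    Peptides are sampled from a random ``protein_fraction`` of the database
    proteins (an immunopeptidome presents only part of the proteome, and the
    presented/non-presented contrast needs non-presented proteins to exist).
    A ``hotspot_fraction`` of the peptides are drawn as nested ladders:
    hotspot sites are chosen on sampled proteins long enough to host a full
    ladder, and each ladder peptide spans the site's 9-residue core extended
    by 0–4 random residues on each side. The remaining peptides are placed
    uniformly (uniform protein, uniform feasible start, length uniform in
    ``length_range``). Rows carry no coordinates — localization is left to
    peptide→protein mapping — and the emitted table is shuffled.

    The returned ground truth records every planted interval and the true
    per-protein coverage arrays of the distinct planted peptides (computed
    by an independent naive scan over the whole database, so chance
    occurrences elsewhere are included).
    """
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    if not (0.0 <= hotspot_fraction <= 1.0):
        raise ValueError("hotspot_fraction must be in [0, 1]")
    if not (0.0 < protein_fraction <= 1.0):
        raise ValueError("protein_fraction must be in (0, 1]")
    lo, hi = length_range
    all_accessions = sorted(db.entries)
    rng = np.random.default_rng(seed)
    n_sampled = max(1, int(round(protein_fraction * len(all_accessions))))
    accessions = sorted(
        rng.choice(all_accessions, size=n_sampled, replace=False).tolist()
    )
    max_len = max(len(db.entries[a].sequence) for a in accessions)
    if not (1 <= lo <= hi) or lo > max_len:
        raise ValueError(
            f"peptide length range {length_range!r} infeasible for database "
            f"(longest protein: {max_len})"
        )
    ladder_span = LADDER_CORE_LENGTH + 2 * LADDER_MAX_EXTENSION
    n_hot = int(round(hotspot_fraction * n_peptides))
    n_uniform = n_peptides - n_hot
    rows: list[IdentificationRow] = []
    truth = GroundTruth(seed=seed)

    if n_hot:
        hot_hosts = [a for a in accessions if len(db.entries[a].sequence) >= ladder_span]
        if not hot_hosts:
            raise ValueError(
                f"no protein is long enough ({ladder_span} residues) to host a hotspot ladder"
            )
        n_hotspots = max(1, int(np.ceil(n_hot / peptides_per_hotspot)))
        sites = []
        for _ in range(n_hotspots):
            acc = hot_hosts[int(rng.integers(len(hot_hosts)))]
            seq = db.entries[acc].sequence
            core_start = int(
                rng.integers(
                    LADDER_MAX_EXTENSION,
                    len(seq) - LADDER_CORE_LENGTH - LADDER_MAX_EXTENSION + 1,
                )
            )
            sites.append((acc, core_start))
        for i in range(n_hot):
            acc, core_start = sites[i % len(sites)]
            seq = db.entries[acc].sequence
            up = int(rng.integers(0, LADDER_MAX_EXTENSION + 1))
            down = int(rng.integers(0, LADDER_MAX_EXTENSION + 1))
            start = core_start - up
            end = core_start + LADDER_CORE_LENGTH + down
            peptide = seq[start:end]
            rows.append(IdentificationRow(peptide, acc))
            truth.mappings.append((peptide, acc, start, end))

    for _ in range(n_uniform):
        while True:
            acc = accessions[int(rng.integers(len(accessions)))]
            seq = db.entries[acc].sequence
            if len(seq) >= lo:
                break
        length = int(rng.integers(lo, min(hi, len(seq)) + 1))
        start = int(rng.integers(0, len(seq) - length + 1))
        peptide = seq[start : start + length]
        rows.append(IdentificationRow(peptide, acc))
        truth.mappings.append((peptide, acc, start, start + length))

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    truth.mappings = [truth.mappings[i] for i in order]
    # ladders can draw the same peptide twice; emit the table already
    # normalized (one row per distinct (peptide, accession)) so the planted
    # file round-trips through the reader without collapses
    seen: set[tuple[str, str]] = set()
    unique_rows = []
    for row in rows:
        key = (row.peptide, row.accession)
        if key not in seen:
            seen.add(key)
            unique_rows.append(row)
    truth.organisms = {acc: db.entries[acc].organism for acc in all_accessions}
    truth.coverage = _naive_coverage(db, [r.peptide for r in unique_rows])
    table = IdentificationTable(rows=unique_rows, source_name=source_name)
    return table, truth


def simulate_expression(
    db: SequenceDB,
    presented_accessions: Sequence[str],
    log2_shift: float = 1.0,
    noise_sd: float = 0.5,
    base_log2_mean: float = 5.0,
    seed: int = 0,
) -> ExpressionProfile:
    """Generate a log-normal expression profile with a planted presented shift.

    Every database accession receives a baseline value
    ``2^N(base_log2_mean, noise_sd)``; presented accessions are multiplied by
    ``2^log2_shift``. The defaults (two-fold shift, 0.5 log2-units of noise)
    give the rank-sum comparison essentially full power at ≥ 50 proteins per
    group while a zero shift leaves the groups exchangeable.
    """
    if log2_shift < 0:
        raise ValueError("log2_shift must be >= 0")
    rng = np.random.default_rng(seed)
    presented = set(presented_accessions)
    profile = ExpressionProfile()
    for accession in sorted(db.entries):
        log2_value = rng.normal(base_log2_mean, noise_sd)
        if accession in presented:
            log2_value += log2_shift
        profile.values[accession] = float(2.0**log2_value)
        profile.aux_flag[accession] = "core"
    return profile


def simulate_locations(
    db: SequenceDB,
    compartments: Sequence[str] = _DEFAULT_COMPARTMENTS,
    unknown_fraction: float = 0.1,
    max_compartments: int = 3,
    seed: int = 0,
) -> CellularLocationMap:
    """Generate a subcellular-location map over a proteome.

    Each protein is unannotated (empty list, meaning unknown) with
    probability ``unknown_fraction`` and otherwise assigned 1 to
    ``max_compartments`` distinct compartments uniformly at random.
    """
    if not (0.0 <= unknown_fraction <= 1.0):
        raise ValueError("unknown_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pool = list(compartments)
    locmap = CellularLocationMap()
    for accession in sorted(db.entries):
        if rng.random() < unknown_fraction:
            locmap.locations[accession] = []
        else:
            k = int(rng.integers(1, min(max_compartments, len(pool)) + 1))
            chosen = rng.choice(len(pool), size=k, replace=False)
            locmap.locations[accession] = [pool[i] for i in sorted(chosen)]
        locmap.aux_flag[accession] = "core"
    return locmap
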