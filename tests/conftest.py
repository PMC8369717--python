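import pytest

from ligandkit import (
    ExperimentSet,
    IdentificationRow,
    IdentificationTable,
    SequenceDB,
    FastaEntry,
    build_experiment,
    simulate_experiment,
    simulate_proteome,
)


def make_db(**seqs: str) -> SequenceDB:
    """In-memory sequence database from accession=sequence keyword pairs."""
    db = SequenceDB()
    for acc, seq in seqs.items():
        db.entries[acc] = FastaEntry(sequence=seq, entry_name=acc)
    return db


def make_table(*rows, name="test") -> IdentificationTable:
    """Identification table from (peptide, accession[, start, end]) tuples."""
    out = []
    for row in rows:
        if len(row) == 2:
            out.append(IdentificationRow(row[0], row[1]))
        else:
            out.append(IdentificationRow(*row))
    return IdentificationTable(rows=out, source_name=name)


def synthetic_experiment(seed, n_proteins=10, n_peptides=50, length_range=(80, 150),
                         organisms=None, name=None):
    """A small simulated experiment with its database and ground truth."""
    db, _ = simulate_proteome(n_proteins, length_range=length_range,
                              organisms=organisms, seed=seed)
    table, truth = simulate_experiment(db, n_peptides=n_peptides, seed=seed + 1000)
    exp = build_experiment(table, db, name=name or f"exp{seed}")
    return db, exp, truth


def synthetic_expset(n_experiments, base_seed, n_proteins=12, n_peptides=60):
    """Several experiments sharing one synthetic database."""
    db, _ = simulate_proteome(n_proteins, length_range=(80, 150), seed=base_seed)
    exps = []
    for i in range(n_experiments):
        table, _ = simulate_experiment(db, n_peptides=n_peptides, seed=base_seed + i + 1)
        exps.append(build_experiment(table, db, name=f"exp{i + 1}"))
    return db, ExperimentSet.from_experiments(exps)


@pytest.fixture
def tiny_db():
    return make_db(P1="MKLVAQWERTY", P2="ABCDEFKLVGH")
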