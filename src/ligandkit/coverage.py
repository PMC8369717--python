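"""Per-protein coverage arrays and the coverage-based experiment distance.

Coverage is the positional analogue of sequencing depth: for each residue of
a parent protein it counts the identified peptides whose occurrence interval
contains that position. Each *distinct* peptide sequence contributes one
count per occurrence interval — a peptide repeated at two sites covers both,
while duplicate identification rows never double-count.

The difference in presentation of one protein between two conditions is the
L1 distance between its coverage arrays, and the distance between two
experiments is that score averaged over a fixed protein universe. With the
universe held fixed this is a scaled L1 metric on concatenated coverage
vectors, so symmetry and the triangle inequality hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import Experiment, ExperimentSet, proteins_union


@dataclass
class CoverageArray:
    """Integer per-residue peptide coverage of one protein.

    ``values[i]`` is the number of counted peptide occurrences whose interval
    contains position ``i``; the array has the same length as the protein.
    """

    accession: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be a 1-D vector")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def total(self) -> int:
        """Sum over cells = sum of counted occurrence-interval lengths."""
        return int(self.values.sum())

    @property
    def max(self) -> int:
        return int(self.values.max()) if len(self.values) else 0


@dataclass
class DistanceMatrix:
    """Symmetric experiment × experiment coverage-distance matrix."""

    names: list[str]
    d: np.ndarray
    protein_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.names)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match names")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.names, columns=self.names)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="experiment")


def compute_coverage(exp: Experiment, accession: str) -> CoverageArray:
    """Coverage array of one inferred protein in one experiment.

    Every mapping interval of every distinct peptide increments all covered
    cells by one; one peptide mapped at two sites contributes 2 at doubly
    covered cells.
    """
    if accession not in exp.proteins:
        raise KeyError(
            f"accession {accession!r} is not an inferred protein of experiment {exp.name!r}"
        )
    values = np.zeros(exp.proteins[accession].length, dtype=np.int64)
    for pep in exp.peptides.values():
        for start, end in pep.mappings_to(accession):
            values[start:end] += 1
    return CoverageArray(accession=accession, values=values)


def _coverage_or_zeros(exp: Experiment, accession: str, length: int) -> np.ndarray:
    if accession in exp.proteins:
        return compute_coverage(exp, accession).values
    return np.zeros(length, dtype=np.int64)


def protein_coverage_distance(c1: CoverageArray, c2: CoverageArray) -> float:
    """Sum of absolute per-residue coverage differences for one protein.

    Zero iff the arrays are identical. A length mismatch signals inconsistent
    sequence databases and raises.
    """
    if c1.accession != c2.accession:
        raise ValueError(
            f"coverage arrays refer to different proteins: {c1.accession!r} vs {c2.accession!r}"
        )
    if len(c1) != len(c2):
        raise ValueError(
            f"coverage length mismatch for {c1.accession!r}: {len(c1)} vs {len(c2)} "
            "(inconsistent sequence databases?)"
        )
    return float(np.abs(c1.values - c2.values).sum())


def _universe_lengths(
    experiments: Iterable[Experiment], universe: Iterable[str]
) -> dict[str, int]:
    lengths: dict[str, int] = {}
    exps = list(experiments)
    for acc in universe:
        found = None
        for exp in exps:
            if acc in exp.proteins:
                length = exp.proteins[acc].length
                if found is None:
                    found = length
                elif found != length:
                    raise ValueError(
                        f"protein {acc!r} has two different lengths across experiments "
                        f"({found} vs {length}); experiments must share a sequence database"
                    )
        if found is not None:
            lengths[acc] = found
    return lengths


def experiment_distance(
    e1: Experiment,
    e2: Experiment,
    protein_universe: Optional[Iterable[str]] = None,
    *,
    length_normalized: bool = False,
) -> float:
    """Coverage distance between two experiments.

    The per-protein L1 coverage distance is averaged over ``protein_universe``
    (default: the union of the two experiments' inferred proteins); a protein
    absent from an experiment contributes an all-zero array. With
    ``length_normalized`` each protein's score is divided by its length
    before averaging.
    """
    if protein_universe is None:
        universe = sorted(e1.protein_accessions() | e2.protein_accessions())
    else:
        universe = sorted(set(protein_universe))
    if not universe:
        raise ValueError("protein universe is empty")
    lengths = _universe_lengths((e1, e2), universe)
    total = 0.0
    for acc in universe:
        if acc not in lengths:
            continue  # inferred in neither experiment: zero-vs-zero, score 0
        a = _coverage_or_zeros(e1, acc, lengths[acc])
        b = _coverage_or_zeros(e2, acc, lengths[acc])
        score = float(np.abs(a - b).sum())
        if length_normalized:
            score /= lengths[acc]
        total += score
    return total / len(universe)


def distance_matrix(
    expset: ExperimentSet, *, length_normalized: bool = False
) -> DistanceMatrix:
    """Pairwise coverage-distance matrix over an experiment set.

    The protein universe is fixed to the union of inferred proteins over the
    whole set and is identical for every pair, which makes the result a
    scaled L1 metric (triangle inequality guaranteed). The universe used is
    recorded on the returned matrix.
    """
    names = expset.names
    universe = sorted(proteins_union(expset))
    lengths = _universe_lengths(expset, universe)
    # concatenated coverage vector per experiment, fixed accession order
    flat: dict[str, np.ndarray] = {}
    for exp in expset:
        parts = []
        for acc in universe:
            v = _coverage_or_zeros(exp, acc, lengths[acc]).astype(float)
            if length_normalized:
                v = v / lengths[acc]
            parts.append(v)
        flat[exp.name] = np.concatenate(parts)
    n = len(names)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(
                np.abs(flat[names[i]] - flat[names[j]]).sum()
            ) / len(universe)
    return DistanceMatrix(names=names, d=d, protein_universe=universe)


def n_coverage_table(expset: ExperimentSet, accession: str) -> pd.DataFrame:
    """Coverage of one protein across all experiments of a set.

    One row per experiment (all zeros where the protein was not inferred),
    one column per residue position (0-based). This is the tabular form of
    the n-coverage representation comparing presentation of the same protein
    across conditions.
    """
    lengths = {}
    for exp in expset:
        if accession in exp.proteins:
            lengths[exp.name] = exp.proteins[accession].length
    if not lengths:
        raise KeyError(f"protein {accession!r} is inferred in no experiment of the set")
    length = next(iter(lengths.values()))
    if any(l != length for l in lengths.values()):
        raise ValueError(f"protein {accession!r} has inconsistent lengths across experiments")
    rows = {
        exp.name: _coverage_or_zeros(exp, accession, length) for exp in expset
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(length))


def coverage_color_scale(c: CoverageArray) -> np.ndarray:
    """Map a coverage array to [0, 1] for color-gradient rendering.

    Max-normalization: ``values / max(values)`` when the maximum is positive,
    all zeros otherwise. Monotone in coverage and invariant to scaling the
    array by a positive constant.
    """
    m = c.max
    if m == 0:
        return np.zeros(len(c), dtype=float)
    return c.values / float(m)
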