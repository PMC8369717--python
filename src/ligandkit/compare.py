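"""Experiment-set comparison: overlap counts, Jaccard matrices, classical MDS.

Pairwise overlap (exact peptide or protein matches between two experiments)
is a raw similarity that is biased by immunopeptidome size; the Jaccard
index |A∩B|/|A∪B| normalizes for it. Classical (Torgerson) MDS embeds any
:class:`~ligandkit.coverage.DistanceMatrix` into k dimensions for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Set

import numpy as np
import pandas as pd

from .coverage import DistanceMatrix
from .model import Experiment, ExperimentSet

logger = logging.getLogger("ligandkit")


@dataclass
class OverlapMatrix:
    """Symmetric pairwise overlap counts at peptide or protein level.

    The diagonal holds each experiment's own set size, so every off-diagonal
    entry is bounded by the smaller of the two diagonal entries.
    """

    names: list[str]
    m: np.ndarray
    level: str

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m)
        if self.level not in ("peptide", "protein"):
            raise ValueError(f"level must be 'peptide' or 'protein', got {self.level!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.m, index=self.names, columns=self.names)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="experiment")


@dataclass
class MDSEmbedding:
    """Classical MDS embedding of a distance matrix.

    ``coords`` is experiments × k; ``eigenvalues`` is the full descending
    spectrum of the double-centered matrix; ``clipped_mass`` is the total
    magnitude of negative eigenvalues clipped to zero (0 for distances that
    are exactly Euclidean-realizable); ``stress`` is the relative residual
    √(Σ(d−d̂)²/Σd²) between input and embedded distances.
    """

    names: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    stress: float
    clipped_mass: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        k = self.coords.shape[1]
        return pd.DataFrame(
            self.coords, index=self.names, columns=[f"dim{i + 1}" for i in range(k)]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="experiment")


def jaccard(set_a: Set, set_b: Set) -> float:
    """Jaccard index |A∩B| / |A∪B| of two finite sets.

    Two empty sets are identical, so the index is 1.0 (logged, since an
    empty comparison usually signals an upstream problem).
    """
    union = len(set_a | set_b)
    if union == 0:
        logger.info("jaccard of two empty sets: returning 1.0 (identical sets)")
        return 1.0
    return len(set_a & set_b) / union


def _level_sets(expset: ExperimentSet, level: str) -> list[set[str]]:
    if level == "peptide":
        return [exp.peptide_sequences() for exp in expset]
    if level == "protein":
        return [exp.protein_accessions() for exp in expset]
    raise ValueError(f"level must be 'peptide' or 'protein', got {level!r}")


def overlap_matrix(expset: ExperimentSet, level: str = "peptide") -> OverlapMatrix:
    """Pairwise exact-match counts between experiments.

    Entries are computed on distinct peptide sequences (or distinct protein
    accessions); the diagonal is each experiment's set size.
    """
    sets = _level_sets(expset, level)
    n = len(sets)
    m = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        m[i, i] = len(sets[i])
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = len(sets[i] & sets[j])
    return OverlapMatrix(names=expset.names, m=m, level=level)


def jaccard_matrix(expset: ExperimentSet, level: str = "peptide") -> OverlapMatrix:
    """Pairwise Jaccard indices between experiments; the diagonal is 1.0."""
    sets = _level_sets(expset, level)
    n = len(sets)
    m = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jaccard(sets[i], sets[j])
    return OverlapMatrix(names=expset.names, m=m, level=level)


def classical_mds(dm: DistanceMatrix, k: int) -> MDSEmbedding:
    """Classical (Torgerson) multidimensional scaling.

    Squares the distances, double-centers (B = −½·J·D²·J with
    J = I − 11ᵀ/n), eigendecomposes B, and takes the top-k eigenvectors
    scaled by the square root of their eigenvalues. Negative eigenvalues
    (non-Euclidean residual) are clipped to zero and their total magnitude
    reported. Each coordinate axis is sign-flipped so that its first nonzero
    loading is positive, making the embedding byte-reproducible; axes with
    eigenvalues equal within 1e-12 are rotation-degenerate and follow the
    decomposition order.
    """
    n = len(dm.names)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    D = dm.d
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    clipped_mass = float(np.abs(eigvals[eigvals < 0]).sum())
    lam = np.clip(eigvals[:k], 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(lam)
    # deterministic sign convention: first nonzero loading of each axis positive
    for col in range(k):
        nz = np.flatnonzero(np.abs(coords[:, col]) > 1e-12)
        if nz.size and coords[nz[0], col] < 0:
            coords[:, col] = -coords[:, col]
    dhat = np.sqrt(
        np.maximum(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2), 0.0
        )
    )
    denom = float((D**2).sum())
    stress = float(np.sqrt(((D - dhat) ** 2).sum() / denom)) if denom > 0 else 0.0
    return MDSEmbedding(
        names=list(dm.names),
        coords=coords,
        eigenvalues=eigvals,
        stress=stress,
        clipped_mass=clipped_mass,
    )
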