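"""Flanking-region extraction and position frequency matrices.

The residues immediately upstream and downstream of an identified peptide in
its parent protein carry the cleavage context of the antigen-processing
machinery. This module extracts fixed-length flanks (padded with ``-`` at
protein termini) and summarizes sets of equal-length sequences as position
frequency matrices with per-position information content, the standard
motif-analysis primitives.

Flanks are extracted per mapping interval, not per distinct peptide:
cleavage context is positional, so repeated occurrences contribute their
local context separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CANONICAL_AA, EXTENDED_AA
from .model import Experiment

#: Padding character used beyond protein termini.
PAD_CHAR = "-"

#: Default flank length in residues.
DEFAULT_FLANK_LENGTH = 5

#: Column alphabet of a PFM: canonical residues, ambiguity codes, pad.
PFM_ALPHABET = tuple(EXTENDED_AA) + (PAD_CHAR,)

_LOG2_20 = float(np.log2(len(CANONICAL_AA)))


@dataclass(frozen=True)
class FlankRecord:
    """Flanking context of one peptide occurrence in one protein."""

    peptide: str
    accession: str
    start: int
    end: int
    upstream: str
    downstream: str


@dataclass
class FlankSet:
    """All flanking n-mers of an experiment, one record per mapping interval."""

    n: int
    records: list[FlankRecord]

    def __len__(self) -> int:
        return len(self.records)

    def upstream_sequences(self) -> list[str]:
        return [r.upstream for r in self.records]

    def downstream_sequences(self) -> list[str]:
        return [r.downstream for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.peptide, r.accession, r.start, r.upstream, r.downstream)
                for r in self.records
            ],
            columns=["peptide", "protein", "start", "upstream", "downstream"],
        )

    def to_tsv(self, path: str | Path) -> None:
        """Export in a form directly usable as motif-tool input."""
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue frequencies of a set of equal-length sequences.

    Rows (positions) sum to 1; columns follow :data:`PFM_ALPHABET`.
    """

    freqs: np.ndarray
    n_sequences: int
    alphabet: tuple[str, ...] = PFM_ALPHABET

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freqs, index=range(self.length), columns=list(self.alphabet)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="position")


def extract_flanks(exp: Experiment, n: int = DEFAULT_FLANK_LENGTH) -> FlankSet:
    """Extract the n-residue upstream and downstream flanks of every mapping.

    Upstream is the ``n`` residues before the occurrence start, downstream
    the ``n`` residues after its end; at protein termini the flank is padded
    with ``-`` (left-padded upstream, right-padded downstream) so both
    strings always have length ``n``.
    """
    if n < 1:
        raise ValueError("flank length n must be >= 1")
    records: list[FlankRecord] = []
    for pep in exp.peptides.values():
        for accession, start, end in pep.mappings:
            seq = exp.proteins[accession].sequence
            upstream = seq[max(0, start - n) : start].rjust(n, PAD_CHAR)
            downstream = seq[end : end + n].ljust(n, PAD_CHAR)
            records.append(
                FlankRecord(
                    peptide=pep.sequence,
                    accession=accession,
                    start=start,
                    end=end,
                    upstream=upstream,
                    downstream=downstream,
                )
            )
    records.sort(key=lambda r: (r.peptide, r.accession, r.start))
    return FlankSet(n=n, records=records)


def position_frequency_matrix(seqs: Sequence[str]) -> PositionFrequencyMatrix:
    """Tally a set of equal-length sequences into a PFM.

    ``freqs[p][a]`` is the fraction of sequences carrying character ``a`` at
    position ``p``; every row sums to one.
    """
    if not seqs:
        raise ValueError("at least one sequence is required")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("all sequences must have equal length")
    index = {c: i for i, c in enumerate(PFM_ALPHABET)}
    counts = np.zeros((length, len(PFM_ALPHABET)), dtype=float)
    for s in seqs:
        for p, c in enumerate(s.upper()):
            if c not in index:
                raise ValueError(f"character {c!r} outside the PFM alphabet")
            counts[p, index[c]] += 1
    return PositionFrequencyMatrix(freqs=counts / len(seqs), n_sequences=len(seqs))


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-position information content in bits, IC = log2(20) − H.

    The pad column is excluded from the entropy alphabet: non-pad
    frequencies are renormalized before computing H, and an all-pad position
    has IC 0. IC is clipped at 0 and bounded above by log2(20) ≈ 4.32 bits
    (a one-hot position).
    """
    pad_col = pfm.alphabet.index(PAD_CHAR)
    residue_freqs = np.delete(pfm.freqs, pad_col, axis=1)
    ic = np.zeros(pfm.length, dtype=float)
    for p in range(pfm.length):
        mass = residue_freqs[p].sum()
        if mass <= 0:
            continue
        f = residue_freqs[p] / mass
        nz = f[f > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic[p] = max(0.0, _LOG2_20 - entropy)
    return ic
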