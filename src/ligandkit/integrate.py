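"""Link expression and subcellular-location layers to an experiment.

Two questions are answered here. First, are the proteins whose peptides are
presented on HLA expressed differently from the profiled proteins that are
not presented? The groups are compared with a two-sided Mann–Whitney
rank-sum test (expression values are not normally distributed). Second, from
which subcellular compartments does the presented proteome originate?
Proteins annotated to several compartments count once in each; proteins
without annotation are pooled under ``"unknown"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erfc, sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CellularLocationMap, ExpressionProfile
from .model import Experiment

logger = logging.getLogger("ligandkit")

#: Compartment bucket for proteins with no (or empty) location annotation.
UNKNOWN_COMPARTMENT = "unknown"

#: Largest combined sample size handled by exact permutation enumeration.
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class ExpressionComparison:
    """Presented-vs-background expression comparison result."""

    presented_values: np.ndarray
    background_values: np.ndarray
    statistic: float  # Mann–Whitney U of the presented group
    p_value: float
    n_presented: int
    n_background: int
    n_excluded_missing: int = 0
    n_excluded_aux: int = 0

    def summary_json(self) -> str:
        return json.dumps(
            {
                "U": self.statistic,
                "p_value": self.p_value,
                "n_presented": self.n_presented,
                "n_background": self.n_background,
                "n_excluded_missing": self.n_excluded_missing,
                "n_excluded_aux": self.n_excluded_aux,
            }
        )


@dataclass
class CompartmentCounts:
    """Per-compartment protein and distinct-peptide counts.

    ``counts`` always contains the ``"unknown"`` bucket; a protein annotated
    to several compartments contributes once to each of them.
    """

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, n_prot, n_pep) for name, (n_prot, n_pep) in self.counts.items()
        ]
        return pd.DataFrame(rows, columns=["compartment", "n_proteins", "n_peptides"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def split_presented_background(
    exp: Experiment,
    profile: ExpressionProfile,
    *,
    include_auxiliary: bool = False,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Split a profiled expression table into presented and background groups.

    Presented = profiled accessions that are inferred proteins of the
    experiment; background = the remaining profiled accessions. Inferred
    proteins absent from the profile are excluded and counted in the returned
    report, as are auxiliary-flagged entries (unless ``include_auxiliary``).
    The two groups partition the retained profile.

    Raises
    ------
    ValueError
        If either group ends up empty — there is nothing to compare.
    """
    if not profile.values:
        raise ValueError("expression profile is empty")
    inferred = exp.protein_accessions()
    presented: list[float] = []
    background: list[float] = []
    n_aux = 0
    for accession, value in profile.values.items():
        if not include_auxiliary and profile.flag(accession) == "auxiliary":
            n_aux += 1
            continue
        (presented if accession in inferred else background).append(value)
    n_missing = sum(1 for acc in inferred if acc not in profile.values)
    if n_missing:
        logger.info(
            "%s: %d inferred proteins absent from the expression profile",
            exp.name,
            n_missing,
        )
    if not presented:
        raise ValueError("presented group is empty: no inferred protein is profiled")
    if not background:
        raise ValueError("background group is empty: every profiled protein is presented")
    report = {"n_excluded_missing": n_missing, "n_excluded_aux": n_aux}
    return np.asarray(presented, dtype=float), np.asarray(background, dtype=float), report


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U of x against y via midranks (ties counted half)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rank_sum_x = ranks[: len(x)].sum()
    return float(rank_sum_x - len(x) * (len(x) + 1) / 2)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    For combined sample sizes n+m ≤ 12 the null distribution is enumerated
    exactly over all C(n+m, n) group assignments of the pooled values (valid
    under ties); larger samples use the normal approximation with tie and
    continuity corrections. Returns (U of the first sample, two-sided p).
    Identical values across both groups give p = 1.0 — no evidence, not an
    error.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if np.unique(np.concatenate([x, y])).size == 1:
        return u_obs, 1.0
    mid = n * m / 2
    if n + m <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([x, y])
        total = comb(n + m, n)
        extreme = 0
        obs_dev = abs(u_obs - mid)
        for idx in combinations(range(n + m), n):
            xi = pooled[list(idx)]
            yi = np.delete(pooled, list(idx))
            u = _u_statistic(xi, yi)
            if abs(u - mid) >= obs_dev - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(p)


def compare_expression(
    exp: Experiment,
    profile: ExpressionProfile,
    *,
    include_auxiliary: bool = False,
) -> ExpressionComparison:
    """Presented-vs-background comparison with the rank-sum test applied."""
    presented, background, report = split_presented_background(
        exp, profile, include_auxiliary=include_auxiliary
    )
    u, p = rank_sum_test(presented, background)
    return ExpressionComparison(
        presented_values=presented,
        background_values=background,
        statistic=u,
        p_value=p,
        n_presented=len(presented),
        n_background=len(background),
        n_excluded_missing=report["n_excluded_missing"],
        n_excluded_aux=report["n_excluded_aux"],
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg FDR-adjusted p-values for a family of comparisons."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def compartment_counts(exp: Experiment, locmap: CellularLocationMap) -> CompartmentCounts:
    """Count inferred proteins and distinct peptides per subcellular compartment.

    ``n_proteins`` is the number of inferred proteins annotated to the
    compartment; ``n_peptides`` is the number of distinct peptide sequences
    mapping to at least one such protein. Proteins absent from the location
    map, or annotated with an empty list, are counted under ``"unknown"``.
    """
    compartment_of: dict[str, list[str]] = {}
    for accession in exp.proteins:
        annotated = locmap.locations.get(accession, [])
        compartment_of[accession] = annotated if annotated else [UNKNOWN_COMPARTMENT]

    all_compartments = sorted({c for cs in compartment_of.values() for c in cs})
    counts: dict[str, tuple[int, int]] = {}
    for compartment in all_compartments + (
        [UNKNOWN_COMPARTMENT] if UNKNOWN_COMPARTMENT not in all_compartments else []
    ):
        proteins = {acc for acc, cs in compartment_of.items() if compartment in cs}
        peptides = {
            seq
            for seq, pep in exp.peptides.items()
            if pep.accessions() & proteins
        }
        counts[compartment] = (len(proteins), len(peptides))
    return CompartmentCounts(counts=counts)
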