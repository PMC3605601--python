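"""Plaintext reference pipeline.

Computes the same tables, exact integer statistic fractions and decisions as
the secure path, directly from the staged genotype matrix — no shares, no
protocols.  The secure pipeline must reproduce its decision bits exactly;
tests enforce that, and the CLI can run both sides for verification.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import (
    TrendWeights,
    catt_fraction,
    chi2_fraction,
    chi2_prop_fraction,
    tdt_fraction,
)
from .cohort import Node, evaluate_criterion_plain
from .genotypes import ENCODING, GenotypeMatrix, TrioStructure
from .significance import RationalThreshold, bh_rank_thresholds


def _code_rows(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(fA, fB) count arrays of shape (n_snps, n_donors)."""
    fa = np.array([[ENCODING[c][0] for c in row] for row in matrix.calls])
    fb = np.array([[ENCODING[c][1] for c in row] for row in matrix.calls])
    return fa, fb


def allele_counts(
    matrix: GenotypeMatrix, case_mask: np.ndarray, ctrl_mask: np.ndarray
) -> list[tuple[int, int, int, int]]:
    """Per-SNP (a, b, c, d): allele A/B totals in cases and controls."""
    fa, fb = _code_rows(matrix)
    a = fa[:, case_mask].sum(axis=1)
    c = fb[:, case_mask].sum(axis=1)
    b = fa[:, ctrl_mask].sum(axis=1)
    d = fb[:, ctrl_mask].sum(axis=1)
    return [tuple(int(v) for v in row) for row in zip(a, b, c, d)]


def genotype_counts(
    matrix: GenotypeMatrix, case_mask: np.ndarray, ctrl_mask: np.ndarray
) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """Per-SNP ((r0,r1,r2), (s0,s1,s2)) genotype-class counts, NN excluded."""
    out = []
    for row in matrix.calls:
        arr = np.array(row)
        r = tuple(int(((arr == g) & case_mask).sum()) for g in ("AA", "AB", "BB"))
        s = tuple(int(((arr == g) & ctrl_mask).sum()) for g in ("AA", "AB", "BB"))
        out.append((r, s))
    return out


def tdt_uv(matrix: GenotypeMatrix, trios: TrioStructure) -> list[tuple[int, int]]:
    """Per-SNP (u, v) over trios whose parents are both heterozygous."""
    out = []
    for row in matrix.calls:
        u = v = 0
        for child, mother, father in trios.trios:
            if row[mother] == "AB" and row[father] == "AB":
                if row[child] == "AA":
                    u += 1
                elif row[child] == "BB":
                    v += 1
        out.append((u, v))
    return out


def statistic_fractions(
    matrix: GenotypeMatrix,
    test: str,
    case_mask: np.ndarray | None = None,
    ctrl_mask: np.ndarray | None = None,
    trios: TrioStructure | None = None,
    weights: TrendWeights = TrendWeights(),
) -> list[tuple[int, int]]:
    """Exact integer (m, n) fractions per SNP for one of the four tests."""
    if test in ("chi2", "chi2prop"):
        frac = chi2_fraction if test == "chi2" else chi2_prop_fraction
        return [frac(a, b, c, d) for a, b, c, d in allele_counts(matrix, case_mask, ctrl_mask)]
    if test == "catt":
        return [
            catt_fraction(r, s, weights)
            for r, s in genotype_counts(matrix, case_mask, ctrl_mask)
        ]
    if test == "tdt":
        if trios is None:
            raise ValueError("tdt requires trio structure")
        return [tdt_fraction(u, v) for u, v in tdt_uv(matrix, trios)]
    raise ValueError(f"unknown test {test!r}")


@dataclass
class PlainDecisions:
    snp_ids: list[str]
    decisions: list[int]
    undefined: list[int]
    rejection_count: int


def decide_fractions(
    fractions: Sequence[tuple[int, int]], th: RationalThreshold
) -> tuple[list[int], list[int]]:
    """Exact rational decisions m*q >= p*n; zero denominators are undefined
    and never significant."""
    decisions, undefined = [], []
    for m, n in fractions:
        if n == 0:
            decisions.append(0)
            undefined.append(1)
        else:
            decisions.append(1 if m * th.q >= th.p * n else 0)
            undefined.append(0)
    return decisions, undefined


def bh_plain(
    fractions: Sequence[tuple[int, int]],
    alpha: float,
    snp_ids: Sequence[str],
    q_precision: int,
) -> PlainDecisions:
    """Benjamini-Hochberg with the same rational per-rank thresholds the
    secure procedure uses, evaluated in the clear."""
    norm = [(m, n) if n > 0 else (0, 1) for m, n in fractions]
    undefined = [1 if n == 0 else 0 for _, n in fractions]

    # descending by fraction value; exact comparison via cross-multiplication
    def cmp(i, j):
        mi, ni = norm[i]
        mj, nj = norm[j]
        lhs, rhs = mi * nj, mj * ni
        return -1 if lhs > rhs else (1 if lhs < rhs else 0)

    order = sorted(range(len(norm)), key=functools.cmp_to_key(cmp))
    thresholds = bh_rank_thresholds(alpha, len(norm), q_precision)
    i_max = -1
    for rank, idx in enumerate(order):
        m, n = norm[idx]
        th = thresholds[rank]
        if m * th.q >= th.p * n:
            i_max = rank
    decisions = [0] * len(norm)
    for rank, idx in enumerate(order):
        if rank <= i_max:
            decisions[idx] = 1
    return PlainDecisions(
        snp_ids=list(snp_ids),
        decisions=decisions,
        undefined=undefined,
        rejection_count=sum(decisions),
    )


def cohort_masks(
    matrix: GenotypeMatrix,
    case_ids: Sequence[str] | None = None,
    phenotypes: pd.DataFrame | None = None,
    criterion: Node | str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Case/control boolean masks, from explicit IDs (scenario 1) or from a
    plaintext criterion evaluation (scenario 2); controls are the complement."""
    if case_ids is not None:
        case_set = set(case_ids)
        case_mask = np.array([d in case_set for d in matrix.donor_ids])
    elif criterion is not None and phenotypes is not None:
        flags = evaluate_criterion_plain(phenotypes.loc[matrix.donor_ids], criterion)
        case_mask = np.asarray(flags, dtype=bool)
    else:
        raise ValueError("need case_ids or (phenotypes, criterion)")
    return case_mask, ~case_mask
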