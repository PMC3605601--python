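"""Calibration diagnostics: reconstructed statistic fractions per SNP.

These helpers pool all three hosts' shares to recover the exact (m, n)
statistic fractions — a diagnostic/validation action that a deployed system
would only perform under an explicit disclosure agreement.  They exist for
null-calibration studies and the reproduction script; the production path
releases decision bits only.

Secure computation is streamed one SNP at a time (share the four rows,
tabulate, reconstruct the fraction, discard the shares), so genome-scale
panels never materialise a full shared database in memory.
"""

from __future__ import annotations

from typing import Sequence

from .assoc import (
    TrendWeights,
    chi2_independence,
    chi2_proportion,
    cochran_armitage,
    tdt,
)
from .cohort import IndexVector, complement
from .contingency import (
    allele_table,
    genotype_table,
    heterozygous_parent_vector,
    tdt_counts,
)
from .errors import ConfigurationError
from .genotypes import ENCODING, GenotypeMatrix, TrioStructure
from .mpc import Engine


def _share_snp_rows(engine: Engine, calls: Sequence[str]):
    enc = [ENCODING[c] for c in calls]
    fA = engine.share_vector([e[0] for e in enc])
    fB = engine.share_vector([e[1] for e in enc])
    hAA = engine.share_vector([1 if c == "AA" else 0 for c in calls])
    hBB = engine.share_vector([1 if c == "BB" else 0 for c in calls])
    return fA, fB, hAA, hBB


def secure_fractions(
    engine: Engine,
    matrix: GenotypeMatrix,
    test: str,
    case_bits: Sequence[int] | None = None,
    trios: TrioStructure | None = None,
    weights: TrendWeights = TrendWeights(),
) -> list[tuple[int, int]]:
    """Run the secure tabulation + statistic for every SNP and reconstruct
    the exact integer fractions (m, n).  ``case_bits`` is the plaintext
    membership vector for case-control tests; controls are its complement."""
    out: list[tuple[int, int]] = []
    if test == "tdt":
        if trios is None:
            raise ConfigurationError("tdt requires a trio structure")
        trios.validate(matrix.n_donors)
        mo, fa_idx, ch = trios.mothers, trios.fathers, trios.children
        for calls in matrix.calls:
            fA, fB, hAA, hBB = _share_snp_rows(engine, calls)
            z = heterozygous_parent_vector(
                engine, fA.take(mo), fB.take(mo), fA.take(fa_idx), fB.take(fa_idx)
            )
            stat = tdt(engine, tdt_counts(engine, z, hAA.take(ch), hBB.take(ch)))
            out.append((engine.reconstruct(stat.m), engine.reconstruct(stat.n)))
        return out

    if case_bits is None:
        raise ConfigurationError(f"test {test!r} requires case membership bits")
    x = IndexVector(engine.share_vector([int(b) for b in case_bits]).rows, engine.ring)
    y = complement(x)
    for calls in matrix.calls:
        fA, fB, hAA, hBB = _share_snp_rows(engine, calls)
        if test in ("chi2", "chi2prop"):
            t = allele_table(engine, x, y, fA, fB)
            stat = (chi2_independence if test == "chi2" else chi2_proportion)(engine, t)
        elif test == "catt":
            gt = genotype_table(engine, x, y, fA, fB, hAA, hBB)
            stat = cochran_armitage(engine, gt, weights)
        else:
            raise ConfigurationError(f"unknown test {test!r}")
        out.append((engine.reconstruct(stat.m), engine.reconstruct(stat.n)))
    return out


def secure_fractions_multi(
    engine: Engine,
    matrix: GenotypeMatrix,
    tests: Sequence[str],
    case_bits: Sequence[int],
    weights: TrendWeights = TrendWeights(),
) -> dict[str, list[tuple[int, int]]]:
    """As :func:`secure_fractions` for several case-control tests at once,
    sharing each SNP's rows (and its allele table) a single time."""
    x = IndexVector(engine.share_vector([int(b) for b in case_bits]).rows, engine.ring)
    y = complement(x)
    out: dict[str, list[tuple[int, int]]] = {t: [] for t in tests}
    want_allele = [t for t in tests if t in ("chi2", "chi2prop")]
    for calls in matrix.calls:
        fA, fB, hAA, hBB = _share_snp_rows(engine, calls)
        if want_allele:
            t2 = allele_table(engine, x, y, fA, fB)
            for t in want_allele:
                stat = (chi2_independence if t == "chi2" else chi2_proportion)(engine, t2)
                out[t].append((engine.reconstruct(stat.m), engine.reconstruct(stat.n)))
        if "catt" in tests:
            gt = genotype_table(engine, x, y, fA, fB, hAA, hBB)
            stat = cochran_armitage(engine, gt, weights)
            out["catt"].append((engine.reconstruct(stat.m), engine.reconstruct(stat.n)))
    return out
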