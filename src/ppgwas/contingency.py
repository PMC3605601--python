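"""Secure assembly of contingency tables from shared rows and index vectors.

With the allele-count encoding, every cell of the allele 2x2 table is an
inner product between an index vector and a genotype row:

    a = x . fA    c = x . fB      (cases)
    b = y . fA    d = y . fB      (controls)

For the genotype 2x3 table the class indicators come from the redundant
hAA/hBB flag rows plus ``iAB = fA * fB`` (1 exactly for heterozygotes under
valid encodings), so each cell is again a dot product.  Missing (NN) donors
have all indicators zero and drop out of every margin, including N.

For the TDT, trios are informative when both parents are heterozygous:
``z = (mother_fA * mother_fB) * (father_fA * father_fB)`` is 1 exactly then
(any homozygous or missing parent zeroes a factor), and

    u = z . child_hAA      v = z . child_hBB
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ProtocolError
from .genotypes import SharedGenotypeDB, TrioStructure
from .mpc import Engine, SharedBit, SharedScalar, SharedVector
from .cohort import IndexVector


@dataclass
class AlleleTable2x2:
    """Allele counts: rows cases/controls, columns allele A / allele B."""

    a: SharedScalar  # cases, allele A
    c: SharedScalar  # cases, allele B
    b: SharedScalar  # controls, allele A
    d: SharedScalar  # controls, allele B


@dataclass
class GenotypeTable2x3:
    """Genotype-class counts with margins (NN donors excluded throughout)."""

    r0: SharedScalar
    r1: SharedScalar
    r2: SharedScalar
    m1: SharedScalar  # case total
    s0: SharedScalar
    s1: SharedScalar
    s2: SharedScalar
    m2: SharedScalar  # control total
    n0: SharedScalar
    n1: SharedScalar
    n2: SharedScalar
    N: SharedScalar   # grand total


@dataclass
class TdtCounts:
    u: SharedScalar  # AA children of double-heterozygote trios
    v: SharedScalar  # BB children of double-heterozygote trios


def secure_dot(engine: Engine, x: SharedVector, y: SharedVector) -> SharedScalar:
    """Inner product of two shared vectors (one batched multiplication round)."""
    if len(x) != len(y):
        raise ProtocolError(f"dot-product length mismatch: {len(x)} vs {len(y)}")
    return engine.dot(x, y)


def allele_table(
    engine: Engine,
    x: IndexVector,
    y: IndexVector,
    gA: SharedVector,
    gB: SharedVector,
) -> AlleleTable2x2:
    if not len(x) == len(y) == len(gA) == len(gB):
        raise ProtocolError("index vectors and genotype rows must share one length")
    return AlleleTable2x2(
        a=engine.dot(x, gA),
        c=engine.dot(x, gB),
        b=engine.dot(y, gA),
        d=engine.dot(y, gB),
    )


def genotype_indicators(
    engine: Engine,
    fA: SharedScalar,
    fB: SharedScalar,
    hAA: SharedScalar,
    hBB: SharedScalar,
) -> tuple[SharedBit, SharedBit, SharedBit, SharedBit]:
    """Per-donor genotype-class indicator bits (iAA, iAB, iBB, iNN).

    iAA and iBB are the stored flag rows; iAB = fA*fB (one secure product);
    iNN = 1 - iAA - iAB - iBB.  Exactly one indicator is 1 for every valid
    allele-count pair; invalid encodings violate the contract and yield
    undefined bits.
    """
    iAB = engine.mul(fA, fB)
    mask = engine.ring.mask
    vals = tuple(
        (-(aa + ab + bb)) & mask
        for aa, ab, bb in zip(hAA.values, iAB.values, hBB.values)
    )
    iNN = engine.add_public(SharedScalar.from_values(vals, engine.ring), 1)
    return (
        SharedBit.from_scalar(hAA),
        SharedBit.from_scalar(iAB),
        SharedBit.from_scalar(hBB),
        SharedBit.from_scalar(iNN),
    )


def indicator_vectors(
    engine: Engine, fA: SharedVector, fB: SharedVector,
    hAA: SharedVector, hBB: SharedVector,
) -> tuple[SharedVector, SharedVector, SharedVector]:
    """Vectorised (iAA, iAB, iBB) rows for one SNP."""
    iAB = engine.mul_vec(fA, fB)
    return hAA, iAB, hBB


def genotype_table(
    engine: Engine,
    x: IndexVector,
    y: IndexVector,
    fA: SharedVector,
    fB: SharedVector,
    hAA: SharedVector,
    hBB: SharedVector,
) -> GenotypeTable2x3:
    if not len(x) == len(y) == len(fA) == len(fB) == len(hAA) == len(hBB):
        raise ProtocolError("index vectors and genotype rows must share one length")
    iAA, iAB, iBB = indicator_vectors(engine, fA, fB, hAA, hBB)
    r0 = engine.dot(x, iAA)
    r1 = engine.dot(x, iAB)
    r2 = engine.dot(x, iBB)
    s0 = engine.dot(y, iAA)
    s1 = engine.dot(y, iAB)
    s2 = engine.dot(y, iBB)
    m1 = engine.add(engine.add(r0, r1), r2)
    m2 = engine.add(engine.add(s0, s1), s2)
    return GenotypeTable2x3(
        r0=r0, r1=r1, r2=r2, m1=m1,
        s0=s0, s1=s1, s2=s2, m2=m2,
        n0=engine.add(r0, s0), n1=engine.add(r1, s1), n2=engine.add(r2, s2),
        N=engine.add(m1, m2),
    )


def heterozygous_parent_vector(
    engine: Engine,
    mother_fA: SharedVector,
    mother_fB: SharedVector,
    father_fA: SharedVector,
    father_fB: SharedVector,
) -> IndexVector:
    """Trio informativeness bits: 1 iff both parents are heterozygous."""
    if not len(mother_fA) == len(mother_fB) == len(father_fA) == len(father_fB):
        raise ProtocolError("trio-aligned parent rows must share one length")
    m_het = engine.mul_vec(mother_fA, mother_fB)
    f_het = engine.mul_vec(father_fA, father_fB)
    z = engine.mul_vec(m_het, f_het)
    return IndexVector(z.rows, z.ring)


def tdt_counts(
    engine: Engine,
    z: IndexVector,
    child_hAA: SharedVector,
    child_hBB: SharedVector,
) -> TdtCounts:
    if not len(z) == len(child_hAA) == len(child_hBB):
        raise ProtocolError("trio-aligned vectors must share one length")
    return TdtCounts(u=engine.dot(z, child_hAA), v=engine.dot(z, child_hBB))


def tdt_counts_for_snp(
    engine: Engine, db: SharedGenotypeDB, snp_index: int, trios: TrioStructure
) -> TdtCounts:
    """Convenience wrapper: gather trio columns for one SNP and count u, v."""
    trios.validate(db.n_donors)
    mothers, fathers, children = trios.mothers, trios.fathers, trios.children
    z = heterozygous_parent_vector(
        engine,
        db.fA[snp_index].take(mothers), db.fB[snp_index].take(mothers),
        db.fA[snp_index].take(fathers), db.fB[snp_index].take(fathers),
    )
    return tdt_counts(
        engine, z,
        db.hAA[snp_index].take(children), db.hBB[snp_index].take(children),
    )
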