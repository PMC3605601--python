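"""The four association statistics as exact integer fractions on shares.

Floating point is avoided entirely: each statistic T is carried as a shared
non-negative fraction m/n whose rational value equals T exactly, so the later
significance comparison ``T >= t(alpha)`` can be decided by one secure integer
comparison after cross-multiplication.

With the allele 2x2 table (a, c cases / b, d controls) and N' = a+b+c+d:

* Pearson chi-square of independence:
      m = N' * (a*d - b*c)^2
      n = (a+b) * (c+d) * (a+c) * (b+d)

* pooled two-proportion z^2 for allele A (algebraically the same value on a
  2x2 table, computed along its own route so the identity is verified by
  tests rather than assumed):
      m = N' * (a*(b+d) - b*(a+c))^2
      n = (a+c) * (b+d) * (a+b) * (c+d)

* Cochran-Armitage trend over the 2x3 genotype table with public weights w:
      m = N * (sum_j w_j * (m2*r_j - m1*s_j))^2
      n = m1 * m2 * (N * sum_j w_j^2 * n_j - (sum_j w_j * n_j)^2)

* TDT (McNemar form) from trio counts:
      m = (u - v)^2,    n = u + v

All four are approximately chi-square with one degree of freedom under their
nulls.  Signed intermediates (a*d - b*c, m2*r_j - m1*s_j, u - v) live in
two's complement on the ring and are squared before use, so m and n are
non-negative.  A denominator reconstructing to zero (monomorphic SNP, empty
group) marks the statistic undefined; the decision stage maps undefined to
"not significant" so genome-wide runs never abort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .contingency import AlleleTable2x2, GenotypeTable2x3, TdtCounts
from .errors import ConfigurationError
from .mpc import Engine, SharedScalar


@dataclass(frozen=True)
class TrendWeights:
    """Public per-genotype-class trend weights; (0,1,2) models additive
    (per-allele) dose response, which is the usual choice."""

    w0: int = 0
    w1: int = 1
    w2: int = 2

    def __post_init__(self) -> None:
        if self.w0 == self.w1 == self.w2:
            raise ConfigurationError("trend weights must not all be equal")

    @property
    def as_tuple(self) -> tuple[int, int, int]:
        return (self.w0, self.w1, self.w2)


@dataclass
class RationalStat:
    """A test statistic held as a shared non-negative fraction m/n."""

    m: SharedScalar
    n: SharedScalar
    test_id: str


# --------------------------------------------------------------------------
# plaintext integer-fraction forms (shared with the reference pipeline;
# the secure versions below mirror them operation for operation)

def chi2_fraction(a: int, b: int, c: int, d: int) -> tuple[int, int]:
    m = (a + b + c + d) * (a * d - b * c) ** 2
    n = (a + b) * (c + d) * (a + c) * (b + d)
    return m, n


def chi2_prop_fraction(a: int, b: int, c: int, d: int) -> tuple[int, int]:
    n1, n2 = a + c, b + d
    m = (a + b + c + d) * (a * n2 - b * n1) ** 2
    n = n1 * n2 * (a + b) * (c + d)
    return m, n


def catt_fraction(
    r: Sequence[int], s: Sequence[int], weights: TrendWeights = TrendWeights()
) -> tuple[int, int]:
    w = weights.as_tuple
    m1, m2 = sum(r), sum(s)
    n_j = [rj + sj for rj, sj in zip(r, s)]
    N = m1 + m2
    diff = sum(wj * (m2 * rj - m1 * sj) for wj, rj, sj in zip(w, r, s))
    m = N * diff * diff
    n = m1 * m2 * (N * sum(wj * wj * nj for wj, nj in zip(w, n_j))
                   - sum(wj * nj for wj, nj in zip(w, n_j)) ** 2)
    return m, n


def tdt_fraction(u: int, v: int) -> tuple[int, int]:
    return (u - v) ** 2, u + v


# --------------------------------------------------------------------------
# secure forms

def chi2_independence(engine: Engine, t: AlleleTable2x2) -> RationalStat:
    """Pearson chi-square on the shared allele table (7 secure products)."""
    total = engine.add(engine.add(t.a, t.b), engine.add(t.c, t.d))
    ad = engine.mul(t.a, t.d)
    bc = engine.mul(t.b, t.c)
    diff = engine.sub(ad, bc)
    m = engine.mul(total, engine.mul(diff, diff))
    n = engine.mul(
        engine.mul(engine.add(t.a, t.b), engine.add(t.c, t.d)),
        engine.mul(engine.add(t.a, t.c), engine.add(t.b, t.d)),
    )
    return RationalStat(m=m, n=n, test_id="chi2")


def chi2_proportion(engine: Engine, t: AlleleTable2x2) -> RationalStat:
    """Pooled two-proportion z^2 for allele A, computed along its own
    algebraic route (a*n2 - b*n1 rather than a*d - b*c)."""
    n1 = engine.add(t.a, t.c)
    n2 = engine.add(t.b, t.d)
    total = engine.add(n1, n2)
    an2 = engine.mul(t.a, n2)
    bn1 = engine.mul(t.b, n1)
    diff = engine.sub(an2, bn1)
    m = engine.mul(total, engine.mul(diff, diff))
    n = engine.mul(
        engine.mul(n1, n2),
        engine.mul(engine.add(t.a, t.b), engine.add(t.c, t.d)),
    )
    return RationalStat(m=m, n=n, test_id="chi2prop")


def cochran_armitage(
    engine: Engine, t: GenotypeTable2x3, weights: TrendWeights = TrendWeights()
) -> RationalStat:
    w = weights.as_tuple
    r = (t.r0, t.r1, t.r2)
    s = (t.s0, t.s1, t.s2)
    n_j = (t.n0, t.n1, t.n2)
    # sum_j w_j (m2 r_j - m1 s_j): 6 products, then public-weighted sum
    diff = None
    for wj, rj, sj in zip(w, r, s):
        term = engine.sub(engine.mul(t.m2, rj), engine.mul(t.m1, sj))
        term = engine.mul_public(term, wj)
        diff = term if diff is None else engine.add(diff, term)
    m = engine.mul(t.N, engine.mul(diff, diff))
    # n = m1 m2 (N sum w^2 n_j - (sum w n_j)^2): weighted sums are local
    wsum = None
    w2sum = None
    for wj, nj in zip(w, n_j):
        a = engine.mul_public(nj, wj)
        b = engine.mul_public(nj, wj * wj)
        wsum = a if wsum is None else engine.add(wsum, a)
        w2sum = b if w2sum is None else engine.add(w2sum, b)
    bracket = engine.sub(engine.mul(t.N, w2sum), engine.mul(wsum, wsum))
    n = engine.mul(engine.mul(t.m1, t.m2), bracket)
    return RationalStat(m=m, n=n, test_id="catt")


def tdt(engine: Engine, c: TdtCounts) -> RationalStat:
    diff = engine.sub(c.u, c.v)
    return RationalStat(
        m=engine.mul(diff, diff), n=engine.add(c.u, c.v), test_id="tdt"
    )
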