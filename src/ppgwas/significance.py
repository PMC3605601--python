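"""Integer-only significance decisions; nothing but decision bits is released.

A SNP is called significant when its statistic T = m/n reaches the
chi-square(1) critical value t(alpha).  With t(alpha) approximated from
below by a public fraction p/q, the test

    m/n >= p/q      <=>      m*q >= p*n

needs only one secure multiplication-free scaling (q and p are public) and
one secure comparison per SNP.  Rounding p = floor(t*q) errs toward calling
significance by at most 1/q, and decisions can disagree with the
floating-point rule only for statistics inside [p/q, t(alpha)) — a band of
width < 1/q.  Ties at the threshold count as significant (the >= convention).

Multiple testing: Bonferroni simply rebuilds the threshold at level
alpha/#tests.  The false-discovery-rate procedure (Benjamini-Hochberg) is
performed obliviously: the shared fractions are sorted with a Batcher
odd-even merge network — whose comparator sequence depends only on the list
length — each rank is compared against its public per-rank threshold, the
rejection region is closed downward with a shared suffix-OR, and the
rank-space decisions are mapped back to SNP order by replaying the network's
conditional swaps in reverse.  Only the per-SNP bits and the rejection count
are opened.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import chi2 as _chi2

from .assoc import RationalStat
from .errors import ConfigurationError
from .mpc import Engine, SharedScalar

DEFAULT_Q = 10**6


@dataclass(frozen=True)
class RationalThreshold:
    """Public integer fraction p/q with p/q <= t(alpha) < (p+1)/q, where
    t(alpha) is the chi-square(1) upper-alpha critical value."""

    p: int
    q: int
    alpha: float

    def __post_init__(self) -> None:
        if self.q < 1 or self.p < 0:
            raise ConfigurationError("threshold fraction must be non-negative with q >= 1")


def chi2_critical_rational(alpha: float, q_precision: int = DEFAULT_Q) -> RationalThreshold:
    """Build the public rational threshold for the chi-square(1) critical value.

    ``q_precision`` trades disclosure granularity for fidelity: the band of
    possible disagreement with the exact real-valued rule has width 1/q.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"significance level must be in (0,1), got {alpha}")
    if q_precision < 10**3:
        raise ConfigurationError("q_precision below 10^3 gives a uselessly coarse threshold")
    t = float(_chi2.isf(alpha, df=1))
    return RationalThreshold(p=math.floor(t * q_precision), q=q_precision, alpha=alpha)


def bonferroni(alpha: float, n_tests: int, q_precision: int = DEFAULT_Q) -> RationalThreshold:
    """Family-wise threshold at per-test level alpha/n_tests."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    return chi2_critical_rational(alpha / n_tests, q_precision)


def ring_width_check(k: int, n_donors: int, q_precision: int = DEFAULT_Q) -> tuple[bool, int]:
    """Overflow-safety check for the significance comparison.

    ``16 * (2N)^5 * q`` bounds the cross-multiplied sides m*q and p*n over
    all four tests at N donors; the comparison contract requires both sides
    below 2^(k-2).  Returns (ok, minimal safe k).
    """
    bound = 16 * (2 * n_donors) ** 5 * q_precision
    min_k = bound.bit_length() + 2  # smallest k with 2^(k-2) > bound
    return (1 << (k - 2)) > bound, min_k


def bh_ring_width_check(k: int, n_donors: int, q_precision: int = DEFAULT_Q) -> tuple[bool, int]:
    """Overflow bound for the BH sorting comparators, which cross-multiply two
    statistics: m_i * n_j <= 16*(2N)^5 * (2N)^4."""
    bound = max(16 * (2 * n_donors) ** 9, 16 * (2 * n_donors) ** 5 * q_precision)
    min_k = bound.bit_length() + 2
    return (1 << (k - 2)) > bound, min_k


@dataclass
class DecisionVector:
    """The only public output of a run: per-SNP significance bits plus the
    per-SNP undefined-statistic flags (monomorphic SNP / empty group)."""

    snp_ids: list[str]
    decisions: list[int]
    undefined: list[int]
    test_id: str
    alpha: float
    correction: str
    q_precision: int
    rejection_count: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not len(self.snp_ids) == len(self.decisions) == len(self.undefined):
            raise ConfigurationError("decision vector fields must share one length")


# --------------------------------------------------------------------------
# single-threshold decisions

def _definedness(engine: Engine, stat: RationalStat) -> SharedScalar:
    one = engine.share(1)
    return engine.geq(stat.n, one)


def decide(
    engine: Engine, stat: RationalStat, th: RationalThreshold, label: str = "snp"
) -> tuple[int, int]:
    """Open the per-SNP decision bit (and undefined flag) for one statistic.

    An undefined statistic (denominator 0) always decides non-significant;
    its flag is released so downstream reporting can count such SNPs.
    """
    defined = _definedness(engine, stat)
    lhs = engine.mul_public(stat.m, th.q)
    rhs = engine.mul_public(stat.n, th.p)
    cmp_bit = engine.geq(lhs, rhs)
    sig = engine.mul(defined, cmp_bit)
    decision = engine.open(sig, label=label, kind="decision")
    undefined = 1 - engine.open(defined, label=label, kind="undefined_flag")
    return decision, undefined


def decide_all(
    engine: Engine,
    stats: Sequence[RationalStat],
    th: RationalThreshold,
    snp_ids: Sequence[str],
    correction: str = "none",
) -> DecisionVector:
    decisions, undefined = [], []
    for sid, stat in zip(snp_ids, stats):
        d, u = decide(engine, stat, th, label=sid)
        decisions.append(d)
        undefined.append(u)
    return DecisionVector(
        snp_ids=list(snp_ids),
        decisions=decisions,
        undefined=undefined,
        test_id=stats[0].test_id if stats else "",
        alpha=th.alpha,
        correction=correction,
        q_precision=th.q,
        rejection_count=sum(decisions),
    )


# --------------------------------------------------------------------------
# oblivious Benjamini-Hochberg

def batcher_network(n: int) -> list[tuple[int, int]]:
    """Comparator list (i, j), i < j, of Batcher's odd-even merge sort for a
    power-of-two ``n``.  The sequence is data independent: the obliviousness
    of the BH procedure rests on it."""
    if n & (n - 1):
        raise ConfigurationError("batcher_network requires a power-of-two length")
    net: list[tuple[int, int]] = []
    p = 1
    while p < n:
        step = p
        while step >= 1:
            for j in range(step % p, n - step, 2 * step):
                for i in range(min(step, n - j - step)):
                    if (i + j) // (2 * p) == (i + j + step) // (2 * p):
                        net.append((i + j, i + j + step))
            step //= 2
        p *= 2
    return net


def bh_rank_thresholds(alpha: float, n_stats: int, q_precision: int) -> list[RationalThreshold]:
    """Per-rank public thresholds t(alpha*i/m) for i = 1..m (descending-rank
    statistic space; the rank condition p_(i) <= alpha*i/m maps through the
    monotone chi-square quantile)."""
    return [
        chi2_critical_rational(alpha * i / n_stats, q_precision)
        for i in range(1, n_stats + 1)
    ]


def _cond_swap(engine: Engine, s: SharedScalar, x: SharedScalar, y: SharedScalar):
    """(x, y) if s == 1 else (y, x); one secure product."""
    w = engine.mul(s, engine.sub(x, y))
    return engine.add(y, w), engine.sub(x, w)


def secure_bh(
    engine: Engine,
    stats: Sequence[RationalStat],
    alpha: float,
    snp_ids: Sequence[str],
    q_precision: int = DEFAULT_Q,
) -> DecisionVector:
    """Privacy-preserving Benjamini-Hochberg over shared statistic fractions.

    Opens nothing but the final rejection count and the per-SNP decision
    bits; sorting, rank thresholding and the rank-to-identity mapping all
    run on shares with a data-independent operation schedule.
    """
    m_real = len(stats)
    if m_real == 0:
        raise ConfigurationError("secure_bh needs at least one statistic")
    # normalise: undefined (n == 0) becomes the neutral fraction 0/1
    ms: list[SharedScalar] = []
    ns: list[SharedScalar] = []
    undefined: list[int] = []
    for sid, st in zip(snp_ids, stats):
        delta = _definedness(engine, st)
        ms.append(engine.mul(delta, st.m))
        nn = engine.mul(delta, st.n)
        nn = engine.add_public(engine.sub(nn, delta), 1)  # delta*n + 1 - delta
        ns.append(nn)
        undefined.append(1 - engine.open(delta, label=sid, kind="undefined_flag"))
    # pad to a power of two with the same neutral fraction (public zeros)
    n_pad = 1 << max(1, (m_real - 1).bit_length())
    zero = SharedScalar.from_values((0, 0, 0), engine.ring)
    one = SharedScalar.from_values((1, 0, 0), engine.ring)
    ms += [zero] * (n_pad - m_real)
    ns += [one] * (n_pad - m_real)

    # oblivious descending sort, recording the comparator outcomes
    gates = batcher_network(n_pad)
    outcomes: list[SharedScalar] = []
    for i, j in gates:
        lhs = engine.mul(ms[i], ns[j])
        rhs = engine.mul(ms[j], ns[i])
        s = engine.geq(lhs, rhs)  # 1: already descending at (i, j)
        outcomes.append(s)
        ms[i], ms[j] = _cond_swap(engine, s, ms[i], ms[j])
        ns[i], ns[j] = _cond_swap(engine, s, ns[i], ns[j])

    # per-rank exceedance bits for the real ranks; padding ranks are never
    # exceedances (their fraction is 0/1 and every p >= 1)
    thresholds = bh_rank_thresholds(alpha, m_real, q_precision)
    exceed: list[SharedScalar] = []
    for rank in range(n_pad):
        if rank < m_real:
            th = thresholds[rank]
            lhs = engine.mul_public(ms[rank], th.q)
            rhs = engine.mul_public(ns[rank], th.p)
            exceed.append(engine.geq(lhs, rhs))
        else:
            exceed.append(zero)

    # close the rejection region downward: o_i = OR_{j >= i} e_j
    rejected = [zero] * n_pad
    acc = exceed[-1]
    rejected[-1] = acc
    for i in range(n_pad - 2, -1, -1):
        prod = engine.mul(exceed[i], acc)
        acc = engine.sub(engine.add(exceed[i], acc), prod)
        rejected[i] = acc

    count = engine.open(
        _sum_shares(engine, rejected), label="bh", kind="rejection_count"
    )

    # map rank-space decisions back to original SNP order: conditional swaps
    # are involutions, so replaying the network in reverse inverts the sort
    for (i, j), s in zip(reversed(gates), reversed(outcomes)):
        rejected[i], rejected[j] = _cond_swap(engine, s, rejected[i], rejected[j])

    decisions = [
        engine.open(rejected[i], label=snp_ids[i], kind="decision")
        for i in range(m_real)
    ]
    return DecisionVector(
        snp_ids=list(snp_ids),
        decisions=decisions,
        undefined=undefined,
        test_id=stats[0].test_id,
        alpha=alpha,
        correction="bh",
        q_precision=q_precision,
        rejection_count=count,
    )


def _sum_shares(engine: Engine, xs: Sequence[SharedScalar]) -> SharedScalar:
    mask = engine.ring.mask
    vals = [0, 0, 0]
    for x in xs:
        v = x.values
        vals[0] += v[0]
        vals[1] += v[1]
        vals[2] += v[2]
    return SharedScalar.from_values(tuple(v & mask for v in vals), engine.ring)


# --------------------------------------------------------------------------
# public outputs

def write_decisions_tsv(dv: DecisionVector, path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\ttest\tdecision\tundefined_flag\n")
        for sid, d, u in zip(dv.snp_ids, dv.decisions, dv.undefined):
            fh.write(f"{sid}\t{dv.test_id}\t{d}\t{u}\n")


def write_run_metadata(dv: DecisionVector, path, extra: dict | None = None) -> None:
    payload = {
        "test": dv.test_id,
        "alpha": dv.alpha,
        "correction": dv.correction,
        "q_precision": dv.q_precision,
        "n_snps": len(dv.snp_ids),
        "n_significant": sum(dv.decisions),
        "n_undefined": sum(dv.undefined),
        "rejection_count": dv.rejection_count,
    }
    payload.update(dv.meta)
    payload.update(extra or {})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
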