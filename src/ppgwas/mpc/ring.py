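"""Algebraic containers for 3-out-of-3 additive secret sharing over Z_{2^k}.

A secret ``x`` is held as three ring elements ``s0, s1, s2`` with
``(s0 + s1 + s2) mod 2^k == x``, one summand per host.  Any single share, and
any pair of shares, is marginally uniform on the ring when the sharing
randomness is uniform, so individual hosts (and any two colluding hosts under
this 3-out-of-3 scheme with an honest dealer) see only noise.

Signed quantities are represented in two's complement on the ring: the
intermediate differences that arise inside the test statistics (e.g.
``a*d - b*c``) may wrap, but they are always squared before any comparison,
and ``(-x)^2 == x^2 (mod 2^k)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from ..errors import RangeError, RingError

N_HOSTS = 3


@dataclass(frozen=True)
class RingConfig:
    """The ring Z_{2^k}. ``k`` defaults to 128 bits, wide enough for the
    cross-multiplied significance comparisons at biobank-scale cohorts
    (see :func:`ppgwas.significance.ring_width_check`)."""

    k: int = 128

    def __post_init__(self) -> None:
        if self.k < 8:
            raise RingError(f"ring bit-width must be >= 8, got k={self.k}")

    @property
    def modulus(self) -> int:
        return 1 << self.k

    @property
    def mask(self) -> int:
        return (1 << self.k) - 1

    def reduce(self, x: int) -> int:
        return x & self.mask

    def to_signed(self, x: int) -> int:
        """Interpret a ring element in two's complement."""
        half = 1 << (self.k - 1)
        return x - self.modulus if x >= half else x

    def from_signed(self, x: int) -> int:
        m = self.modulus
        if not -(m >> 1) <= x < m:
            raise RangeError(f"value {x} not representable on a {self.k}-bit ring")
        return x & self.mask


@dataclass(frozen=True)
class Share:
    """One host's additive summand of a secret."""

    host_id: int
    value: int


@dataclass(frozen=True)
class SharedScalar:
    """A secret split into exactly three shares over a common ring."""

    shares: tuple[Share, Share, Share]
    ring: RingConfig

    def __post_init__(self) -> None:
        if len(self.shares) != N_HOSTS:
            raise RingError(f"expected {N_HOSTS} shares, got {len(self.shares)}")
        for expect, sh in enumerate(self.shares):
            if sh.host_id != expect:
                raise RingError(
                    f"shares must be ordered by host id 0,1,2; "
                    f"slot {expect} holds host {sh.host_id}"
                )
            if not 0 <= sh.value < self.ring.modulus:
                raise RingError(f"share value {sh.value} outside ring Z_2^{self.ring.k}")

    @classmethod
    def from_values(cls, values: Sequence[int], ring: RingConfig) -> "SharedScalar":
        if len(values) != N_HOSTS:
            raise RingError(f"expected {N_HOSTS} share values, got {len(values)}")
        return cls(tuple(Share(i, v & ring.mask) for i, v in enumerate(values)), ring)

    @property
    def values(self) -> tuple[int, int, int]:
        return tuple(sh.value for sh in self.shares)  # type: ignore[return-value]


class SharedBit(SharedScalar):
    """A :class:`SharedScalar` whose secret is guaranteed to be 0 or 1.

    The guarantee is the producing protocol's contract; it is checked by
    reconstruction only in tests, never during a secure run.
    """

    @classmethod
    def from_scalar(cls, s: SharedScalar) -> "SharedBit":
        return cls(s.shares, s.ring)


class SharedVector:
    """A sequence of secrets over one ring, stored as three parallel share
    rows (one row per host) for speed.  ``v[i]`` materialises an individual
    :class:`SharedScalar` on demand."""

    __slots__ = ("ring", "rows")

    def __init__(self, rows: tuple[list[int], list[int], list[int]], ring: RingConfig):
        if len(rows) != N_HOSTS:
            raise RingError(f"expected {N_HOSTS} share rows, got {len(rows)}")
        n = len(rows[0])
        if any(len(r) != n for r in rows):
            raise RingError("share rows have unequal lengths")
        self.rows = rows
        self.ring = ring

    def __len__(self) -> int:
        return len(self.rows[0])

    def __getitem__(self, i: int) -> SharedScalar:
        return SharedScalar.from_values((self.rows[0][i], self.rows[1][i], self.rows[2][i]), self.ring)

    def __iter__(self) -> Iterator[SharedScalar]:
        for i in range(len(self)):
            yield self[i]

    @property
    def elements(self) -> list[SharedScalar]:
        return list(iter(self))

    @classmethod
    def from_scalars(cls, scalars: Iterable[SharedScalar]) -> "SharedVector":
        scalars = list(scalars)
        if not scalars:
            raise RingError("cannot build a shared vector from zero scalars")
        ring = scalars[0].ring
        if any(s.ring != ring for s in scalars):
            raise RingError("all elements of a shared vector must share one ring")
        rows = tuple([s.values[h] for s in scalars] for h in range(N_HOSTS))
        return cls(rows, ring)  # type: ignore[arg-type]

    def take(self, indices: Sequence[int]) -> "SharedVector":
        """Gather a sub-vector by public column indices (a local operation)."""
        rows = tuple([row[i] for i in indices] for row in self.rows)
        return SharedVector(rows, self.ring)  # type: ignore[arg-type]


def check_same_ring(*items: SharedScalar | SharedVector) -> RingConfig:
    ring = items[0].ring
    for it in items[1:]:
        if it.ring != ring:
            raise RingError(f"ring mismatch: {it.ring} vs {ring}")
    return ring
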