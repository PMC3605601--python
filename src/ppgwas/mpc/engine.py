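"""Simulated three-host secure computation engine.

The three hosts are modelled as in-process actors.  Every protocol step that
would cross the network in a deployed system is recorded on a
:class:`MessageBus`; local (communication-free) operations never touch the
bus.  The bus log is the test surface for the obliviousness proxy: the number
and sizes of messages depend only on the shapes of the inputs, never on the
secret data.

Security model
--------------
Honest-but-curious hosts with a trusted offline dealer:

* multiplication uses Beaver triples ``(a, b, c = a*b)`` issued by the dealer;
  the protocol opens only the masked differences ``x - a`` and ``y - b``,
  which are uniform on the ring and therefore leak nothing;
* comparison masks the (offset) difference with a dealer-supplied random
  ring element whose bit decomposition the hosts hold in shared form, opens
  the uniform masked value, and recovers the deciding bit of the difference
  through a shared borrow chain.

This is a functional simulation for analysis correctness and communication
accounting — not a hardened cryptographic deployment (no networking, no
malicious security, no timing-channel defences).
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from typing import Sequence

from ..errors import ConfigurationError, ProtocolError, RangeError
from .ring import (
    N_HOSTS,
    RingConfig,
    SharedBit,
    SharedScalar,
    SharedVector,
    check_same_ring,
)

__all__ = [
    "MessageBus",
    "TripleProvider",
    "Engine",
    "AuditRecord",
    "share_secret",
    "reconstruct",
    "add_shared",
    "sub_shared",
    "add_public",
    "mul_public",
    "mul_shared",
    "secure_geq",
]


def derive_seed(root_seed: int, stream: str) -> int:
    """Split one root seed into named independent streams (sharing, triples,
    masks).  SHA-256 based so streams are uncorrelated; result fits in 63 bits."""
    h = hashlib.sha256(f"{root_seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:8], "little") >> 1


class MessageBus:
    """Counts inter-host messages and payload sizes per protocol round.

    One *round* is a simultaneous broadcast: each of the three hosts sends one
    message to each of the other two (6 messages), carrying ``payload``
    ring elements each.
    """

    __slots__ = ("messages", "payload_elements", "rounds", "per_tag")

    def __init__(self) -> None:
        self.messages = 0
        self.payload_elements = 0
        self.rounds = 0
        self.per_tag: dict[str, int] = {}

    def record_round(self, tag: str, payload: int) -> None:
        self.rounds += 1
        self.messages += 2 * N_HOSTS
        self.payload_elements += 2 * N_HOSTS * payload
        self.per_tag[tag] = self.per_tag.get(tag, 0) + 1

    def snapshot(self) -> dict:
        return {
            "messages": self.messages,
            "payload_elements": self.payload_elements,
            "rounds": self.rounds,
            "per_tag": dict(self.per_tag),
        }


class TripleProvider:
    """Trusted-dealer source of Beaver triples and shared random bits.

    Each issued triple satisfies ``c == a*b (mod 2^k)`` and is consumed by
    exactly one multiplication; the dealer stream never replays.  A finite
    ``capacity`` models a preprocessing budget — exceeding it is a
    configuration error, mirroring a deployment that ran out of
    precomputed material.
    """

    def __init__(self, ring: RingConfig, seed: int, capacity: int | None = None):
        self.ring = ring
        self.capacity = capacity
        self.issued = 0
        self.bits_issued = 0
        self._rng = random.Random(seed)

    def _charge(self, n: int) -> None:
        self.issued += n
        if self.capacity is not None and self.issued > self.capacity:
            raise ConfigurationError(
                f"Beaver triple budget exhausted ({self.issued} > {self.capacity})"
            )

    def raw_triple(self) -> tuple[int, ...]:
        """Nine ring elements: shares of a, b and c = a*b."""
        self._charge(1)
        g = self._rng.getrandbits
        k, mask = self.ring.k, self.ring.mask
        a = g(k)
        b = g(k)
        c = (a * b) & mask
        a0, a1 = g(k), g(k)
        b0, b1 = g(k), g(k)
        c0, c1 = g(k), g(k)
        return (
            a0, a1, (a - a0 - a1) & mask,
            b0, b1, (b - b0 - b1) & mask,
            c0, c1, (c - c0 - c1) & mask,
        )

    def triple(self) -> tuple[SharedScalar, SharedScalar, SharedScalar]:
        t = self.raw_triple()
        r = self.ring
        return (
            SharedScalar.from_values(t[0:3], r),
            SharedScalar.from_values(t[3:6], r),
            SharedScalar.from_values(t[6:9], r),
        )

    def raw_bit_shares(self, n: int) -> list[tuple[int, int, int]]:
        """``n`` uniformly random bits, each additively shared on the ring."""
        self.bits_issued += n
        g = self._rng.getrandbits
        k, mask = self.ring.k, self.ring.mask
        out = []
        for _ in range(n):
            beta = g(1)
            s0, s1 = g(k), g(k)
            out.append((s0, s1, (beta - s0 - s1) & mask))
        return out


@dataclass(frozen=True)
class AuditRecord:
    """One controlled disclosure: what was opened, why, and the public value."""

    kind: str
    label: str
    value: int


@dataclass
class Engine:
    """Owns the ring, the randomness streams, the dealer and the message bus
    for one secure run, and exposes the secure operations.

    One root seed is split into independent streams for input sharing,
    triple generation and comparison masks, so reruns are bit-reproducible.
    """

    ring: RingConfig = field(default_factory=RingConfig)
    seed: int = 0
    triple_capacity: int | None = None

    def __post_init__(self) -> None:
        self.bus = MessageBus()
        self.audit: list[AuditRecord] = []
        self.triples = TripleProvider(
            self.ring, derive_seed(self.seed, "triples"), self.triple_capacity
        )
        self._rng_share = random.Random(derive_seed(self.seed, "sharing"))

    # ------------------------------------------------------------------ input
    def share(self, x: int) -> SharedScalar:
        """Secret-share a ring element; shares 0 and 1 are uniform draws."""
        if not 0 <= x < self.ring.modulus:
            raise RangeError(f"secret {x} outside ring Z_2^{self.ring.k}")
        k, mask = self.ring.k, self.ring.mask
        s0 = self._rng_share.getrandbits(k)
        s1 = self._rng_share.getrandbits(k)
        return SharedScalar.from_values((s0, s1, (x - s0 - s1) & mask), self.ring)

    def share_bit(self, b: int) -> SharedBit:
        if b not in (0, 1):
            raise RangeError(f"bit secret must be 0 or 1, got {b}")
        return SharedBit.from_scalar(self.share(b))

    def share_vector(self, values: Sequence[int]) -> SharedVector:
        k, mask = self.ring.k, self.ring.mask
        g = self._rng_share.getrandbits
        r0, r1, r2 = [], [], []
        for x in values:
            if not 0 <= x < self.ring.modulus:
                raise RangeError(f"secret {x} outside ring Z_2^{self.ring.k}")
            s0 = g(k)
            s1 = g(k)
            r0.append(s0)
            r1.append(s1)
            r2.append((x - s0 - s1) & mask)
        return SharedVector((r0, r1, r2), self.ring)

    # ----------------------------------------------------------------- output
    def reconstruct(self, v: SharedScalar) -> int:
        """Pool all three shares.  Used by tests and by explicitly authorised
        openings; raises if the shares do not form a complete triple."""
        if v.ring != self.ring:
            raise ProtocolError("cannot reconstruct a scalar from a different ring")
        s = v.values
        return (s[0] + s[1] + s[2]) & self.ring.mask

    def reconstruct_vector(self, v: SharedVector) -> list[int]:
        if v.ring != self.ring:
            raise ProtocolError("cannot reconstruct a vector from a different ring")
        mask = self.ring.mask
        r0, r1, r2 = v.rows
        return [(a + b + c) & mask for a, b, c in zip(r0, r1, r2)]

    def open(self, v: SharedScalar, label: str, kind: str = "value") -> int:
        """Controlled disclosure: all hosts broadcast their share and the
        public value is logged on the audit trail."""
        value = self.reconstruct(v)
        self.bus.record_round("open", 1)
        self.audit.append(AuditRecord(kind=kind, label=label, value=value))
        return value

    # ------------------------------------------------------- local arithmetic
    def add(self, a: SharedScalar, b: SharedScalar) -> SharedScalar:
        check_same_ring(a, b)
        mask = a.ring.mask
        return SharedScalar.from_values(
            tuple((x + y) & mask for x, y in zip(a.values, b.values)), a.ring
        )

    def sub(self, a: SharedScalar, b: SharedScalar) -> SharedScalar:
        check_same_ring(a, b)
        mask = a.ring.mask
        return SharedScalar.from_values(
            tuple((x - y) & mask for x, y in zip(a.values, b.values)), a.ring
        )

    def add_public(self, a: SharedScalar, c: int) -> SharedScalar:
        """Add a public constant: host 0 adjusts its share, others do nothing."""
        mask = a.ring.mask
        v = a.values
        return SharedScalar.from_values(((v[0] + c) & mask, v[1], v[2]), a.ring)

    def mul_public(self, a: SharedScalar, c: int) -> SharedScalar:
        mask = a.ring.mask
        return SharedScalar.from_values(tuple((c * x) & mask for x in a.values), a.ring)

    def neg(self, a: SharedScalar) -> SharedScalar:
        return self.mul_public(a, -1)

    def add_vec(self, x: SharedVector, y: SharedVector) -> SharedVector:
        check_same_ring(x, y)
        self._check_len(x, y)
        mask = x.ring.mask
        rows = tuple(
            [(a + b) & mask for a, b in zip(rx, ry)] for rx, ry in zip(x.rows, y.rows)
        )
        return SharedVector(rows, x.ring)  # type: ignore[arg-type]

    # ------------------------------------------------------- secure protocols
    @staticmethod
    def _check_len(x: SharedVector, y: SharedVector) -> None:
        if len(x) != len(y):
            raise ProtocolError(f"vector length mismatch: {len(x)} vs {len(y)}")

    def _mul_raw(self, ax: tuple[int, int, int], bx: tuple[int, int, int],
                 *, record: bool = True) -> tuple[int, int, int]:
        """Beaver multiplication on raw share triples."""
        mask = self.ring.mask
        (a0, a1, a2, b0, b1, b2, c0, c1, c2) = self.triples.raw_triple()
        d = (ax[0] + ax[1] + ax[2] - a0 - a1 - a2) & mask  # opened: x - a, uniform
        e = (bx[0] + bx[1] + bx[2] - b0 - b1 - b2) & mask  # opened: y - b, uniform
        if record:
            self.bus.record_round("beaver_open", 2)
        return (
            (c0 + d * b0 + e * a0 + d * e) & mask,
            (c1 + d * b1 + e * a1) & mask,
            (c2 + d * b2 + e * a2) & mask,
        )

    def mul(self, a: SharedScalar, b: SharedScalar) -> SharedScalar:
        check_same_ring(a, b)
        if a.ring != self.ring:
            raise ProtocolError("operands belong to a different ring than the engine")
        return SharedScalar.from_values(self._mul_raw(a.values, b.values), self.ring)

    def mul_vec(self, x: SharedVector, y: SharedVector) -> SharedVector:
        """Element-wise secure multiplication; masked differences for the whole
        vector are opened in a single communication round."""
        check_same_ring(x, y)
        self._check_len(x, y)
        mask = self.ring.mask
        n = len(x)
        x0, x1, x2 = x.rows
        y0, y1, y2 = y.rows
        o0: list[int] = []
        o1: list[int] = []
        o2: list[int] = []
        raw_triple = self.triples.raw_triple
        for i in range(n):
            a0, a1, a2, b0, b1, b2, c0, c1, c2 = raw_triple()
            d = (x0[i] + x1[i] + x2[i] - a0 - a1 - a2) & mask
            e = (y0[i] + y1[i] + y2[i] - b0 - b1 - b2) & mask
            o0.append((c0 + d * b0 + e * a0 + d * e) & mask)
            o1.append((c1 + d * b1 + e * a1) & mask)
            o2.append((c2 + d * b2 + e * a2) & mask)
        self.bus.record_round("beaver_open_vec", 2 * n)
        return SharedVector((o0, o1, o2), self.ring)

    def dot(self, x: SharedVector, y: SharedVector) -> SharedScalar:
        """Secure inner product: one batched multiplication round followed by
        local summation of the product shares."""
        z = self.mul_vec(x, y)
        mask = self.ring.mask
        return SharedScalar.from_values(
            tuple(sum(row) & mask for row in z.rows), self.ring
        )

    def _geq_raw(self, av: tuple[int, int, int], bv: tuple[int, int, int]) -> tuple[int, int, int]:
        """Raw shares of the bit [a >= b] for secrets in [0, 2^(k-2)).

        Offsets the difference so its sign sits in bit k-2, masks with a
        dealer random ``r`` (held bit-wise in shared form), opens the uniform
        masked value ``c``, and extracts bit k-2 of ``c - r`` with a shared
        borrow chain driven by the public bits of ``c``.
        """
        k, mask = self.ring.k, self.ring.mask
        offset = 1 << (k - 2)
        # d = a - b + 2^(k-2); in-contract the true value lies in (0, 2^(k-1))
        d = ((av[0] - bv[0] + offset) & mask, (av[1] - bv[1]) & mask, (av[2] - bv[2]) & mask)
        bits = self.triples.raw_bit_shares(k)
        # hosts derive their share of r locally from the shared bits
        r0 = sum(bits[i][0] << i for i in range(k)) & mask
        r1 = sum(bits[i][1] << i for i in range(k)) & mask
        r2 = sum(bits[i][2] << i for i in range(k)) & mask
        c = (d[0] + d[1] + d[2] + r0 + r1 + r2) & mask  # opened, uniform
        self.bus.record_round("compare_open", 1)
        # borrow chain for D = c - r over bits 0 .. k-3
        bw = (0, 0, 0)
        for i in range(k - 2):
            ri = bits[i]
            prod = self._mul_raw(ri, bw, record=False)
            if (c >> i) & 1:
                bw = prod  # borrow out = r_i AND borrow_in
            else:  # borrow out = r_i OR borrow_in
                bw = (
                    (ri[0] + bw[0] - prod[0]) & mask,
                    (ri[1] + bw[1] - prod[1]) & mask,
                    (ri[2] + bw[2] - prod[2]) & mask,
                )
        self.bus.record_round("compare_chain", k - 2)
        # bit k-2 of D is c_{k-2} XOR r_{k-2} XOR borrow
        rtop = bits[k - 2]
        prod = self._mul_raw(rtop, bw, record=False)
        t = (
            (rtop[0] + bw[0] - 2 * prod[0]) & mask,
            (rtop[1] + bw[1] - 2 * prod[1]) & mask,
            (rtop[2] + bw[2] - 2 * prod[2]) & mask,
        )
        if (c >> (k - 2)) & 1:
            return ((1 - t[0]) & mask, (-t[1]) & mask, (-t[2]) & mask)
        return t

    def geq(self, a: SharedScalar, b: SharedScalar) -> SharedBit:
        """Secure [a >= b] for non-negative secrets below 2^(k-2).

        The bound is the caller's obligation; out-of-contract operands yield an
        undefined bit (nothing is detectable obliviously).
        """
        check_same_ring(a, b)
        if a.ring != self.ring:
            raise ProtocolError("operands belong to a different ring than the engine")
        return SharedBit.from_scalar(
            SharedScalar.from_values(self._geq_raw(a.values, b.values), self.ring)
        )


# ---------------------------------------------------------------------------
# Functional aliases matching the protocol vocabulary.  ``Engine`` is the
# stateful API; these free functions serve call sites that hold an engine.

def share_secret(x: int, engine: Engine) -> SharedScalar:
    return engine.share(x)


def reconstruct(v: SharedScalar, engine: Engine) -> int:
    return engine.reconstruct(v)


def add_shared(a: SharedScalar, b: SharedScalar, engine: Engine) -> SharedScalar:
    return engine.add(a, b)


def sub_shared(a: SharedScalar, b: SharedScalar, engine: Engine) -> SharedScalar:
    return engine.sub(a, b)


def add_public(a: SharedScalar, c: int, engine: Engine) -> SharedScalar:
    return engine.add_public(a, c)


def mul_public(a: SharedScalar, c: int, engine: Engine) -> SharedScalar:
    return engine.mul_public(a, c)


def mul_shared(a: SharedScalar, b: SharedScalar, engine: Engine) -> SharedScalar:
    return engine.mul(a, b)


def secure_geq(a: SharedScalar, b: SharedScalar, engine: Engine) -> SharedBit:
    return engine.geq(a, b)
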