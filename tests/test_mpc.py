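"""Protocol-level checks for the simulated three-host engine: exhaustive
oracle equivalence with plaintext modular arithmetic on small rings,
share-uniformity privacy proxies, and communication discipline."""

import random

import pytest
from scipy.stats import chisquare

from ppgwas.errors import ConfigurationError, ProtocolError, RangeError, RingError
from ppgwas.mpc import (
    Engine,
    RingConfig,
    SharedScalar,
    SharedVector,
    add_shared,
    mul_public,
    mul_shared,
    reconstruct,
    secure_geq,
    share_secret,
)


class TestSharingRoundTrip:
    def test_zero_shares_sum_to_zero(self, engine):
        assert engine.reconstruct(engine.share(0)) == 0

    def test_defining_property_k32(self):
        eng = Engine(RingConfig(32), seed=3)
        s = eng.share(5)
        assert sum(s.values) % 2**32 == 5

    def test_exhaustive_round_trip_k8(self, small_engine):
        for x in range(256):
            assert small_engine.reconstruct(small_engine.share(x)) == x

    def test_random_round_trip_k8_many(self, small_engine):
        rng = random.Random(0)
        for _ in range(1000):
            x = rng.randrange(256)
            assert small_engine.reconstruct(small_engine.share(x)) == x

    def test_out_of_range_secret_rejected(self, small_engine):
        with pytest.raises(RangeError):
            small_engine.share(256)
        with pytest.raises(RangeError):
            small_engine.share(-1)

    def test_vector_round_trip(self, engine):
        values = list(range(50))
        assert engine.reconstruct_vector(engine.share_vector(values)) == values


class TestReconstruct:
    def test_sum_mod_256(self, small_engine):
        s = SharedScalar.from_values((1, 2, 3), RingConfig(8))
        assert small_engine.reconstruct(s) == 6

    def test_wraparound(self, small_engine):
        s = SharedScalar.from_values((255, 1, 0), RingConfig(8))
        assert small_engine.reconstruct(s) == 0

    def test_ring_mismatch_rejected(self, small_engine):
        s = SharedScalar.from_values((1, 2, 3), RingConfig(16))
        with pytest.raises(ProtocolError):
            small_engine.reconstruct(s)

    def test_malformed_share_tuple_rejected(self):
        with pytest.raises(RingError):
            SharedScalar.from_values((1, 2), RingConfig(8))


class TestLocalHomomorphisms:
    def test_add_exhaustive_k6(self):
        eng = Engine(RingConfig(8), seed=9)  # k=8 ring, exhaustive on 6-bit secrets
        shares = [eng.share(x) for x in range(64)]
        for x in range(64):
            for y in range(64):
                assert eng.reconstruct(eng.add(shares[x], shares[y])) == (x + y) % 256

    def test_add_identity(self, engine):
        a = engine.share(41)
        assert engine.reconstruct(engine.add(a, engine.share(0))) == 41

    def test_mul_public_matches_plaintext(self):
        eng = Engine(RingConfig(16), seed=5)
        rng = random.Random(1)
        for _ in range(200):
            c, x = rng.randrange(2**16), rng.randrange(2**16)
            assert eng.reconstruct(eng.mul_public(eng.share(x), c)) == (c * x) % 2**16

    def test_mul_public_annihilator_and_doubling(self, engine):
        x = engine.share(5)
        assert engine.reconstruct(engine.mul_public(x, 0)) == 0
        assert engine.reconstruct(engine.mul_public(x, 2)) == 10

    def test_add_public(self, small_engine):
        x = small_engine.share(250)
        assert small_engine.reconstruct(small_engine.add_public(x, 10)) == 4


class TestSecureMultiplication:
    def test_exhaustive_k8_ring(self):
        eng = Engine(RingConfig(8), seed=7)
        for x in range(256):
            sx = eng.share(x)
            for y in range(256):
                assert eng.reconstruct(eng.mul(sx, eng.share(y))) == (x * y) % 256

    def test_identity_and_annihilator(self, engine):
        x = engine.share(12345)
        assert engine.reconstruct(engine.mul(engine.share(1), x)) == 12345
        assert engine.reconstruct(engine.mul(engine.share(0), x)) == 0

    def test_triple_exhaustion_is_configuration_error(self, engine_factory):
        eng = engine_factory(capacity=2)
        a, b = eng.share(2), eng.share(3)
        eng.mul(a, b)
        eng.mul(a, b)
        with pytest.raises(ConfigurationError):
            eng.mul(a, b)

    def test_issued_triples_satisfy_c_eq_ab(self, engine):
        for _ in range(100):
            ta, tb, tc = engine.triples.triple()
            a = engine.reconstruct(ta)
            b = engine.reconstruct(tb)
            assert engine.reconstruct(tc) == (a * b) % engine.ring.modulus


class TestSecureComparison:
    def test_exhaustive_k8_in_contract(self):
        eng = Engine(RingConfig(8), seed=11)
        bound = 1 << 6  # 2^(k-2)
        for a in range(bound):
            sa = eng.share(a)
            for b in range(bound):
                got = eng.reconstruct(eng.geq(sa, eng.share(b)))
                assert got == int(a >= b), (a, b)

    def test_reflexive(self, engine):
        a = engine.share(77)
        assert engine.reconstruct(engine.geq(a, a)) == 1

    def test_zero_below_one(self, engine):
        assert engine.reconstruct(engine.geq(engine.share(0), engine.share(1))) == 0

    def test_large_operands_k128(self, engine):
        rng = random.Random(2)
        bound = 1 << 126
        for _ in range(50):
            a, b = rng.randrange(bound), rng.randrange(bound)
            got = engine.reconstruct(engine.geq(engine.share(a), engine.share(b)))
            assert got == int(a >= b)


class TestOpenAudit:
    def test_open_equals_reconstruct_and_logs(self, engine):
        v = engine.add(engine.share(3), engine.share(4))
        assert engine.open(v, label="sum", kind="value") == 7
        assert len(engine.audit) == 1
        rec = engine.audit[0]
        assert (rec.kind, rec.label, rec.value) == ("value", "sum", 7)

    def test_one_audit_entry_per_open(self, engine):
        for i in range(5):
            engine.open(engine.share(i), label=f"x{i}")
        assert len(engine.audit) == 5


class TestPrivacyProxy:
    """Over many sharings of one fixed secret, each single share — and the sum
    of any pair of shares — should be indistinguishable from uniform."""

    N_SAMPLES = 10_000

    @pytest.fixture(scope="class")
    @staticmethod
    def share_samples():
        eng = Engine(RingConfig(8), seed=20_717)
        return [eng.share(42).values for _ in range(TestPrivacyProxy.N_SAMPLES)]

    @pytest.mark.parametrize("host", [0, 1, 2])
    def test_single_share_uniform(self, share_samples, host):
        counts = [0] * 256
        for vals in share_samples:
            counts[vals[host]] += 1
        assert chisquare(counts).pvalue > 0.01

    @pytest.mark.parametrize("pair", [(0, 1), (0, 2), (1, 2)])
    def test_pairwise_share_sum_uniform(self, share_samples, pair):
        i, j = pair
        counts = [0] * 256
        for vals in share_samples:
            counts[(vals[i] + vals[j]) % 256] += 1
        assert chisquare(counts).pvalue > 0.01


class TestCommunicationDiscipline:
    def test_local_ops_send_no_messages(self, engine):
        a, b = engine.share(3), engine.share(4)
        before = engine.bus.messages
        engine.add(a, b)
        engine.add_public(a, 9)
        engine.mul_public(a, 5)
        assert engine.bus.messages == before

    def test_mul_message_count_is_input_independent(self, engine_factory):
        counts = []
        for secrets in ((0, 0), (1, 1), (2**100, 2**90)):
            eng = engine_factory(seed=5)
            eng.mul(eng.share(secrets[0]), eng.share(secrets[1]))
            counts.append(eng.bus.snapshot()["messages"])
        assert len(set(counts)) == 1

    def test_geq_message_count_is_input_independent(self, engine_factory):
        counts = []
        for a, b in ((0, 0), (1, 2**60), (2**125, 3)):
            eng = engine_factory(seed=5)
            eng.geq(eng.share(a), eng.share(b))
            counts.append(eng.bus.snapshot()["messages"])
        assert len(set(counts)) == 1

    def test_dot_payload_scales_with_length_only(self, engine_factory):
        snaps = []
        for fill in (0, 1, 2):
            eng = engine_factory(seed=8)
            x = eng.share_vector([fill] * 40)
            y = eng.share_vector([2] * 40)
            eng.dot(x, y)
            snaps.append(eng.bus.snapshot()["payload_elements"])
        assert len(set(snaps)) == 1


class TestFunctionalAliases:
    def test_alias_surface(self, engine):
        a = share_secret(9, engine)
        b = share_secret(4, engine)
        assert reconstruct(add_shared(a, b, engine), engine) == 13
        assert reconstruct(mul_shared(a, b, engine), engine) == 36
        assert reconstruct(mul_public(a, 3, engine), engine) == 27
        assert reconstruct(secure_geq(a, b, engine), engine) == 1


class TestSharedVector:
    def test_take_gathers_columns(self, engine):
        v = engine.share_vector([10, 20, 30, 40])
        sub = v.take([3, 1])
        assert engine.reconstruct_vector(sub) == [40, 20]

    def test_from_scalars_round_trip(self, engine):
        scalars = [engine.share(i * i) for i in range(5)]
        v = SharedVector.from_scalars(scalars)
        assert engine.reconstruct_vector(v) == [0, 1, 4, 9, 16]

    def test_ragged_rows_rejected(self):
        with pytest.raises(RingError):
            SharedVector(([1], [2, 3], [4]), RingConfig(8))
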