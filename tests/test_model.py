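import math

import numpy as np
import pytest

from lapasm import model
from lapasm.model import (
    AlignmentHit,
    ModelConfigError,
    ModelParams,
    ReadSet,
    combined_lap,
    connected_mask,
    connectivity_penalty,
    default_noalign_scale,
    log_alignment_weight,
    log_no_alignment_floor,
    no_alignment_floor,
    pair_distance,
    paired_read_probability,
    read_set_lap,
    single_read_probability,
)


def hit(start=0, end=20, strand=1, matches=20, errors=0, wid=0, lw=None):
    return AlignmentHit(wid, start, end, strand, matches, errors, lw)


class TestAlignmentWeight:
    def test_matches_closed_form(self):
        eps = 0.01
        assert log_alignment_weight(2, 98, eps) == pytest.approx(
            2 * math.log(eps) + 98 * math.log(1 - eps)
        )

    def test_zero_error_rate_limit(self):
        assert log_alignment_weight(0, 50, 0.0) == 0.0
        assert log_alignment_weight(1, 49, 0.0) == -math.inf


class TestSingleRead:
    def test_sum_over_hits(self):
        params = ModelParams(error_rate=0.05)
        hits = [hit(errors=0, matches=20), hit(start=50, end=70, errors=2, matches=18)]
        expected = (0.95**20 + 0.05**2 * 0.95**18) / (2 * 1000)
        assert single_read_probability(hits, 1000, params) == pytest.approx(expected)

    def test_empty_hits_is_zero(self):
        assert single_read_probability([], 1000, ModelParams()) == 0.0

    def test_precomputed_log_weight_used(self):
        params = ModelParams(error_rate=0.1)
        h = hit(lw=math.log(0.5))
        assert single_read_probability([h], 1, params) == pytest.approx(0.25)


class TestPairDistance:
    def test_fr_geometry(self):
        a = hit(start=0, end=100, strand=1)
        b = hit(start=400, end=500, strand=-1)
        assert pair_distance(a, b, "fr") == 500.0
        assert pair_distance(b, a, "fr") == 500.0  # order-insensitive

    def test_wrong_strands_rejected(self):
        a = hit(start=0, end=100, strand=-1)
        b = hit(start=400, end=500, strand=1)
        assert pair_distance(a, b, "fr") is None
        assert pair_distance(a, b, "rf") == 500.0

    def test_same_strand_and_walk_mismatch(self):
        a = hit(strand=1)
        assert pair_distance(a, hit(strand=1, start=300, end=400), "fr") is None
        assert pair_distance(a, hit(strand=-1, wid=1, start=300, end=400), "fr") is None

    def test_paired_probability_matches_manual(self):
        params = ModelParams(error_rate=0.01, insert_mean=500, insert_sd=50)
        h1 = [hit(start=0, end=100, strand=1, matches=100)]
        h2 = [hit(start=400, end=500, strand=-1, matches=99, errors=1)]
        L = 10000
        w = 0.99**100 * (0.01 * 0.99**99)
        dens = math.exp(-0.5 * 0.0) / (50 * math.sqrt(2 * math.pi))
        assert paired_read_probability(h1, h2, L, params) == pytest.approx(
            w * dens / (2 * L)
        )


class TestFloor:
    def test_floor_value(self):
        params = ModelParams(noalign_offset=-15, noalign_scale=-0.2)
        assert log_no_alignment_floor(100, params) == pytest.approx(-35.0)
        assert no_alignment_floor([100, 100], params) == pytest.approx(math.exp(-55.0))

    def test_default_scale_by_technology(self):
        assert default_noalign_scale(0.01, "short-accurate") == -0.2
        k_long = default_noalign_scale(0.1, "long-noisy")
        per_base = 0.1 * math.log(0.1) + 0.9 * math.log(0.9)
        assert k_long == pytest.approx(1.5 * per_base)
        assert k_long < per_base  # genuine placements clear the floor


class TestConnectivity:
    def test_connected_requires_early_start(self):
        # base j connected iff covered by an interval starting >= w before it
        mask = connected_mask(100, [(10, 60)], conn_window=20)
        assert not mask[:30].any()
        assert mask[30:60].all()
        assert not mask[60:].any()

    def test_exempt_intervals(self):
        mask = connected_mask(50, [], conn_window=10, exempt_intervals=[(0, 9)])
        assert mask[:9].all() and not mask[9:].any()

    def test_penalty_with_boundary_exemption(self):
        params = ModelParams(conn_window=10, penalty_alpha=2.0)
        d, pen = connectivity_penalty({0: 30}, {0: []}, params)
        assert d == 30 - 2 * 10  # conn_window bases exempt at each boundary
        assert pen == 2.0 * d

    def test_penalty_without_exemption(self):
        params = ModelParams(conn_window=10, penalty_alpha=3.0, exempt_walk_starts=False)
        d, _ = connectivity_penalty({0: 30}, {0: []}, params)
        assert d == 30


class TestCombination:
    def test_weighted_total_with_penalty_inside(self):
        p1 = ModelParams(weight=1.0, penalty_alpha=3.0)
        p2 = ModelParams(weight=0.5, penalty_alpha=2.0)
        b = combined_lap([-10.0, -20.0], [2, 1], [p1, p2])
        assert b.total == pytest.approx(1.0 * (-10 - 6) + 0.5 * (-20 - 2))
        assert b.penalties == [6.0, 2.0]

    def test_zero_weight_set_contributes_nothing(self):
        p = ModelParams(weight=0.0)
        assert combined_lap([-999.0], [100], [p]).total == 0.0

    def test_lap_mean_of_logs(self):
        assert read_set_lap([math.exp(-1), math.exp(-3)]) == pytest.approx(-2.0)

    def test_lap_rejects_zero_probability(self):
        with pytest.raises(RuntimeError):
            read_set_lap([0.5, 0.0])


class TestValidation:
    def test_paired_set_needs_insert_model(self):
        with pytest.raises(ModelConfigError):
            ReadSet(reads=["ACGT"], mates=["ACGT"], paired=True, params=ModelParams())

    def test_bad_orientation(self):
        with pytest.raises(ModelConfigError):
            ModelParams(orientation="ff").validate()

    def test_positive_noalign_scale_rejected(self):
        with pytest.raises(ModelConfigError):
            ModelParams(noalign_scale=0.1).validate()
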