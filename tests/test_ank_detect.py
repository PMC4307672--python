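"""Detection rule set: the four criteria, boundary rules, tandem grouping."""

import numpy as np
import pytest

from ankpred import (
    AnkFixtureSpec,
    DetectionParams,
    EigenProfile,
    HelixSpec,
    build_ank_fixture,
    build_contact_network,
    build_helix,
    build_parallel_bundle,
    chain_passes_batch_filter,
    core_length_ok,
    detect_ank,
    eigen_dominance,
    find_hth_candidates,
    is_antiparallel,
    peak_distance_ok,
    principal_eigenvector,
    repeat_end,
    repeat_start,
    verify_repeat,
)
from ankpred.ank_detect import HelixPair
from ankpred.ss_assign import SSClass, SSESegment, assign_internal, segments_from_classes
from ankpred.synthetic_fixtures import build_extended_chain, coords_to_chain

PARAMS = DetectionParams()


def make_pair(s1, e1, s2, e2, peak1=None, peak2=None):
    return HelixPair(
        h1=SSESegment(SSClass.HELIX, s1, e1),
        h2=SSESegment(SSClass.HELIX, s2, e2),
        peak1=s1 if peak1 is None else peak1,
        peak2=s2 if peak2 is None else peak2,
    )


def profile_from(values):
    v = np.asarray(values, dtype=float)
    return EigenProfile(lam=1.0, levc=v)


class TestCriteria:
    def test_antiparallel_true_for_reversed_helix(self):
        h1 = build_helix(HelixSpec(n_res=10))
        h2 = build_helix(
            HelixSpec(
                n_res=10,
                axis_origin=(9.0, 13.5, 0.0),
                axis_direction=(0.0, -1.0, 0.0),
            )
        )
        chain = coords_to_chain(np.vstack([h1, h2]))
        pair = make_pair(0, 9, 10, 19)
        assert is_antiparallel(chain, pair) is True

    def test_antiparallel_false_for_parallel_helices(self):
        h1 = build_helix(HelixSpec(n_res=10))
        h2 = build_helix(HelixSpec(n_res=10, axis_origin=(9.0, 0.0, 0.0)))
        chain = coords_to_chain(np.vstack([h1, h2]))
        pair = make_pair(0, 9, 10, 19)
        assert is_antiparallel(chain, pair) is False

    def test_antiparallel_degenerate_coincident_points(self):
        # E2 coincides with S1: 0 < d(E1, E2), so anti-parallel holds
        coords = build_extended_chain(20)
        coords[19] = coords[0]
        chain = coords_to_chain(coords)
        assert is_antiparallel(chain, make_pair(0, 9, 10, 19)) is True

    def test_eigen_dominance_strict_mean_comparison(self):
        prof = profile_from([0.10] * 5 + [0.0] * 2 + [0.05] * 5)
        pair = make_pair(0, 4, 7, 11)
        assert eigen_dominance(prof, pair) is True
        # equal means fail the strict inequality; so does a flat profile
        flat = profile_from([0.2] * 12)
        assert eigen_dominance(flat, pair) is False

    @pytest.mark.parametrize(
        "p1,p2,ok",
        [(10, 20, True), (10, 15, True), (10, 25, True),
         (10, 14, False), (10, 26, False)],
    )
    def test_peak_distance_bounds_inclusive(self, p1, p2, ok):
        pair = make_pair(0, 12, 14, 30, peak1=p1, peak2=p2)
        assert peak_distance_ok(pair, PARAMS) is ok

    @pytest.mark.parametrize(
        "s1,e2,ok", [(0, 12, True), (0, 11, False), (5, 30, True)]
    )
    def test_core_length_minimum(self, s1, e2, ok):
        pair = make_pair(s1, s1 + 4, e2 - 4, e2)
        assert core_length_ok(pair, PARAMS) is ok


class TestBoundaries:
    @pytest.mark.parametrize(
        "s1,start,terminal", [(10, 6, False), (4, 0, False), (2, 0, True)]
    )
    def test_start_minus_four_with_clamp(self, s1, start, terminal):
        pair = make_pair(s1, s1 + 5, s1 + 8, s1 + 14)
        assert repeat_start(pair, PARAMS) == (start, terminal)

    def test_end_is_argmin_over_turn_residues(self):
        # H2 ends at 9; TURN at 10-12 with values 0.05, 0.02, 0.04
        classes = [SSClass.HELIX] * 10 + [SSClass.TURN] * 3 + [SSClass.COIL] * 17
        segs = segments_from_classes(classes, "test")
        levc = np.full(30, 0.5)
        levc[10:13] = [0.05, 0.02, 0.04]
        pair = make_pair(0, 4, 5, 9)
        end, rule = repeat_end(profile_from(levc), segs, pair, None, PARAMS)
        assert (end, rule) == (11, "turn_min")

    def test_end_falls_back_to_coil_without_turns(self):
        classes = [SSClass.HELIX] * 10 + [SSClass.COIL] * 20
        segs = segments_from_classes(classes, "test")
        levc = np.full(30, 0.5)
        levc[14] = 0.01
        pair = make_pair(0, 4, 5, 9)
        end, rule = repeat_end(profile_from(levc), segs, pair, None, PARAMS)
        assert (end, rule) == (14, "turn_min")

    def test_terminal_repeat_ends_at_chain_end(self):
        # H2 ends 3 residues before the chain end: window runs past it
        classes = [SSClass.HELIX] * 10 + [SSClass.COIL] * 3
        segs = segments_from_classes(classes, "test")
        pair = make_pair(0, 4, 5, 9)
        end, rule = repeat_end(profile_from(np.full(13, 0.3)), segs, pair, None, PARAMS)
        assert (end, rule) == (12, "chain_end")

    def test_window_truncated_by_next_repeat(self):
        # next repeat starts 6 residues after E2; a deeper minimum at +9
        # lies outside the truncated 5-residue window
        classes = [SSClass.HELIX] * 10 + [SSClass.TURN] * 10 + [SSClass.COIL] * 10
        segs = segments_from_classes(classes, "test")
        levc = np.full(30, 0.5)
        levc[12] = 0.10  # within window (E2+1 .. E2+5)
        levc[18] = 0.01  # at +9: outside
        pair = make_pair(0, 4, 5, 9)
        end, rule = repeat_end(profile_from(levc), segs, pair, 15, PARAMS)
        assert (end, rule) == (12, "turn_min")

    def test_tie_breaks_to_lowest_index(self):
        classes = [SSClass.HELIX] * 10 + [SSClass.TURN] * 5 + [SSClass.COIL] * 15
        segs = segments_from_classes(classes, "test")
        levc = np.full(30, 0.5)
        levc[10:15] = [0.3, 0.1, 0.1, 0.3, 0.3]
        pair = make_pair(0, 4, 5, 9)
        end, _ = repeat_end(profile_from(levc), segs, pair, None, PARAMS)
        assert end == 11


class TestCandidates:
    def test_strand_between_helices_breaks_pair(self):
        classes = (
            [SSClass.HELIX] * 6 + [SSClass.STRAND] * 3 + [SSClass.HELIX] * 6
        )
        segs = segments_from_classes(classes, "test")
        assert find_hth_candidates(segs, profile_from(np.ones(15))) == []

    def test_turn_between_helices_forms_pair(self):
        classes = [SSClass.HELIX] * 6 + [SSClass.TURN] * 3 + [SSClass.HELIX] * 6
        segs = segments_from_classes(classes, "test")
        pairs = find_hth_candidates(segs, profile_from(np.ones(15)))
        assert len(pairs) == 1
        assert (pairs[0].s1, pairs[0].e1, pairs[0].e2) == (0, 5, 14)

    def test_peak_tie_takes_lowest_index(self):
        classes = [SSClass.HELIX] * 6 + [SSClass.COIL] * 2 + [SSClass.HELIX] * 6
        segs = segments_from_classes(classes, "test")
        pairs = find_hth_candidates(segs, profile_from(np.ones(14)))
        assert (pairs[0].peak1, pairs[0].peak2) == (0, 8)


class TestDetection:
    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_copy_number_recovery(self, k):
        chain = build_ank_fixture(AnkFixtureSpec(n_copies=k, seed=1))
        net = build_contact_network(chain)
        prof = principal_eigenvector(net)
        segs = assign_internal(chain)
        regions = detect_ank(chain, segs, prof)
        assert len(regions) == 1
        assert regions[0].n_repeats == k

    def test_single_copy_discarded(self):
        chain = build_ank_fixture(AnkFixtureSpec(n_copies=1, seed=1))
        net = build_contact_network(chain)
        regions = detect_ank(chain, assign_internal(chain), principal_eigenvector(net))
        assert regions == []

    def test_negative_control_single_helix(self):
        chain = coords_to_chain(build_helix(HelixSpec(n_res=60)))
        net = build_contact_network(chain)
        regions = detect_ank(chain, assign_internal(chain), principal_eigenvector(net))
        assert regions == []

    def test_negative_control_parallel_bundle(self):
        chain = build_parallel_bundle()
        net = build_contact_network(chain)
        regions = detect_ank(chain, assign_internal(chain), principal_eigenvector(net))
        assert regions == []

    def test_gap_sensitivity_long_loop_splits_region(self):
        chain = build_ank_fixture(AnkFixtureSpec(n_copies=2, seed=1, loop_len=25))
        net = build_contact_network(chain)
        regions = detect_ank(chain, assign_internal(chain), principal_eigenvector(net))
        assert regions == []

    def test_zero_helices_empty_result(self):
        chain = coords_to_chain(build_extended_chain(60))
        net = build_contact_network(chain)
        regions = detect_ank(chain, assign_internal(chain), principal_eigenvector(net))
        assert regions == []

    def test_determinism(self, ank4):
        chain, _, prof, segs = ank4
        r1 = detect_ank(chain, segs, prof)
        r2 = detect_ank(chain, segs, prof)
        assert [
            (x.start, x.end, x.end_rule, x.terminal) for g in r1 for x in g.repeats
        ] == [(x.start, x.end, x.end_rule, x.terminal) for g in r2 for x in g.repeats]

    def test_reported_repeats_satisfy_all_criteria(self, ank4):
        chain, _, prof, segs = ank4
        regions = detect_ank(chain, segs, prof)
        for region in regions:
            for rep in region.repeats:
                assert verify_repeat(chain, prof, rep)

    def test_region_invariants(self, ank4):
        chain, _, prof, segs = ank4
        regions = detect_ank(chain, segs, prof)
        for region in regions:
            assert region.n_repeats >= 2
            for a, b in zip(region.repeats, region.repeats[1:]):
                assert a.end < b.start
                assert (b.start - a.end - 1) <= PARAMS.tandem_gap_max

    def test_first_copy_is_clamped_terminal(self, ank4):
        chain, _, prof, segs = ank4
        regions = detect_ank(chain, segs, prof)
        first = regions[0].repeats[0]
        assert first.start == 0
        assert first.terminal
        # interior repeats start exactly 4 before their first helix
        for rep in regions[0].repeats[1:]:
            assert rep.pair.s1 - rep.start == PARAMS.start_offset


@pytest.mark.parametrize("n,ok", [(49, False), (50, True), (500, True)])
def test_batch_filter_boundary(n, ok):
    chain = coords_to_chain(build_extended_chain(n))
    assert chain_passes_batch_filter(chain, PARAMS) is ok


def test_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(peak_dist_min=16)
    with pytest.raises(ValueError):
        DetectionParams(r_c=-1.0)
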