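"""The cherry-pick workflow: validation, deconvolution, reservation, mapping."""

import math
import random
from datetime import date

import pytest

import screenkit as sk
from screenkit.cherrypick import view_well_volumes
from screenkit.core_model import ScreenType, WellKey, WellType
from screenkit.inventory import ul_to_nl


@pytest.fixture
def sm_setup(sm_library, screener, log, today):
    """A screen over the SM library with one cherry-pick source copy at 10 µL."""
    screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
    sk.create_copy(sm_library, "C", "cherry_pick_source", 10.0)
    return screen, sm_library, screener


def _request(screen, lib, screener, picks, volume=2.0, log=None, **options):
    req = sk.create_request(
        screen, picks, volume, [lib], screener, date(2024, 3, 1), log=log, **options
    )
    sk.deconvolute(req, [lib])
    return req


def _experimental_keys(lib, n):
    keys = sorted(k for k, w in lib.wells.items() if w.well_type is WellType.EXPERIMENTAL)
    return keys[:n]


class TestValidation:
    def test_valid_picks_accepted(self, sm_setup):
        screen, lib, screener = sm_setup
        req = _request(screen, lib, screener, _experimental_keys(lib, 100))
        assert sum(p.status == "accepted" for p in req.screener_picks) == 100

    def test_duplicate_rejected(self, sm_setup):
        screen, lib, screener = sm_setup
        key = _experimental_keys(lib, 1)[0]
        req = _request(screen, lib, screener, [key, key])
        statuses = [(p.status, p.rejection_reason) for p in req.screener_picks]
        assert statuses == [("accepted", None), ("rejected", "duplicate")]

    def test_deprecated_rejected(self, sm_setup, volume_admin, log):
        screen, lib, screener = sm_setup
        keys = _experimental_keys(lib, 10)
        sk.deprecate_wells(lib, [keys[3]], "contamination", volume_admin, log)
        req = _request(screen, lib, screener, keys)
        rejected = [p for p in req.screener_picks if p.status == "rejected"]
        assert len(rejected) == 1 and rejected[0].rejection_reason == "deprecated"

    def test_over_limit_in_submission_order(self, sm_setup):
        screen, lib, screener = sm_setup
        req = _request(screen, lib, screener, _experimental_keys(lib, 7), max_picks_policy=5)
        reasons = [p.rejection_reason for p in req.screener_picks]
        assert reasons == [None] * 5 + ["over_limit", "over_limit"]

    def test_control_well_rejected_non_experimental(self, sm_setup):
        screen, lib, screener = sm_setup
        control = next(
            k for k, w in lib.wells.items() if w.well_type is WellType.DMSO_CONTROL
        )
        req = _request(screen, lib, screener, [control])
        assert req.screener_picks[0].rejection_reason == "non_experimental"

    def test_unknown_well_rejected(self, sm_setup):
        screen, lib, screener = sm_setup
        req = _request(screen, lib, screener, [WellKey(999, "A01")])
        assert req.screener_picks[0].rejection_reason == "unknown_well"

    def test_zero_volume_rejected(self, sm_setup):
        screen, lib, screener = sm_setup
        with pytest.raises(sk.ValidationError):
            _request(screen, lib, screener, _experimental_keys(lib, 1), volume=0.0)


class TestDeconvolution:
    def test_small_molecule_one_to_one(self, sm_setup):
        screen, lib, screener = sm_setup
        req = _request(screen, lib, screener, _experimental_keys(lib, 10))
        assert len(req.lab_picks) == 10
        assert all(p.status == "unfulfilled" for p in req.lab_picks)

    def test_pool_expands_to_duplexes(self, rnai_libraries, screener):
        pool_lib, duplex_lib = rnai_libraries
        screen = sk.Screen("R1", ScreenType.RNAI, libraries=[pool_lib, duplex_lib])
        picks = _experimental_keys(pool_lib, 2)
        req = sk.create_request(screen, picks, 2.0, [pool_lib, duplex_lib], screener,
                                date(2024, 3, 1))
        sk.deconvolute(req, [pool_lib, duplex_lib])
        assert len(req.lab_picks) == 8  # 2 pools × 4 duplexes
        for p in req.lab_picks:
            assert duplex_lib.wells[p.source_well].reagent.silencing_type == "duplex"

    def test_mixed_pools_and_duplexes_sum(self, rnai_libraries, screener):
        """Expansion equals the brute-force sum over the pick→duplex mapping."""
        pool_lib, duplex_lib = rnai_libraries
        screen = sk.Screen("R1", ScreenType.RNAI, libraries=[pool_lib, duplex_lib])
        pool_picks = _experimental_keys(pool_lib, 2)
        duplex_picks = _experimental_keys(duplex_lib, 3)
        req = sk.create_request(screen, pool_picks + duplex_picks, 2.0,
                                [pool_lib, duplex_lib], screener, date(2024, 3, 1))
        sk.deconvolute(req, [pool_lib, duplex_lib])
        expected = sum(
            len(pool_lib.wells[k].reagent.duplex_well_keys) for k in pool_picks
        ) + len(duplex_picks)
        assert expected == 11
        assert len(req.lab_picks) == expected


class TestViewWellVolumes:
    def test_sufficiency_rows(self, sm_library, screener):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        sk.create_copy(sm_library, "C", "cherry_pick_source", 10.0)
        sk.create_copy(sm_library, "D", "cherry_pick_source", 1.0)
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, 1))
        rows = view_well_volumes(req)
        assert [(r[1], r[2], r[3]) for r in rows] == [("C", 10.0, True), ("D", 1.0, False)]

    def test_exact_volume_is_sufficient(self, sm_library, screener):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        sk.create_copy(sm_library, "C", "cherry_pick_source", 2.0)
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, 1))
        assert view_well_volumes(req)[0][3] is True

    def test_retired_plates_excluded(self, sm_library, screener):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        copy = sk.create_copy(sm_library, "C", "cherry_pick_source", 10.0)
        for plate in copy.plates.values():
            plate.retired = True
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, 1))
        assert view_well_volumes(req) == []


class TestReserve:
    def test_smallest_sufficient_copy_wins(self, sm_library, screener):
        """Brute-force check of the copy-selection rule on a 2-copy case."""
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        sk.create_copy(sm_library, "C", "cherry_pick_source", 10.0)
        sk.create_copy(sm_library, "D", "cherry_pick_source", 3.0)
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, 1))
        sk.reserve_reagent(req)
        pick = req.lab_picks[0]
        # oracle: among sufficient copies pick min (remaining, name)
        candidates = [(ul_to_nl(10.0), "C"), (ul_to_nl(3.0), "D")]
        expected = min(c for c in candidates if c[0] >= ul_to_nl(2.0))[1]
        assert pick.source_copy == expected == "D"
        assert sm_library.copies["D"].remaining_ul(pick.source_well) == 1.0
        assert sm_library.copies["C"].remaining_ul(pick.source_well) == 10.0

    def test_no_sufficient_copy_leaves_unfulfilled(self, sm_library, screener):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        sk.create_copy(sm_library, "C", "cherry_pick_source", 1.0)
        sk.create_copy(sm_library, "D", "cherry_pick_source", 1.0)
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, 1))
        assert sk.reserve_reagent(req) == 0
        assert req.lab_picks[0].status == "unfulfilled"
        key = req.lab_picks[0].source_well
        assert sm_library.copies["C"].remaining_ul(key) == 1.0

    def test_sequential_depletion_same_source_well(self, rnai_libraries, screener):
        """Two lab picks drawing the same duplex well deplete it sequentially."""
        pool_lib, duplex_lib = rnai_libraries
        screen = sk.Screen("R1", ScreenType.RNAI, libraries=[pool_lib, duplex_lib])
        sk.create_copy(duplex_lib, "C", "cherry_pick_source", 3.0)
        libs = [pool_lib, duplex_lib]
        target = _experimental_keys(duplex_lib, 1)[0]
        req = sk.create_request(screen, [target], 2.0, libs, screener, date(2024, 3, 1))
        sk.deconvolute(req, libs)
        # duplicate the lab pick manually to simulate two picks on one source well
        req.lab_picks.append(
            sk.LabCherryPick(source_well=target, screener_pick=req.screener_picks[0])
        )
        assert sk.reserve_reagent(req) == 1
        statuses = sorted(p.status for p in req.lab_picks)
        assert statuses == ["reserved", "unfulfilled"]
        assert duplex_lib.copies["C"].remaining_ul(target) == 1.0

    def test_reservation_is_deterministic(self, sm_library, screener):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        sk.create_copy(sm_library, "B", "cherry_pick_source", 5.0)
        sk.create_copy(sm_library, "A", "cherry_pick_source", 5.0)
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, 5))
        sk.reserve_reagent(req)
        # equal volumes: lexicographic tie-break
        assert all(p.source_copy == "A" for p in req.lab_picks)


class TestMapping:
    def _reserved_request(self, sm_library, screener, n_picks, **options):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        if "C" not in sm_library.copies:
            sk.create_copy(sm_library, "C", "cherry_pick_source", 100.0)
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, n_picks),
                       **options)
        sk.reserve_reagent(req)
        return req

    def test_ceiling_plate_count_with_empty_wells(self, sm_library, screener):
        empty = frozenset(
            sk.format_well_name(sk.WellCoordinate(r, c), sk.PlateFormat.F384)
            for r in (0, 15) for c in range(12)
        )  # 24 forbidden wells
        req = self._reserved_request(
            sm_library, screener, 700, required_empty_wells=empty
        )
        plates = sk.map_to_plates(req)
        assert len(plates) == math.ceil(700 / 360)
        assert [len(p.picks) for p in plates] == [360, 340]
        for plate in plates:
            names = [p.destination_well for p in plate.picks]
            assert len(set(names)) == len(names)
            assert not set(names) & empty

    def test_randomized_layout_reproducible(self, sm_library, screener):
        req1 = self._reserved_request(sm_library, screener, 50,
                                      randomize_layout=True, random_seed=42)
        plates1 = sk.map_to_plates(req1)
        assignment1 = [(str(p.source_well), p.destination_well) for p in req1.lab_picks]

        lib2 = sk.generate_library(
            sk.FixtureSpec(seed=11, n_plates=2, short_name="SM1")
        )[0]
        req2 = self._reserved_request(lib2, screener, 50,
                                      randomize_layout=True, random_seed=42)
        sk.map_to_plates(req2)
        assignment2 = [(str(p.source_well), p.destination_well) for p in req2.lab_picks]
        assert assignment1 == assignment2
        # and it is an actual permutation, not row-major
        row_major = [p.destination_well for p in plates1[0].picks]
        assert row_major != sorted(
            row_major, key=lambda n: sk.parse_well_name(n, sk.PlateFormat.F384)
        )

    def test_unrandomized_layout_is_row_major(self, sm_library, screener):
        req = self._reserved_request(sm_library, screener, 30)
        (plate,) = sk.map_to_plates(req)
        dests = [p.destination_well for p in plate.picks]
        assert dests == [
            sk.format_well_name(sk.WellCoordinate(i // 24, i % 24), sk.PlateFormat.F384)
            for i in range(30)
        ]

    def test_source_plates_batched_in_export(self, sm_library, screener):
        req = self._reserved_request(sm_library, screener, 500)
        sk.map_to_plates(req)
        csv = sk.export_plate_mapping(req)
        lines = csv.strip().splitlines()
        assert lines[0].startswith("source_plate,")
        assert len(lines) - 1 == 500
        by_dest = {}
        for line in lines[1:]:
            src_plate, _, _, dest, _, _ = line.split(",")
            by_dest.setdefault(dest, []).append(int(src_plate))
        for seq in by_dest.values():
            assert seq == sorted(seq)  # non-decreasing source plates

    def test_export_before_mapping_rejected(self, sm_library, screener):
        req = self._reserved_request(sm_library, screener, 5)
        with pytest.raises(sk.WorkflowError, match="no mapped picks"):
            sk.export_plate_mapping(req)
        sk.map_to_plates(req)
        assert sk.export_plate_mapping(req).count("\n") == 6

    def test_full_empty_set_rejected(self, sm_library, screener):
        req = self._reserved_request(
            sm_library, screener, 5,
            required_empty_wells=frozenset(
                sk.format_well_name(sk.WellCoordinate(r, c), sk.PlateFormat.F96)
                for r in range(8) for c in range(12)
            ),
        )
        with pytest.raises(sk.ValidationError, match="covers the whole"):
            sk.map_to_plates(req, sk.PlateFormat.F96)


class TestPlateStatus:
    def _mapped(self, sm_library, screener, log, n=20, volume=2.0):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        sk.create_copy(sm_library, "C", "cherry_pick_source", 10.0)
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, n),
                       volume=volume, log=log)
        sk.reserve_reagent(req)
        sk.map_to_plates(req)
        return req

    def test_plated_records_liquid_transfer(self, sm_library, screener, volume_admin, log):
        req = self._mapped(sm_library, screener, log)
        sk.update_plate_status(req, 1, "plated", volume_admin, date(2024, 3, 2), log)
        assert all(p.status == "plated" for p in req.lab_picks)
        assert len(log.query(kind="cherry_pick_liquid_transfer")) == 1

    def test_cancel_reverses_every_debit(self, sm_library, screener, volume_admin, log):
        req = self._mapped(sm_library, screener, log)
        before = {
            str(p.source_well): sm_library.copies["C"].remaining_ul(p.source_well)
            for p in req.lab_picks
        }
        assert all(v == 8.0 for v in before.values())
        sk.update_plate_status(req, 1, "canceled", volume_admin, date(2024, 3, 2), log)
        after = {
            str(p.source_well): sm_library.copies["C"].remaining_ul(p.source_well)
            for p in req.lab_picks
        }
        assert all(v == 10.0 for v in after.values())

    def test_failed_double_debits_and_attempt_two(self, sm_library, screener, volume_admin, log):
        req = self._mapped(sm_library, screener, log)
        sk.update_plate_status(req, 1, "failed", volume_admin, date(2024, 3, 2), log)
        respawned = [p for p in req.lab_picks if p.status == "unfulfilled"]
        assert len(respawned) == 20
        sk.reserve_reagent(req)
        (successor,) = sk.map_to_plates(req)
        assert successor.ordinal == 1 and successor.attempt == 2
        # reagent of the failed attempt stays consumed: two debits total
        for p in respawned:
            assert sm_library.copies["C"].remaining_ul(p.source_well) == 6.0

    def test_terminal_status_is_final(self, sm_library, screener, volume_admin, log):
        req = self._mapped(sm_library, screener, log)
        sk.update_plate_status(req, 1, "plated", volume_admin, date(2024, 3, 2), log)
        with pytest.raises(sk.WorkflowError, match="terminal"):
            sk.update_plate_status(req, 1, "canceled", volume_admin, date(2024, 3, 2), log)


class TestRollover:
    def test_unfulfilled_roll_into_new_request(self, sm_library, screener, log):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        copy = sk.create_copy(sm_library, "C", "cherry_pick_source", 10.0)
        keys = _experimental_keys(sm_library, 100)
        # starve 3 specific source wells
        for key in keys[:3]:
            copy.plates[key.plate_number].remaining_nl[key.well_name] = 0
        req = _request(screen, sm_library, screener, keys, log=log)
        sk.reserve_reagent(req)
        new_req = sk.rollover_unfulfilled(req)
        assert sorted(str(p.source_well) for p in new_req.screener_picks) == sorted(
            str(k) for k in keys[:3]
        )
        assert req.rolled_over

    def test_nothing_unfulfilled_is_error(self, sm_library, screener):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        sk.create_copy(sm_library, "C", "cherry_pick_source", 10.0)
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, 5))
        sk.reserve_reagent(req)
        with pytest.raises(sk.WorkflowError):
            sk.rollover_unfulfilled(req)

    def test_double_rollover_rejected(self, sm_library, screener):
        screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
        copy = sk.create_copy(sm_library, "C", "cherry_pick_source", 1.0)
        req = _request(screen, sm_library, screener, _experimental_keys(sm_library, 2))
        sk.reserve_reagent(req)
        sk.rollover_unfulfilled(req)
        with pytest.raises(sk.WorkflowError, match="already rolled over"):
            sk.rollover_unfulfilled(req)


def test_state_machine_never_leaves_declared_graph(sm_library, screener, volume_admin, log):
    """Random operation sequences can only produce declared status transitions."""
    rng = random.Random(7)
    screen = sk.Screen("S1", ScreenType.SMALL_MOLECULE, libraries=[sm_library])
    sk.create_copy(sm_library, "C", "cherry_pick_source", 6.0)
    keys = sorted(
        k for k, w in sm_library.wells.items() if w.well_type is WellType.EXPERIMENTAL
    )
    allowed = {
        ("unfulfilled", "reserved"), ("reserved", "mapped"), ("mapped", "plated"),
        ("mapped", "failed"), ("mapped", "canceled"),
    }
    for trial in range(5):
        req = _request(screen, sm_library, screener, rng.sample(keys, 40), volume=2.0)
        snapshots = [{id(p): p.status for p in req.lab_picks}]

        def snap():
            states = {id(p): p.status for p in req.lab_picks}
            old = snapshots[-1]
            for pid, status in states.items():
                if pid in old and old[pid] != status:
                    assert (old[pid], status) in allowed, (old[pid], status)
            snapshots.append(states)

        for op in range(6):
            action = rng.choice(["reserve", "map", "status"])
            try:
                if action == "reserve":
                    sk.reserve_reagent(req)
                elif action == "map":
                    sk.map_to_plates(req)
                else:
                    candidates = [p for p in req.plates if p.status == "not_plated"]
                    if candidates:
                        sk.update_plate_status(
                            req, rng.choice(candidates).ordinal,
                            rng.choice(["plated", "failed", "canceled"]),
                            volume_admin, date(2024, 3, 2), log,
                        )
            except sk.ScreenkitError:
                pass
            snap()
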