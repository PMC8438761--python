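"""Ensemble aggregation under the six trajectory-sourcing protocols."""

import numpy as np
import pytest

from esmacs import (EnergyComponents, EnsembleTable, ProtocolSpec,
                    SnapshotRecord, bind_free_energy, decompose,
                    receptor_constant, snapshot_free_energy)
from esmacs.errors import ProtocolInputError

from conftest import WORKED_DECOMPOSITIONS, make_single_record_table


class TestSnapshotFreeEnergy:
    def test_zero_components_give_zero(self):
        zero = EnergyComponents(0, 0, 0, 0, 0)
        assert snapshot_free_energy(zero) == 0.0
        assert snapshot_free_energy(zero, include_nonpolar=True) == 0.0

    @pytest.mark.parametrize("ligand,row", WORKED_DECOMPOSITIONS.items())
    def test_worked_component_sums(self, ligand, row):
        # components and totals are independently rounded to 0.01, so the
        # identity holds to ~0.015 across the whole panel (LDHA12 is off
        # by exactly one rounding ulp)
        ele, vdw, pol, nonpol, total = row
        c = EnergyComponents(0.0, ele, vdw, pol, nonpol)
        assert snapshot_free_energy(c) == pytest.approx(total, abs=0.015)
        assert snapshot_free_energy(c, include_nonpolar=True) == \
            pytest.approx(total + nonpol, abs=0.015)


def _hand_table():
    """2 replicas x 2 frames of hand-listed components for all three legs."""
    recs = []
    vals = {
        ("complex", 1, 0): (4.0, -30.0, -12.0, 20.0, -2.0),
        ("complex", 1, 1): (6.0, -34.0, -10.0, 24.0, -2.4),
        ("complex", 2, 0): (5.0, -28.0, -14.0, 18.0, -1.8),
        ("complex", 2, 1): (3.0, -36.0, -8.0, 26.0, -2.2),
        ("receptor", 1, 0): (3.0, -10.0, -2.0, 5.0, -0.5),
        ("receptor", 1, 1): (4.0, -12.0, -1.0, 6.0, -0.6),
        ("receptor", 2, 0): (3.5, -9.0, -3.0, 4.0, -0.4),
        ("receptor", 2, 1): (2.0, -13.0, -1.5, 7.0, -0.5),
        ("ligand", 1, 0): (1.0, -2.0, -1.0, 3.0, -0.1),
        ("ligand", 1, 1): (2.0, -3.0, -0.5, 4.0, -0.2),
        ("ligand", 2, 0): (1.5, -1.0, -2.0, 2.0, -0.1),
        ("ligand", 2, 1): (1.0, -4.0, -0.5, 5.0, -0.3),
    }
    for (kind, rep, frame), comps in vals.items():
        recs.append(SnapshotRecord("HAND", kind, "complex", rep, frame,
                                   EnergyComponents(*comps)))
    return EnsembleTable.from_records(recs), vals


class TestBindFreeEnergy:
    def test_perfect_cancellation_gives_zero_every_replica(self):
        recs = []
        comp = EnergyComponents(2.0, -8.0, -3.0, 6.0, -0.5)
        for rep in (1, 2, 3):
            for f in (0, 1):
                half = EnergyComponents(1.0, -4.0, -1.5, 3.0, -0.25)
                recs += [SnapshotRecord("L", "complex", "complex", rep, f, comp),
                         SnapshotRecord("L", "receptor", "complex", rep, f, half),
                         SnapshotRecord("L", "ligand", "complex", rep, f, half)]
        table = EnsembleTable.from_records(recs)
        result = bind_free_energy(table, ProtocolSpec("1traj", include_nonpolar=True), "L")
        assert np.all(result.replica_dg == 0.0)

    @pytest.mark.parametrize("ligand", ["LDHA14", "LDHA21", "LDHA26"])
    def test_single_record_tables_reproduce_worked_totals(self, ligand):
        ele, vdw, pol, nonpol, total = WORKED_DECOMPOSITIONS[ligand]
        table = make_single_record_table(ligand, ele, vdw, pol, nonpol)
        result = bind_free_energy(table, ProtocolSpec("1traj"), ligand)
        assert result.dg_mean == pytest.approx(total, abs=1e-9)
        assert result.dg_se is None  # single replica: absent, not zero

    @pytest.mark.parametrize("pairing", ["frame", "replica"])
    def test_hand_listed_table_matches_brute_force(self, pairing):
        table, vals = _hand_table()
        result = bind_free_energy(
            table, ProtocolSpec("1traj", include_nonpolar=True), "HAND",
            pairing=pairing)
        # independent brute force: enumerate every term explicitly
        replica_dg = []
        for rep in (1, 2):
            frame_totals = []
            for f in (0, 1):
                g = {kind: sum(vals[(kind, rep, f)]) for kind in
                     ("complex", "receptor", "ligand")}
                frame_totals.append(g["complex"] - g["receptor"] - g["ligand"])
            replica_dg.append(np.mean(frame_totals))
        assert result.dg_mean == pytest.approx(np.mean(replica_dg), abs=1e-12)
        assert result.replica_dg == pytest.approx(replica_dg, abs=1e-12)

    def test_replica_label_permutation_leaves_mean_unchanged(self):
        table, _ = _hand_table()
        relabel = {1: 2, 2: 1}
        recs = [SnapshotRecord(r.ligand_id, r.system_kind, r.source,
                               relabel[r.replica_index], r.frame_index, r.components)
                for r in table.records()]
        permuted = EnsembleTable.from_records(recs)
        spec = ProtocolSpec("1traj", include_nonpolar=True)
        a = bind_free_energy(table, spec, "HAND")
        b = bind_free_energy(permuted, spec, "HAND")
        assert a.dg_mean == pytest.approx(b.dg_mean, abs=1e-12)

    def test_nonpolar_flag_shift_equals_nonpol_breakdown(self):
        table, _ = _hand_table()
        with_np = bind_free_energy(table, ProtocolSpec("1traj", include_nonpolar=True), "HAND")
        without = bind_free_energy(table, ProtocolSpec("1traj"), "HAND")
        assert with_np.dg_mean - without.dg_mean == \
            pytest.approx(with_np.breakdown["nonpol"].mean, abs=1e-9)

    def test_breakdown_sums_to_total_for_1traj(self):
        table, _ = _hand_table()
        result = bind_free_energy(table, ProtocolSpec("1traj", include_nonpolar=True), "HAND")
        total = sum(result.breakdown[k].mean for k in ("int", "ele", "vdw", "pol", "nonpol"))
        assert total == pytest.approx(result.dg_mean, abs=1e-9)

    def test_missing_source_raises_protocol_input_error(self):
        table, _ = _hand_table()  # no independent records
        with pytest.raises(ProtocolInputError):
            bind_free_energy(table, ProtocolSpec("3traj"), "HAND")

    def test_internal_energy_cancels_on_consistent_tables(self, small_ensemble):
        _, table = small_ensemble
        result = bind_free_energy(table, ProtocolSpec("1traj"), "LIG01")
        assert result.breakdown["int"].mean == pytest.approx(0.0, abs=1e-10)

    def test_averaged_receptor_is_constant_shift_within_set(self, small_ensemble):
        """1traj-ar differs from 1traj by one ligand-independent constant."""
        _, table = small_ensemble
        shifts = []
        for lig in table.ligand_ids:
            a = bind_free_energy(table, ProtocolSpec("1traj"), lig)
            b = bind_free_energy(table, ProtocolSpec("1traj-ar"), lig)
            shifts.append(b.dg_mean - a.dg_mean)
        assert np.ptp(shifts) == pytest.approx(0.0, abs=1e-9)


class TestReceptorConstant:
    def _table_with_receptor_means(self, means):
        zero = EnergyComponents(0, 0, 0, 0, 0)
        recs = []
        for lig, mean in means.items():
            recs.append(SnapshotRecord(lig, "complex", "complex", 1, 0, zero))
            recs.append(SnapshotRecord(lig, "receptor", "complex", 1, 0,
                                       EnergyComponents(mean, 0, 0, 0, 0)))
            recs.append(SnapshotRecord(lig, "ligand", "complex", 1, 0, zero))
        return EnsembleTable.from_records(recs)

    def test_singleton_set_returns_own_average(self):
        table = self._table_with_receptor_means({"A": -12.5})
        assert receptor_constant(table, ["A"]) == pytest.approx(-12.5)

    def test_two_ligand_mean(self):
        table = self._table_with_receptor_means({"A": -10.0, "B": -20.0})
        assert receptor_constant(table, ["A", "B"]) == pytest.approx(-15.0)

    def test_three_ligand_brute_force(self, small_ensemble):
        _, table = small_ensemble
        ligs = table.ligand_ids[:3]
        # brute force: per ligand, average receptor totals per replica then overall
        per_ligand = []
        for lig in ligs:
            df = table.select(lig, "receptor", "complex")
            totals = df[["e_int", "e_ele", "e_vdw", "g_pol"]].sum(axis=1)
            per_ligand.append(totals.groupby(df["replica"]).mean().mean())
        expected = np.mean(per_ligand)
        assert receptor_constant(table, ligs) == pytest.approx(expected, rel=1e-12)

    def test_empty_set_rejected(self, small_ensemble):
        _, table = small_ensemble
        with pytest.raises(ValueError):
            receptor_constant(table, [])


class TestDecompose:
    def test_perfect_cancellation_gives_zero_components(self):
        zero = EnergyComponents(1.0, -2.0, 3.0, -4.0, 0.5)
        recs = []
        for rep in (1, 2):
            recs += [SnapshotRecord("L", "complex", "complex", rep, 0,
                                    EnergyComponents(2.0, -4.0, 6.0, -8.0, 1.0)),
                     SnapshotRecord("L", "receptor", "complex", rep, 0, zero),
                     SnapshotRecord("L", "ligand", "complex", rep, 0, zero)]
        table = EnsembleTable.from_records(recs)
        breakdown = decompose(table, ProtocolSpec("1traj"), "L")
        for stat in breakdown.values():
            assert stat.mean == pytest.approx(0.0, abs=1e-12)

    def test_worked_single_record_decomposition(self):
        ele, vdw, pol, nonpol, _ = WORKED_DECOMPOSITIONS["LDHA26"]
        table = make_single_record_table("LDHA26", ele, vdw, pol, nonpol)
        breakdown = decompose(table, ProtocolSpec("1traj"), "LDHA26")
        assert breakdown["ele"].mean == pytest.approx(-410.61, abs=1e-9)
        assert breakdown["vdw"].mean == pytest.approx(-56.23, abs=1e-9)
        assert breakdown["pol"].mean == pytest.approx(403.40, abs=1e-9)
        assert breakdown["nonpol"].mean == pytest.approx(-5.89, abs=1e-9)

    def test_multi_replica_breakdown_matches_brute_force(self, small_ensemble):
        _, table = small_ensemble
        breakdown = decompose(table, ProtocolSpec("1traj"), "LIG02")
        for key, col in (("ele", "e_ele"), ("vdw", "e_vdw"),
                         ("pol", "g_pol"), ("nonpol", "g_nonpol")):
            per_replica = []
            for kind_sign in [("complex", 1.0), ("receptor", -1.0), ("ligand", -1.0)]:
                kind, sign = kind_sign
                df = table.select("LIG02", kind, "complex")
                per_replica.append(sign * df.groupby("replica")[col].mean())
            expected = sum(per_replica).mean()
            assert breakdown[key].mean == pytest.approx(expected, abs=1e-9)
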