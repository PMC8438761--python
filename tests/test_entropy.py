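"""Entropy corrections: variational closed forms, WSAS arithmetic, ingestion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esmacs import (EnergyComponents, ProtocolSpec, ThermoParams,
                    WSASWeightTable, apply_entropy_correction, bind_free_energy,
                    gen_gaussian_einter, gen_toy_structure, interaction_energy,
                    interaction_energy_series, read_nm_entropy,
                    variational_entropy, wsas_entropy, wsas_score)
from esmacs.errors import ConfigurationError, DuplicateRecordError
from esmacs.sasa import Atom, AtomSet

from conftest import WORKED_DECOMPOSITIONS, make_single_record_table

THERMO = ThermoParams()


class TestInteractionEnergy:
    @pytest.mark.parametrize("ele,vdw,expected", [
        (0.0, 0.0, 0.0),
        (-22.24, -26.08, -48.32),   # worked component means
        (5.0, -3.0, 2.0),
    ])
    def test_sum_of_electrostatic_and_vdw(self, ele, vdw, expected):
        dc = EnergyComponents(0.0, ele, vdw, 0.0, 0.0)
        assert interaction_energy(dc) == pytest.approx(expected, abs=1e-12)

    def test_series_from_table_uses_1traj_differences(self, small_ensemble):
        spec, table = small_ensemble
        series = interaction_energy_series(table, "LIG01")
        assert len(series) == spec.n_replicas * spec.n_frames
        df_c = table.select("LIG01", "complex", "complex")
        df_r = table.select("LIG01", "receptor", "complex")
        df_l = table.select("LIG01", "ligand", "complex")
        expected = ((df_c["e_ele"] + df_c["e_vdw"])
                    - (df_r["e_ele"] + df_r["e_vdw"])
                    - (df_l["e_ele"] + df_l["e_vdw"])).to_numpy()
        assert series.to_numpy() == pytest.approx(expected, abs=1e-9)


class TestVariationalEntropy:
    def test_constant_series_gives_exact_zero(self):
        res = variational_entropy([3.7] * 50, THERMO)
        assert res.minus_t_delta_s == 0.0

    def test_two_point_series_matches_direct_evaluation(self):
        # centred series {-1/2, +1/2}: kT * ln cosh(beta/2)
        expected = THERMO.kt * math.log(math.cosh(THERMO.beta / 2.0))
        res = variational_entropy([0.0, 1.0], THERMO)
        assert res.minus_t_delta_s == pytest.approx(expected, rel=1e-12)
        assert res.minus_t_delta_s == pytest.approx(0.189, abs=5e-4)

    @pytest.mark.parametrize("sigma,rel_tol", [(0.5, 0.02), (1.0, 0.03), (2.0, 0.30)])
    def test_gaussian_closed_form(self, sigma, rel_tol):
        """For Gaussian fluctuations the penalty is beta*sigma^2/2.

        The Monte-Carlo error of the exponential average grows like
        exp((beta*sigma)^2/2), so the tolerance widens with sigma."""
        series = gen_gaussian_einter(sigma, 100_000, seed=2026)
        res = variational_entropy(series, THERMO)
        assert res.minus_t_delta_s == pytest.approx(
            THERMO.beta * sigma * sigma / 2.0, rel=rel_tol)

    def test_shift_invariance(self):
        series = gen_gaussian_einter(1.0, 500, seed=5)
        a = variational_entropy(series, THERMO).minus_t_delta_s
        b = variational_entropy(series + 1234.5, THERMO).minus_t_delta_s
        assert a == pytest.approx(b, rel=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=40))
    def test_nonnegative_for_any_series(self, values):
        res = variational_entropy(values, THERMO)
        assert res.minus_t_delta_s >= 0.0

    def test_large_fluctuations_do_not_overflow(self):
        series = np.array([0.0, 5000.0, -5000.0])  # exp(beta*5000) overflows naively
        res = variational_entropy(series, THERMO)
        assert math.isfinite(res.minus_t_delta_s)

    def test_per_replica_grouping_reports_mean_and_se(self):
        groups = {1: gen_gaussian_einter(1.0, 400, seed=1),
                  2: gen_gaussian_einter(1.0, 400, seed=2),
                  3: gen_gaussian_einter(1.0, 400, seed=3)}
        res = variational_entropy(groups, THERMO, grouping="per_replica")
        singles = [variational_entropy(v, THERMO).minus_t_delta_s
                   for v in groups.values()]
        assert res.minus_t_delta_s == pytest.approx(np.mean(singles), rel=1e-12)
        assert res.se == pytest.approx(np.std(singles, ddof=1) / math.sqrt(3), rel=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            variational_entropy([1.0], THERMO)


def _weights(w, k=0.8, units="cal/(mol K)", default=None):
    return WSASWeightTable(weights=w, k=k, units=units, default_weight=default)


class TestWsas:
    def test_zero_weights_give_zero_score(self):
        atoms = gen_toy_structure("chain", n_atoms=3, spacing=3.0, radius=1.7)
        assert wsas_score(atoms, _weights({"C": 0.0})) == 0.0

    def test_isolated_atom_score_is_weighted_sphere_area(self):
        # isolated: SAS = 4*pi*3.1^2 = 120.76, BSAS = 0 -> w * SAS
        atoms = gen_toy_structure("single", radius=1.7)
        score = wsas_score(atoms, _weights({"C": 0.5}))
        assert score == pytest.approx(0.5 * 4 * math.pi * 3.1 ** 2, rel=1e-9)
        assert score == pytest.approx(60.38, abs=0.01)

    def test_fully_buried_atom_score(self):
        # bury a C (r=1.7) inside a larger zero-weight sphere: SAS=0,
        # BSAS = sphere -> contribution 0.5 * (0 - 0.8 * 120.76) = -48.31
        inner = Atom("C1", "C", np.zeros(3), 1.7, wsas_type="C")
        outer = Atom("X1", "X", np.zeros(3), 2.0, wsas_type="X")
        score = wsas_score(AtomSet([inner, outer]), _weights({"C": 0.5, "X": 0.0}))
        assert score == pytest.approx(-0.8 * 0.5 * 4 * math.pi * 3.1 ** 2, rel=1e-9)
        assert score == pytest.approx(-48.31, abs=0.01)

    def test_no_burial_change_gives_zero_entropy(self):
        receptor = gen_toy_structure("dimer", spacing=2.8, radius=1.7)
        ligand = gen_toy_structure("single", radius=1.5)
        # "complex" with the ligand 100 A away: no contact, dS = 0
        far = ligand.transformed(translation=np.array([100.0, 0.0, 0.0]))
        complex_atoms = AtomSet(receptor.atoms + far.atoms, label="complex")
        res = wsas_entropy(complex_atoms, receptor, ligand,
                           _weights({"C": 0.03}), THERMO)
        assert res.minus_t_delta_s == pytest.approx(0.0, abs=1e-6)

    def test_toy_complex_matches_per_atom_brute_force(self):
        from esmacs import bsas, sasa_lee_richards
        receptor = gen_toy_structure("dimer", spacing=3.0, radius=1.7)
        ligand = gen_toy_structure("single", radius=1.5)
        near = ligand.transformed(translation=np.array([1.5, 1.5, 0.0]))
        complex_atoms = AtomSet(receptor.atoms + near.atoms, label="complex")
        wt = _weights({"C": 0.02}, k=0.8)
        res = wsas_entropy(complex_atoms, receptor, ligand, wt, THERMO)

        def brute(atomset):
            sas = sasa_lee_richards(atomset)
            return sum(0.02 * (s - 0.8 * bsas(a, float(s)))
                       for a, s in zip(atomset.atoms, sas))
        ds_cal = brute(complex_atoms) - brute(receptor) - brute(ligand)
        expected = -THERMO.temperature * ds_cal / 1000.0  # cal -> kcal
        assert res.minus_t_delta_s == pytest.approx(expected, rel=1e-9)
        assert res.minus_t_delta_s > 0  # burial on binding costs entropy here

    def test_missing_unit_declaration_rejected(self):
        atoms = gen_toy_structure("single", radius=1.7)
        wt = WSASWeightTable(weights={"C": 0.1}, units=None)
        with pytest.raises(ConfigurationError):
            wsas_entropy(atoms, atoms, atoms, wt, THERMO)


class TestNormalModeIngestion:
    def test_empty_file_gives_empty_map(self, tmp_path):
        p = tmp_path / "nm.csv"
        p.write_text("ligand_id,minus_t_delta_s,se\n")
        assert read_nm_entropy(p) == {}

    def test_values_round_trip_and_optional_se(self, tmp_path):
        p = tmp_path / "nm.csv"
        p.write_text("ligand_id,minus_t_delta_s,se\nLDHA14,12.5,0.8\nLDHA21,15.25,\n")
        out = read_nm_entropy(p)
        assert out["LDHA14"].minus_t_delta_s == 12.5
        assert out["LDHA14"].se == 0.8
        assert out["LDHA21"].se is None

    def test_duplicate_ligand_rejected(self, tmp_path):
        p = tmp_path / "nm.csv"
        p.write_text("ligand_id,minus_t_delta_s\nA,1.0\nA,2.0\n")
        with pytest.raises(DuplicateRecordError):
            read_nm_entropy(p)


class TestApplyCorrection:
    def _result(self, ligand="LDHA14"):
        ele, vdw, pol, nonpol, _ = WORKED_DECOMPOSITIONS[ligand]
        table = make_single_record_table(ligand, ele, vdw, pol, nonpol)
        return bind_free_energy(table, ProtocolSpec("1traj"), ligand)

    def test_zero_correction_is_identity(self):
        from esmacs import EntropyResult
        res = self._result()
        corrected = apply_entropy_correction(res, EntropyResult("LDHA14", "nmode", 0.0))
        assert corrected.dg == res.dg_mean

    def test_worked_arithmetic_and_inverse(self):
        from esmacs import EntropyResult
        res = self._result()
        up = apply_entropy_correction(res, EntropyResult("LDHA14", "nmode", 5.0))
        assert up.dg == pytest.approx(-5.63, abs=1e-9)
        # subtracting the same correction returns to the original estimate
        assert up.dg - 5.0 == pytest.approx(res.dg_mean, abs=1e-12)

    def test_ligand_mismatch_rejected(self):
        from esmacs import EntropyResult
        with pytest.raises(ValueError):
            apply_entropy_correction(self._result(), EntropyResult("OTHER", "nmode", 1.0))
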