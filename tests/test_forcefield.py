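"""Energy-model unit tests: analytic pair values, scaling, decomposition."""

import numpy as np
import pytest

from hybridff.forcefield import (
    HybridPairTable,
    PairModel,
    ParameterLookupError,
    apply_scaling,
    combine_lorentz_berthelot,
    coulomb_reaction_field,
    energy_decomposition,
    lj_energy,
)
from hybridff.system import ParticleSystem, minimum_image

from conftest import make_random_system


class TestLennardJones:
    @pytest.mark.parametrize("eps,sigma", [(1.0, 0.3), (2.5, 0.47), (0.2, 0.6)])
    def test_minimum_at_two_sixth_sigma(self, eps, sigma):
        assert lj_energy(2 ** (1 / 6) * sigma, eps, sigma) == pytest.approx(-eps, rel=1e-12)

    @pytest.mark.parametrize("eps,sigma", [(1.0, 0.3), (3.0, 0.5)])
    def test_zero_crossing_at_sigma(self, eps, sigma):
        assert lj_energy(sigma, eps, sigma) == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic_value(self):
        # 4 * (0.5**12 - 0.5**6) at r = 2*sigma
        assert lj_energy(0.6, 1.0, 0.3) == pytest.approx(-0.0615234375, abs=1e-15)

    def test_zero_epsilon_gives_zero(self):
        assert lj_energy(0.4, 0.0, 0.3) == 0.0

    def test_attractive_between_sigma_and_cutoff(self):
        r = np.linspace(0.31, 1.2, 50)
        assert np.all(lj_energy(r, 1.0, 0.3) < 0)

    @pytest.mark.parametrize("r,sigma", [(0.0, 0.3), (-1.0, 0.3), (0.5, 0.0), (0.5, -0.2)])
    def test_domain_errors(self, r, sigma):
        with pytest.raises(ValueError):
            lj_energy(r, 1.0, sigma)


class TestReactionField:
    def test_zero_charge_gives_zero(self):
        r = np.linspace(0.1, 1.2, 20)
        assert np.all(coulomb_reaction_field(r, 0.0, 1.0) == 0.0)

    def test_symmetric_under_charge_swap(self):
        a = coulomb_reaction_field(0.5, 1.0, -2.0)
        b = coulomb_reaction_field(0.5, -2.0, 1.0)
        assert a == b

    def test_shifted_form_vanishes_at_cutoff(self):
        assert coulomb_reaction_field(1.2, 1.0, 1.0, cutoff=1.2) == pytest.approx(0.0, abs=1e-12)

    def test_zero_beyond_cutoff_by_contract(self):
        assert coulomb_reaction_field(1.5, 1.0, 1.0, cutoff=1.2) == 0.0

    def test_continuous_in_r(self):
        r = np.linspace(0.3, 1.19, 200)
        u = coulomb_reaction_field(r, 1.0, -1.0)
        assert np.all(np.abs(np.diff(u)) < 1.0)

    def test_nonpositive_r_is_domain_error(self):
        with pytest.raises(ValueError):
            coulomb_reaction_field(0.0, 1.0, 1.0)


class TestCombiningRule:
    def test_identity_on_self_pair(self):
        assert combine_lorentz_berthelot(1.0, 0.3, 1.0, 0.3) == (1.0, 0.3)

    def test_geometric_and_arithmetic_means(self):
        assert combine_lorentz_berthelot(1.0, 0.2, 4.0, 0.4) == pytest.approx((2.0, 0.3))

    def test_zero_epsilon_dominates(self):
        eps, _ = combine_lorentz_berthelot(0.0, 0.3, 5.0, 0.5)
        assert eps == 0.0


class TestScalingLayer:
    def make_table(self, eps_cg, eps_dual):
        return HybridPairTable(
            pairs={("A", "A"): (1.0, 0.4), ("B", "B"): (2.0, 0.5), ("A", "B"): (1.5, 0.45)},
            eps_cg=eps_cg,
            eps_dual=eps_dual,
        )

    def test_unity_factors_are_identity(self):
        table = self.make_table(1.0, 1.0)
        eff = apply_scaling(table, {"A": "UA", "B": "CG"})
        assert eff == table.pairs

    def test_cg_pairs_scaled_by_eps_cg(self):
        table = self.make_table(0.2, 1.0)
        eff = apply_scaling(table, {"A": "CG", "B": "CG"})
        for key, (eps, sigma) in table.pairs.items():
            assert eff[key] == (pytest.approx(0.2 * eps), sigma)

    def test_only_mixed_pairs_scaled_by_eps_dual(self):
        table = self.make_table(1.0, 0.8)
        eff = apply_scaling(table, {"A": "UA", "B": "CG"})
        assert eff[("A", "A")] == (1.0, 0.4)  # UA-UA untouched
        assert eff[("B", "B")] == (2.0, 0.5)  # CG-CG untouched (eps_cg=1)
        assert eff[("A", "B")] == (pytest.approx(0.8 * 1.5), 0.45)

    def test_sigma_never_modified(self):
        table = self.make_table(0.2, 0.8)
        for res in ({"A": "CG", "B": "CG"}, {"A": "UA", "B": "CG"}):
            eff = apply_scaling(table, res)
            for key in table.pairs:
                assert eff[key][1] == table.pairs[key][1]

    @pytest.mark.parametrize("bad", [0.0, -0.5, 2.5])
    def test_factor_sanity_bounds(self, bad):
        with pytest.raises(ValueError):
            self.make_table(bad, 0.8)

    def test_symmetric_lookup(self):
        table = self.make_table(1.0, 1.0)
        assert table.lookup("A", "B") == table.lookup("B", "A")


def brute_force_decomposition(system, table):
    """Independent O(N^2) double-loop oracle over public pair functions."""
    from hybridff.forcefield import reaction_field_constants

    terms = {"UA-UA": 0.0, "CG-CG": 0.0, "UA-CG": 0.0}
    n = len(system)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in system.exclusions:
                continue
            d = minimum_image(system.positions[i] - system.positions[j], system.box)
            r = float(np.linalg.norm(d))
            if r >= table.cutoff:
                continue
            ri, rj = system.resolution[i], system.resolution[j]
            key = "UA-UA" if (ri == rj == "UA") else ("CG-CG" if ri == rj == "CG" else "UA-CG")
            eps, sigma = table.effective_pair(system.types[i], system.types[j], ri, rj)
            u = lj_energy(r, eps, sigma)
            if table.shift_lj:
                u -= lj_energy(table.cutoff, eps, sigma)
            qq = system.charges[i] * system.charges[j] * table.coulomb_scale(ri, rj)
            if qq != 0.0:
                u += coulomb_reaction_field(r, qq, 1.0, table.cutoff, table.eps_r, table.eps_rf)
            terms[key] += u
    return terms


class TestEnergyDecomposition:
    def test_pure_ua_system_has_only_ua_term(self, pair_table):
        system = make_random_system(n=10, seed=3)
        system.resolution[:] = "UA"
        dec = energy_decomposition(system, pair_table)
        assert dec.u_cg == 0.0 and dec.u_cross == 0.0
        assert dec.u_ua != 0.0

    def test_single_mixed_pair_is_all_cross(self, pair_table):
        system = ParticleSystem.create(
            [[0.0, 0, 0], [0.5, 0, 0]],
            resolution=np.asarray(["UA", "CG"], dtype=object),
            types=np.asarray(["LEU", "VAL"], dtype=object),
            masses=72.0,
        )
        dec = energy_decomposition(system, pair_table)
        assert dec.u_total == dec.u_cross != 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_oracle(self, pair_table, seed):
        system = make_random_system(n=30, seed=seed)
        dec = energy_decomposition(system, pair_table)
        oracle = brute_force_decomposition(system, pair_table)
        assert dec.u_ua == pytest.approx(oracle["UA-UA"], rel=1e-9, abs=1e-12)
        assert dec.u_cg == pytest.approx(oracle["CG-CG"], rel=1e-9, abs=1e-12)
        assert dec.u_cross == pytest.approx(oracle["UA-CG"], rel=1e-9, abs=1e-12)

    def test_decomposition_identity(self, pair_table, random_system):
        dec = energy_decomposition(random_system, pair_table)
        total = dec.u_ua + dec.u_cg + dec.u_cross
        assert dec.u_total == pytest.approx(total, rel=1e-12)
        assert dec.u_ua == dec.u_ua_lj + dec.u_ua_coulomb

    def test_cg_lj_energy_linear_in_eps_cg(self, random_system):
        from dataclasses import replace

        from hybridff.fixtures import default_pair_table

        base = default_pair_table(eps_cg=1.0, eps_dual=1.0)
        u1 = energy_decomposition(random_system, base).u_cg_lj
        for factor in (0.2, 0.5, 1.7):
            scaled = replace(base, pairs=dict(base.pairs), eps_cg=factor)
            assert energy_decomposition(random_system, scaled).u_cg_lj == pytest.approx(
                factor * u1, rel=1e-9
            )

    def test_translation_invariance(self, pair_table, random_system):
        ref = energy_decomposition(random_system, pair_table).u_total
        shifted = random_system.with_positions(random_system.positions + [1.3, -0.7, 2.9])
        assert energy_decomposition(shifted, pair_table).u_total == pytest.approx(ref, rel=1e-9)

    def test_reordering_invariance(self, pair_table):
        system = make_random_system(n=20, seed=5)
        ref = energy_decomposition(system, pair_table).u_total
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(system))
        permuted = ParticleSystem(
            positions=system.positions[perm],
            resolution=system.resolution[perm],
            types=system.types[perm],
            charges=system.charges[perm],
            masses=system.masses[perm],
            chains=system.chains[perm],
            resids=system.resids[perm],
            resnames=system.resnames[perm],
            box=system.box,
        )
        assert energy_decomposition(permuted, pair_table).u_total == pytest.approx(ref, rel=1e-9)

    def test_minimum_image_against_27_image_oracle(self, pair_table):
        system = make_random_system(n=12, seed=9, box=2.6)
        model = PairModel(system, pair_table)
        shifts = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
        ) * system.box
        total = 0.0
        for i in range(len(system)):
            for j in range(i + 1, len(system)):
                d = system.positions[i] - system.positions[j] + shifts
                r = np.linalg.norm(d, axis=1).min()
                if r >= pair_table.cutoff:
                    continue
                ri, rj = system.resolution[i], system.resolution[j]
                eps, sigma = pair_table.effective_pair(system.types[i], system.types[j], ri, rj)
                u = lj_energy(r, eps, sigma) - lj_energy(pair_table.cutoff, eps, sigma)
                qq = system.charges[i] * system.charges[j]
                if qq != 0.0:
                    u += coulomb_reaction_field(r, qq, 1.0, pair_table.cutoff, pair_table.eps_r)
                total += u
        assert model.nonbonded_energy() == pytest.approx(total, rel=1e-9, abs=1e-12)

    def test_unknown_type_label_names_the_label(self, pair_table):
        system = make_random_system(n=5, seed=1)
        system.types[2] = "MYSTERY"
        with pytest.raises(ParameterLookupError, match="MYSTERY"):
            energy_decomposition(system, pair_table)


class TestPairTableAliases:
    def test_alias_resolves_to_target_parameters(self, pair_table):
        assert pair_table.lookup("BB_P5", "LEU") == pair_table.lookup("ASN", "LEU")

    def test_missing_pair_falls_back_to_combination(self, pair_table):
        eps, sigma = pair_table.lookup("LEU", "TRP")
        e1, s1 = pair_table.lookup("LEU", "LEU")
        e2, s2 = pair_table.lookup("TRP", "TRP")
        assert (eps, sigma) == combine_lorentz_berthelot(e1, s1, e2, s2)
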