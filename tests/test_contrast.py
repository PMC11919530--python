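"""SLD construction, isotopic substitution, solvent matching, roughness smearing."""

import numpy as np
import pytest
from scipy.special import ndtr

from mononr.contrast import (
    ContrastScheme,
    ScatteringLengthTable,
    SLDProfile,
    pure_water_sld,
    sld_from_nd,
    smear_profile,
    solve_acmw_fraction,
    standard_schemes,
)
from mononr.density import DensityProfile


def profile_from(densities, water, area=4900.0, bin_width=0.5):
    n = len(water)
    z = (np.arange(n) + 0.5) * bin_width
    dens = {k: np.asarray(v, float) for k, v in densities.items()}
    return DensityProfile(
        z=z, densities=dens, water=np.asarray(water, float),
        area=area, n_frames=1, water_is_fraction=True,
    )


class TestSldFromNd:
    def test_all_zero_gives_zero(self):
        p = profile_from({"C": np.zeros(10)}, np.zeros(10))
        scheme = ContrastScheme("D83-D2O", True, True, "D2O")
        sld = sld_from_nd(p, scheme, solvent_sld=6.36e-6)
        assert np.all(sld.rho == 0.0)

    def test_single_carbon_density(self):
        """n_C = 1e-2 Å⁻³ → ρ = 1e-2 · 6.646 fm · 1e-5 Å/fm = 6.646e-7 Å⁻²."""
        dens = np.zeros(10)
        dens[3] = 1.0e-2
        p = profile_from({"C": dens}, np.zeros(10))
        sld = sld_from_nd(p, ContrastScheme("H-D2O", False, False, "D2O"), solvent_sld=0.0)
        assert sld.rho[10 - 1 - 3] == pytest.approx(6.646e-7, rel=1e-12)

    def test_pure_d2o_slab_matches_quoted_sld(self):
        """Bulk D₂O at 1.105 g/cm³ gives ρ ≈ 6.35e-6 Å⁻² (within 0.5%)."""
        rho_d2o = pure_water_sld(heavy=True)
        assert rho_d2o == pytest.approx(6.35e-6, rel=5e-3)
        p = profile_from({"C": np.zeros(10)}, np.ones(10))
        sld = sld_from_nd(p, ContrastScheme("H-D2O", False, False, "D2O"),
                          solvent_sld=rho_d2o)
        assert np.allclose(sld.rho, rho_d2o)

    def test_linearity_in_density(self):
        rng = np.random.default_rng(12)
        d1 = {"C": rng.uniform(0, 0.03, 20), "H_tail": rng.uniform(0, 0.05, 20)}
        d2 = {"C": rng.uniform(0, 0.03, 20), "H_tail": rng.uniform(0, 0.05, 20)}
        dsum = {k: d1[k] + d2[k] for k in d1}
        scheme = ContrastScheme("D70-ACMW", False, True, "ACMW")
        s1 = sld_from_nd(profile_from(d1, np.zeros(20)), scheme, solvent_sld=1e-7)
        s2 = sld_from_nd(profile_from(d2, np.zeros(20)), scheme, solvent_sld=1e-7)
        ssum = sld_from_nd(profile_from(dsum, np.zeros(20)), scheme, solvent_sld=2e-7)
        assert np.allclose(s1.rho + s2.rho, ssum.rho, rtol=1e-12)

    def test_deuteration_difference_is_substituted_pools(self, monolayer_profile):
        """D83 − H SLD = (b_D − b_H)·(n_Hhead + n_Htail), pointwise."""
        table = ScatteringLengthTable()
        d83 = sld_from_nd(monolayer_profile,
                          ContrastScheme("D83-D2O", True, True, "D2O"), table, 6.36e-6)
        h = sld_from_nd(monolayer_profile,
                        ContrastScheme("H-D2O", False, False, "D2O"), table, 6.36e-6)
        pools = (monolayer_profile.densities["H_head"]
                 + monolayer_profile.densities["H_tail"])[::-1]
        db = table.b_angstrom("D") - table.b_angstrom("H")
        assert np.allclose(d83.rho - h.rho, db * pools, rtol=1e-12, atol=1e-18)

    def test_backbone_hydrogens_never_substituted(self, monolayer_profile):
        """Full deuteration leaves the backbone pool at b(H)."""
        table = ScatteringLengthTable()
        d83 = sld_from_nd(monolayer_profile,
                          ContrastScheme("D83-D2O", True, True, "D2O"), table, 0.0)
        # reconstruct by hand with explicit substitution
        expect = np.zeros_like(monolayer_profile.z)
        sub = {"H_head": "D", "H_tail": "D", "H_backbone": "H"}
        for sp, dens in monolayer_profile.densities.items():
            expect += dens * table.b_angstrom(sub.get(sp, sp))
        assert np.allclose(d83.rho, expect[::-1], rtol=1e-12)

    def test_far_field_limits(self, monolayer_profile):
        """Air end → fronting (0); bulk water end → backing (solvent SLD)."""
        sld = sld_from_nd(monolayer_profile,
                          ContrastScheme("D70-D2O", False, True, "D2O"),
                          solvent_sld=6.36e-6)
        assert sld.rho[0] == pytest.approx(0.0, abs=1e-15)
        # the bulk-water bin carries the profile's counting noise (~0.1%)
        assert sld.rho[-1] == pytest.approx(6.36e-6, rel=3e-3)

    def test_missing_species_rejected(self):
        table = ScatteringLengthTable({"H": -3.739, "D": 6.671, "C": 6.646})
        p = profile_from({"P": np.ones(6) * 1e-3}, np.zeros(6))
        with pytest.raises(KeyError, match="'P' missing"):
            sld_from_nd(p, ContrastScheme("H-D2O", False, False, "D2O"), table, 0.0)

    def test_requires_water_fraction(self):
        p = profile_from({"C": np.zeros(6)}, np.zeros(6))
        p.water_is_fraction = False
        with pytest.raises(ValueError, match="volume fraction"):
            sld_from_nd(p, ContrastScheme("H-D2O", False, False, "D2O"), solvent_sld=0.0)


class TestSchemes:
    def test_seven_standard_contrasts(self):
        schemes = standard_schemes()
        assert len(schemes) == 7
        names = {s.name for s in schemes}
        assert names == {"D83-D2O", "D83-ACMW", "D70-D2O", "D70-ACMW",
                         "D13-D2O", "D13-ACMW", "H-D2O"}
        assert sum(s.solvent == "ACMW" for s in schemes) == 3

    def test_unknown_solvent_rejected(self):
        with pytest.raises(ValueError, match="solvent"):
            ContrastScheme("X", False, False, "H2O")


class TestACMW:
    def test_match_point_is_8_percent(self):
        """Zero-SLD mixture at 8.1% D₂O v/v (to one decimal)."""
        phi = solve_acmw_fraction()
        assert round(100 * phi, 1) == 8.1

    def test_zero_h2o_sld_gives_zero_fraction(self):
        # a table where 2·b(H) + b(O) = 0 makes pure H₂O already matched
        table = ScatteringLengthTable(
            {"H": -2.9015, "D": 6.671, "O": 5.803}
        )
        assert solve_acmw_fraction(table) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_slds_give_half(self):
        # equal number densities (densities ∝ molar masses) and b(D) = −b(H),
        # b(O) = 0 → ρ_D2O = −ρ_H2O exactly
        from mononr.contrast import D2O_MOLAR_MASS, H2O_MOLAR_MASS

        table = ScatteringLengthTable({"H": -3.739, "D": 3.739, "O": 0.0})
        phi = solve_acmw_fraction(table, densities=(H2O_MOLAR_MASS, D2O_MOLAR_MASS))
        assert phi == pytest.approx(0.5, rel=1e-12)

    def test_same_sign_rejected(self):
        table = ScatteringLengthTable({"H": -1e-4, "D": 6.671, "O": 5.803})
        with pytest.raises(ValueError, match="same sign"):
            # both positive: H₂O SLD ≈ b(O) > 0
            solve_acmw_fraction(table)


class TestSmearing:
    def test_zero_sigma_is_identity(self):
        z = np.arange(50) * 0.5
        sld = SLDProfile(z, np.sin(z) * 1e-6 + 2e-6, fronting=2e-6, backing=2e-6)
        out = smear_profile(sld, 0.0)
        assert np.array_equal(out.rho, sld.rho)
        assert np.array_equal(out.z, sld.z)

    @pytest.mark.parametrize("sigma", [1.0, 3.0, 5.0])
    def test_step_becomes_normal_cdf(self, sigma):
        """A sharp step smears to ρ₀·Φ(z/σ) within 1e-4·ρ₀ on a 0.5 Å grid."""
        rho0 = 6.0e-6
        z = np.arange(400) * 0.5
        step_at = z[200]
        rho = np.where(z >= step_at, rho0, 0.0)
        sld = SLDProfile(z, rho, fronting=0.0, backing=rho0)
        out = smear_profile(sld, sigma)
        # step edge sits at the lower edge of bin 200, i.e. z = 99.75 + 0.25
        expected = rho0 * ndtr((out.z - (step_at - 0.25)) / sigma)
        assert np.max(np.abs(out.rho - expected)) < 1e-4 * rho0

    @pytest.mark.parametrize("sigma", [0.7, 2.5])
    def test_area_conserved(self, sigma):
        """∫(ρ − baseline) dz is invariant under smearing."""
        z = np.arange(300) * 0.5
        baseline = 1e-6
        bump = baseline + 4e-6 * np.exp(-0.5 * ((z - 75) / 5) ** 2)
        sld = SLDProfile(z, bump, fronting=baseline, backing=baseline)
        out = smear_profile(sld, sigma)
        area_in = np.sum(sld.rho - baseline) * 0.5
        area_out = np.sum(out.rho - baseline) * 0.5
        assert area_out == pytest.approx(area_in, rel=1e-6)

    def test_commutes_with_constant_baseline(self):
        z = np.arange(200) * 0.5
        rho = 3e-6 * np.exp(-0.5 * ((z - 50) / 8) ** 2)
        base = 1.7e-6
        a = smear_profile(SLDProfile(z, rho, 0.0, 0.0), 2.0)
        b = smear_profile(SLDProfile(z, rho + base, base, base), 2.0)
        assert np.allclose(a.rho + base, b.rho, rtol=1e-12, atol=1e-18)

    def test_negative_sigma_rejected(self):
        sld = SLDProfile(np.arange(10) * 0.5, np.zeros(10))
        with pytest.raises(ValueError, match="non-negative"):
            smear_profile(sld, -1.0)


class TestTable:
    def test_sign_conventions_enforced(self):
        with pytest.raises(ValueError, match="negative"):
            ScatteringLengthTable({"H": 3.739, "D": 6.671})
        with pytest.raises(ValueError, match="positive"):
            ScatteringLengthTable({"H": -3.739, "D": -6.671})

    def test_shipped_table_round_trip(self, tmp_path):
        table = ScatteringLengthTable.shipped()
        assert table.b_fm("C") == pytest.approx(6.646)
        path = tmp_path / "table.txt"
        table.write(path)
        back = ScatteringLengthTable.read(path)
        for sym in "HDCNOP":
            assert back.b_fm(sym) == table.b_fm(sym)
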