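"""Intensity derivation, plane averaging (with a Monte-Carlo oracle) and
summaries."""

import numpy as np
import pytest

import sonowell as sw
from sonowell.postprocess import PlaneSpec, plane_average

WATER = sw.MediumProperties()


def constant_field(value, study, acoustics):
    mesh = sw.build_mesh(study.geometry, 1e6, WATER.sound_speed)
    return sw.PressureField(
        mesh=mesh,
        p=np.full(mesh.n_nodes, value, dtype=complex),
        acoustics=acoustics,
        drive=study.drives[0],
    )


class TestParticleVelocity:
    def test_constant_pressure_gives_zero_velocity(self, study, acoustics):
        field = constant_field(1000.0, study, acoustics)
        vr, vz = sw.particle_velocity(field)
        # zero up to roundoff of the shape-function derivative sums
        assert np.abs(vr).max() < 1e-12 and np.abs(vz).max() < 1e-12

    def test_travelling_wave_relation(self):
        """For p = P exp(-ikz) in a lossless medium, v_z = p/(rho c)."""
        lossless = sw.MediumProperties(dynamic_viscosity=0.0, bulk_viscosity=0.0)
        ac = sw.complex_acoustics(lossless, 1e6)
        drive = sw.SourceDrive.from_practical(0.45, medium=lossless)
        col = sw.analytic_1d_column(
            ac, drive, lossless.characteristic_impedance, 10.78e-3
        )
        z = np.linspace(0, 10.78e-3, 64)
        v_expected = col.pressure(z) / lossless.characteristic_impedance
        v_from_dp = -col.dpressure_dz(z) / (1j * ac.angular_frequency * ac.complex_density)
        assert np.allclose(v_from_dp, v_expected, rtol=1e-12)

    def test_fem_velocity_matches_analytic_derivative(
        self, rigid_fields, column_air
    ):
        """FEM-recovered v agrees with the differentiated closed form, <1% L2."""
        field = rigid_fields[2.0]
        intens = sw.intensity(field)
        z = np.linspace(0, field.mesh.height, 512)
        rho = np.full_like(z, field.mesh.radius / 3)
        _, vz = intens.velocity(rho, z)
        ac = field.acoustics
        vz_an = -column_air.dpressure_dz(z) / (
            1j * ac.angular_frequency * ac.complex_density
        )
        err = np.linalg.norm(vz - vz_an) / np.linalg.norm(vz_an)
        assert err < 1e-2


class TestIntensity:
    def test_rigid_standing_wave_carries_no_flux(self):
        """A lossless column closed by a rigid cap transports no net energy."""
        lossless = sw.MediumProperties(dynamic_viscosity=0.0, bulk_viscosity=0.0)
        ac = sw.complex_acoustics(lossless, 1e6)
        drive = sw.SourceDrive.from_practical(0.45, medium=lossless)
        height = 10.3e-3  # away from a closed-column resonance
        col = sw.analytic_1d_column(ac, drive, np.inf, height)
        z = np.linspace(0, height, 256)
        p = col.pressure(z)
        v = -col.dpressure_dz(z) / (1j * ac.angular_frequency * ac.complex_density)
        i_z = 0.5 * np.real(p * np.conj(v))
        assert np.abs(i_z).max() < 1e-10 * (np.abs(p) * np.abs(v)).max()

    def test_travelling_wave_intensity_closed_form(self):
        lossless = sw.MediumProperties(dynamic_viscosity=0.0, bulk_viscosity=0.0)
        ac = sw.complex_acoustics(lossless, 1e6)
        drive = sw.SourceDrive.from_practical(0.45, medium=lossless)
        col = sw.analytic_1d_column(
            ac, drive, lossless.characteristic_impedance, 10.78e-3
        )
        z = np.linspace(0, 10.78e-3, 64)
        p = col.pressure(z)
        v = -col.dpressure_dz(z) / (1j * ac.angular_frequency * ac.complex_density)
        i_z = 0.5 * np.real(p * np.conj(v))
        expected = np.abs(p) ** 2 / (2 * lossless.characteristic_impedance)
        assert np.allclose(i_z, expected, rtol=1e-12)

    def test_matched_column_delivers_transmitted_intensity(self, study, acoustics):
        """|I| at the driven base of a matched column equals I_0 within viscous
        corrections."""
        drive = study.drives[1]
        col = sw.analytic_1d_column(
            acoustics, drive, WATER.characteristic_impedance,
            study.geometry.solution_height,
        )
        p0 = col.pressure(0.0)
        v0 = -col.dpressure_dz(0.0) / (
            1j * acoustics.angular_frequency * acoustics.complex_density
        )
        i0 = 0.5 * np.real(p0 * np.conj(v0))
        assert i0 == pytest.approx(drive.transmitted_intensity, rel=1e-3)


class TestPlaneAverage:
    @pytest.mark.parametrize(
        "plane",
        [
            PlaneSpec("vertical", 0.0),
            PlaneSpec("vertical", 3.975e-3),
            PlaneSpec("horizontal", 2.5e-3),
            PlaneSpec("volume"),
        ],
    )
    def test_constant_field_averages_to_constant(self, study, plane):
        avg = plane_average(lambda r, z: np.full_like(r, 7.25), plane, study.geometry)
        assert avg == pytest.approx(7.25, rel=1e-12)

    def test_central_plane_of_linear_radial_field(self, study):
        """f = rho/r averaged over the central plane is 1/2 (mean of |y|/r)."""
        r = study.geometry.basis_radius
        avg = plane_average(
            lambda rho, z: rho / r, PlaneSpec("vertical", 0.0), study.geometry
        )
        assert avg == pytest.approx(0.5, rel=1e-10)

    def test_agrees_with_monte_carlo_oracle(self, study, fields_ref1, rng):
        """Quadrature averages match rejection-sampling MC within 3 SE."""
        field = fields_ref1[0.45]
        amp = field.amplitude
        geometry = study.geometry
        r, h = geometry.basis_radius, geometry.solution_height
        n = 1_000_000

        def mc_check(plane, sampler):
            pts_r, pts_z = sampler(n)
            vals = amp(pts_r, pts_z)
            mc, se = vals.mean(), vals.std(ddof=1) / np.sqrt(n)
            quad = plane_average(amp, plane, geometry)
            assert abs(quad - mc) < 3 * se

        x0 = r / 2
        half = np.sqrt(r**2 - x0**2)
        mc_check(
            PlaneSpec("vertical", x0),
            lambda n: (
                np.sqrt(x0**2 + (rng.uniform(-half, half, n)) ** 2),
                rng.uniform(0, h, n),
            ),
        )
        mc_check(
            PlaneSpec("horizontal", 2.5e-3),
            lambda n: (
                r * np.sqrt(rng.uniform(0, 1, n)),
                np.full(n, 2.5e-3),
            ),
        )
        mc_check(
            PlaneSpec("volume"),
            lambda n: (
                r * np.sqrt(rng.uniform(0, 1, n)),
                rng.uniform(0, h, n),
            ),
        )

    def test_resolution_doubling_self_check(self, study, fields_ref1):
        field = fields_ref1[0.45]
        spec = PlaneSpec("vertical", 0.0)
        a = plane_average(field.amplitude, spec, study.geometry, resolution=320)
        b = plane_average(field.amplitude, spec, study.geometry, resolution=640)
        assert a == pytest.approx(b, rel=1e-3)

    def test_plane_outside_domain_rejected(self, study):
        with pytest.raises(ValueError):
            plane_average(
                lambda r, z: r, PlaneSpec("horizontal", 1.0), study.geometry
            )
        with pytest.raises(ValueError):
            PlaneSpec("diagonal")


class TestSummarize:
    def test_radial_monotonicity_of_plane_averages(self, summaries_ref1):
        """central >= r/2 >= wall for both |p| and |I| at every power."""
        for summary in summaries_ref1.values():
            for avg in (summary.pressure_avg, summary.intensity_avg):
                assert avg["central"] >= avg["half_radius"] >= avg["wall"]

    def test_volume_average_below_input_power(self, summaries_ref1):
        for power, summary in summaries_ref1.items():
            assert summary.intensity_avg["volume"] < power * 1e4

    def test_summaries_scale_linearly(self, summaries_ref1):
        """Intensity summaries scale as the power ratio, pressures as its root."""
        s30, s45 = summaries_ref1[0.30], summaries_ref1[0.45]
        for key in ("central", "half_radius", "wall", "volume"):
            assert s45.intensity_avg[key] / s30.intensity_avg[key] == pytest.approx(
                1.5, rel=1e-9
            )
            assert s45.pressure_avg[key] / s30.pressure_avg[key] == pytest.approx(
                np.sqrt(1.5), rel=1e-9
            )
        assert s45.peak_intensity / s30.peak_intensity == pytest.approx(1.5, rel=1e-9)

    def test_zero_drive_summary_is_zero(self, study, acoustics):
        field = constant_field(0.0, study, acoustics)
        summary = sw.summarize(field, sw.intensity(field), study.geometry)
        assert summary.peak_intensity == 0.0
        assert all(v == 0.0 for v in summary.pressure_avg.values())

    def test_mesh_convergence_of_reported_averages(
        self, study, field_ref2, summaries_ref1
    ):
        """Plane averages are Cauchy in refinement and the production (lambda/8)
        grid sits within a few percent of the refined values."""
        s1 = summaries_ref1[0.45]
        s2 = sw.summarize(field_ref2, sw.intensity(field_ref2), study.geometry)
        f3 = sw.simulate(
            study.drives[1], medium=study.medium, geometry=study.geometry,
            config=sw.SolverConfig(refinement=3.0),
        )
        s3 = sw.summarize(f3, sw.intensity(f3), study.geometry)
        for avgs in ("intensity_avg", "pressure_avg"):
            for key in ("central", "half_radius", "wall", "volume"):
                v1 = getattr(s1, avgs)[key]
                v2 = getattr(s2, avgs)[key]
                v3 = getattr(s3, avgs)[key]
                step12 = abs(v2 - v1) / v2
                step23 = abs(v3 - v2) / v3
                assert step12 < 5e-2
                assert step23 < step12 / 3

    def test_table_frame_layout(self, summaries_ref1):
        frame = summaries_ref1[0.45].to_frame()
        assert "0.45 W/cm2" in frame.columns
        assert frame.loc["density_avg_central_W_per_cm2"].iloc[0] > 0


class TestEnergyBalance:
    def test_terms_are_physical(self, fields_ref1):
        eb = sw.energy_balance(fields_ref1[0.45])
        assert eb.power_in_bottom > 0
        assert eb.power_out_lateral > 0
        assert eb.power_out_top > 0
        assert eb.dissipated > 0

    def test_imbalance_shrinks_under_refinement(self, fields_ref1, field_ref2):
        e1 = sw.energy_balance(fields_ref1[0.45]).relative_imbalance
        e2 = sw.energy_balance(field_ref2).relative_imbalance
        assert e2 < e1 / 2
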