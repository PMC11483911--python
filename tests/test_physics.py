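"""Unit and property tests for the closed-form scaling model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdicekit import physics
from cdicekit.config import UL_PER_MIN


class TestWorkedExamples:
    """Frozen hand-checked values for every scaling relation."""

    @pytest.mark.parametrize(
        "rpm, r_i, expected",
        [(1000, 0.01, 1.0472), (0, 0.01, 0.0), (1900, 0.01, 1.98968)],
    )
    def test_tangential_speed(self, rpm, r_i, expected):
        assert physics.tangential_speed(rpm, r_i) == pytest.approx(expected, rel=1e-4)

    def test_capillary_number(self):
        u = physics.tangential_speed(1900, 0.01)
        assert physics.capillary_number(4e-3, u, 1e-3) == pytest.approx(7.9587, rel=1e-4)
        # strong tension suppresses Ca
        assert physics.capillary_number(4e-3, u, 1e3) == pytest.approx(0.0, abs=1e-5)

    def test_capillary_number_spans_published_band(self):
        """Over the explored rpm/viscosity/tension grid, Ca covers ~0.5-10."""
        cas = [
            physics.capillary_number(mu, physics.tangential_speed(rpm, 0.01), gamma)
            for rpm in (1000, 1900, 2700)
            for mu in (4e-3, 5e-3)
            for gamma in (1e-3, 1e-2)
        ]
        assert min(cas) < 0.5 and max(cas) > 10.0
        assert min(cas) > 0.1 and max(cas) < 20.0

    def test_reynolds_number(self):
        u19 = physics.tangential_speed(1900, 0.01)
        u27 = physics.tangential_speed(2700, 0.01)
        assert physics.reynolds_number(934, u19, 5e-4, 4e-3) == pytest.approx(232.3, rel=1e-3)
        assert physics.reynolds_number(934, 0.0, 5e-4, 4e-3) == 0.0
        assert physics.reynolds_number(934, u27, 5e-4, 4e-3) == pytest.approx(330.1, rel=1e-3)

    @pytest.mark.parametrize(
        "re_d, label",
        [
            (0, "steady"),
            (46.9, "steady"),
            (47, "vortex_shedding"),
            (149.9, "vortex_shedding"),
            (150, "three_dimensional"),
            (232, "three_dimensional"),
        ],
    )
    def test_wake_regime(self, re_d, label):
        assert physics.wake_regime(re_d) == label

    def test_critical_jetting_flow_rate(self):
        q = physics.critical_jetting_flow_rate(1e-4, 1e-3, 1018)
        assert q == pytest.approx(2.2e-9, rel=0.01)
        assert q / UL_PER_MIN == pytest.approx(132.2, rel=0.01)
        assert physics.critical_jetting_flow_rate(1e-4, 0.0, 1018) == 0.0

    def test_breakup_regime(self):
        q_op = 25 * UL_PER_MIN
        q_crit = 132 * UL_PER_MIN
        assert physics.breakup_regime(q_op, q_crit, 5.0) == "shear_unstable"
        assert physics.breakup_regime(2 * q_crit, q_crit, 5.0) == "jetting"
        assert physics.breakup_regime(q_op, q_crit, 0.01) == "dripping"

    def test_predicted_droplet_diameter(self):
        """The a/D ~ (6 Ca)^-1 balance reproduces ~100 um at 1900 rpm and
        ~200 um at 1000 rpm for the oil/tension values of that estimate."""
        d_cap, mu, gamma = 363e-6, 4.5e-3, 7e-3
        ca19 = physics.capillary_number(mu, physics.tangential_speed(1900, 0.01), gamma)
        ca10 = physics.capillary_number(mu, physics.tangential_speed(1000, 0.01), gamma)
        d19 = physics.predicted_droplet_diameter(d_cap, ca19)
        d10 = physics.predicted_droplet_diameter(d_cap, ca10)
        assert d19 == pytest.approx(94.6e-6, rel=0.01)
        assert d10 == pytest.approx(179.7e-6, rel=0.01)
        # diameter ~ 1/Omega: doubling the rate halves the prediction
        assert physics.predicted_droplet_diameter(d_cap, 2 * ca19) == pytest.approx(
            d19 / 2, rel=1e-12
        )

    def test_radial_migration_speed(self):
        u_r = physics.radial_migration_speed(123.4, 50e-6, 1900, 0.01, 4e-3)
        assert u_r == pytest.approx(3.05e-2, rel=0.01)
        assert physics.radial_migration_speed(0.0, 50e-6, 1900, 0.01, 4e-3) == 0.0
        # frozen from the formula directly (independent hand evaluation)
        u_r2 = physics.radial_migration_speed(84.3, 35e-6, 1900, 0.01, 4e-3)
        assert u_r2 == pytest.approx(1.022e-2, rel=0.01)

    def test_wake_shear_analysis(self):
        shear, ca_shear, gamma_lim = physics.wake_shear_analysis(
            1900, 0.01, (0.5e-3, 5e-3), 4e-3, 5e-6, tension=1e-3
        )
        assert shear[0] == pytest.approx(398.0, rel=0.01)  # l = 5 mm
        assert shear[1] == pytest.approx(3979.0, rel=0.01)  # l = 0.5 mm
        assert gamma_lim[0] == pytest.approx(7.96e-6, rel=0.01)
        # the tension needed to shear droplets to GUV size is in the
        # 1e-6..1e-5 N/m decade, far below lipid-monolayer tensions
        assert 1e-6 < gamma_lim[0] < 1e-5
        assert ca_shear[0] == pytest.approx(4e-3 * 398 * 5e-6 / 1e-3, rel=0.01)
        # gamma_lim is linear in the droplet radius
        _, _, gl0 = physics.wake_shear_analysis(1900, 0.01, (0.5e-3, 5e-3), 4e-3, 0.0)
        assert gl0 == (0.0, 0.0)

    def test_bond_number(self):
        bo = physics.bond_number(123.4, 1900, 0.015, 100e-6, 1e-3)
        assert bo == pytest.approx(0.733, rel=0.01)
        assert 0.1 < bo < 10  # order one: large droplets deform the interface
        assert physics.bond_number(123.4, 1900, 0.015, 0.0, 1e-3) == 0.0
        assert physics.bond_number(123.4, 1900, 0.015, 400e-6, 1e-3) == pytest.approx(
            16 * bo, rel=1e-9
        )

    def test_breakthrough_tension(self):
        g_max = physics.breakthrough_min_tension(84.3, 1900, 0.015, 5e-6)
        assert g_max == pytest.approx(8.34e-7, rel=0.01)
        assert physics.breakthrough_min_tension(84.3, 1900, 0.015, 0.0) == 0.0
        g_max10 = physics.breakthrough_min_tension(84.3, 1900, 0.015, 10e-6)
        assert g_max10 == pytest.approx(4 * g_max, rel=1e-9)
        # any droplet >= 10 um diameter crosses at the tension its 5 um
        # radius sibling barely tolerates
        assert physics.breakthrough_condition(84.3, 1900, 0.015, 10e-6, g_max)

    def test_droplet_frequency_and_count(self):
        q = 25 * UL_PER_MIN
        assert physics.droplet_frequency(q, 68.6e-6) == pytest.approx(2465, rel=0.01)
        n = physics.total_droplet_count(100e-9, 68.6e-6)
        assert n == pytest.approx(5.92e5, rel=0.01)
        assert n > 5e5
        f = physics.droplet_frequency(q, 68.6e-6)
        assert physics.droplet_frequency(q, 2 * 68.6e-6) == pytest.approx(f / 8, rel=1e-12)

    def test_mixture_density(self):
        assert physics.mixture_density([(1000.0, 1.0)]) == 1000.0
        assert physics.mixture_density([(1320, 0.185), (998, 0.815)]) == pytest.approx(
            1057.6, abs=0.1
        )
        assert physics.mixture_density([(900, 0.5), (1100, 0.5)]) == 1000.0
        with pytest.raises(ValueError):
            physics.mixture_density([(1000, 0.5), (1000, 0.6)])


class TestValidation:
    @pytest.mark.parametrize(
        "call",
        [
            lambda: physics.tangential_speed(-1, 0.01),
            lambda: physics.capillary_number(4e-3, 1.0, 0.0),
            lambda: physics.reynolds_number(934, 1.0, 5e-4, 0.0),
            lambda: physics.critical_jetting_flow_rate(-1e-4, 1e-3, 1018),
            lambda: physics.predicted_droplet_diameter(363e-6, 0.0),
            lambda: physics.radial_migration_speed(100, 1e-6, 1900, 0.01, 0.0),
            lambda: physics.wake_shear_analysis(1900, 0.01, (0.0, 5e-3), 4e-3, 5e-6),
            lambda: physics.bond_number(100, 1900, 0.015, 1e-6, 0.0),
            lambda: physics.droplet_frequency(1e-9, 0.0),
            lambda: physics.FluidPhase("bad", -1.0, 1e-3),
            lambda: physics.OperatingPoint(1900, 1e-9, 0.0, 1e-2),
        ],
    )
    def test_invalid_parameters_raise(self, call):
        with pytest.raises(ValueError):
            call()

    def test_geometry_ordering_enforced(self):
        with pytest.raises(ValueError):
            physics.DeviceGeometry(1e-4, 3.6e-4, 0.02, 0.015, 5e-4, 5e-3, 1e-7)


# SI -> (mm, g, s) coherent system: length x1e3, mass x1e3.
_MM = 1e3  # m -> mm
_G = 1e3  # kg -> g
_CONV = {
    "density": _G / _MM**3,
    "viscosity": _G / _MM,  # Pa s = kg/(m s) -> g/(mm s)
    "speed": _MM,
    "length": _MM,
    "tension": _G,  # N/m = kg/s^2 -> g/s^2
}


class TestProperties:
    @given(
        rpm=st.floats(500, 5000),
        mu=st.floats(1e-3, 1e-2),
        gamma=st.floats(1e-6, 1e-1),
        rho=st.floats(800, 1200),
        d=st.floats(1e-5, 1e-3),
        a=st.floats(1e-6, 1e-4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_unit_system_invariance(self, rpm, mu, gamma, rho, d, a):
        """Dimensionless groups are identical in SI and mm/g/s units."""
        r_i, r_o = 0.01, 0.015
        u = physics.tangential_speed(rpm, r_i)
        ca = physics.capillary_number(mu, u, gamma)
        re = physics.reynolds_number(rho, u, d, mu)
        bo = physics.bond_number(rho * 0.1, rpm, r_o, a, gamma)
        u2 = physics.tangential_speed(rpm, r_i * _CONV["length"])
        ca2 = physics.capillary_number(mu * _CONV["viscosity"], u2, gamma * _CONV["tension"])
        re2 = physics.reynolds_number(
            rho * _CONV["density"], u2, d * _CONV["length"], mu * _CONV["viscosity"]
        )
        bo2 = physics.bond_number(
            rho * 0.1 * _CONV["density"], rpm, r_o * _CONV["length"],
            a * _CONV["length"], gamma * _CONV["tension"],
        )
        for si, alt in ((ca, ca2), (re, re2), (bo, bo2)):
            assert abs(si - alt) <= 1e-10 * max(abs(si), 1.0)

    @given(q=st.floats(1e-12, 1e-8), d=st.floats(1e-6, 1e-3), v=st.floats(1e-9, 1e-6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_volume_conservation(self, q, d, v):
        """frequency x droplet volume == flow rate; count x volume == total."""
        vol = math.pi * d**3 / 6.0
        assert physics.droplet_frequency(q, d) * vol == pytest.approx(q, rel=1e-12)
        assert physics.total_droplet_count(v, d) * vol == pytest.approx(v, rel=1e-12)

    @given(st.lists(st.floats(10, 5000), min_size=2, max_size=6, unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotonicity(self, rpms):
        """Predicted diameter decreases with rotation speed; breakthrough
        tension increases with droplet radius; wake label is nondecreasing
        in Re."""
        rpms = sorted(rpms)
        cas = [
            physics.capillary_number(4e-3, physics.tangential_speed(r, 0.01), 1e-3)
            for r in rpms
        ]
        diams = [physics.predicted_droplet_diameter(363e-6, ca) for ca in cas]
        assert all(d1 > d2 for d1, d2 in zip(diams, diams[1:]))
        radii = np.linspace(1e-6, 1e-4, 5)
        tens = [physics.breakthrough_min_tension(84.3, 1900, 0.015, a) for a in radii]
        assert all(t1 < t2 for t1, t2 in zip(tens, tens[1:]))
        order = ["steady", "vortex_shedding", "three_dimensional"]
        labels = [order.index(physics.wake_regime(re)) for re in np.linspace(0, 400, 30)]
        assert labels == sorted(labels)


def test_default_operating_point_regimes(default_run):
    """The default 1900 rpm point sits in the shear-unstable breakup regime
    with a three-dimensionally unstable wake."""
    report = physics.evaluate_operating_point(
        default_run.inner,
        default_run.oil,
        default_run.geometry,
        default_run.operating_points[0],
    )
    assert report.breakup_regime == "shear_unstable"
    assert report.wake_regime == "three_dimensional"
    assert 0.5 <= report.ca <= 10.0
    assert report.u == pytest.approx(1.99, rel=0.01)
    # radial migration is ~2 orders of magnitude slower than the azimuthal sweep
    assert report.u_r < 0.1 * report.u
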