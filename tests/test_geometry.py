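"""Geometry data model, sphere fit, joint centers, directions and file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equilimb.errors import GeometryError, SchemaError
from equilimb.geometry import (
    HIP,
    PATELLOFEMORAL,
    STIFLE,
    Actuator,
    Joint,
    LimbGeometry,
    Segment,
    derive_joint_centers,
    effective_direction,
    fit_sphere,
    read_geometry,
    write_geometry,
)


def sphere_points(center, radius, n, rng=None, noise=0.0):
    rng = rng or np.random.default_rng(0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = np.asarray(center) + radius * v
    if noise:
        pts = pts + rng.normal(scale=noise, size=pts.shape)
    return pts


class TestFitSphere:
    def test_exact_unit_sphere_identity(self):
        pts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, 0.0, atol=1e-12)
        assert fit.radius == pytest.approx(1.0, abs=1e-12)
        assert fit.residual <= 1e-10

    def test_exact_sphere_recovered_to_solver_tolerance(self):
        pts = sphere_points([1, 2, 3], 0.05, 40)
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, [1, 2, 3], rtol=1e-10, atol=1e-10)
        assert fit.radius == pytest.approx(0.05, rel=1e-10)

    def test_noisy_femoral_head_matches_geometric_refit_oracle(self):
        # independent oracle: generic minimization of the orthogonal-distance
        # sum of squares, started away from the truth
        from scipy.optimize import minimize

        rng = np.random.default_rng(7)
        pts = sphere_points([1, 2, 3], 0.05, 200, rng=rng, noise=1e-4)

        def sq(x):
            return float(np.sum((np.linalg.norm(pts - x[:3], axis=1) - x[3]) ** 2))

        oracle = minimize(sq, x0=[0.9, 2.1, 2.9, 0.1], method="Nelder-Mead",
                          options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20000})
        fit = fit_sphere(pts)
        assert np.linalg.norm(fit.center - np.array([1, 2, 3])) < 1e-3
        assert np.allclose(fit.center, oracle.x[:3], atol=1e-7)
        assert fit.radius == pytest.approx(oracle.x[3], abs=1e-7)

    def test_underdetermined_and_coplanar_inputs_rejected(self):
        with pytest.raises(GeometryError):
            fit_sphere([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        coplanar = [(x, y, 0.0) for x in (0, 1, 2) for y in (0, 1, 2)]
        with pytest.raises(GeometryError):
            fit_sphere(coplanar)


class TestDeriveJointCenters:
    def landmarks(self, **overrides):
        base = {
            "femoral_head_points": sphere_points([0, 0.1, 1.0], 0.04, 12),
            "lateral_epicondyle": (0, -0.05, 0),
            "medial_epicondyle": (0, 0.05, 0),
            "patellar_contact_point": (0.1, 0.0, 0.65),
        }
        base.update(overrides)
        return base

    def test_stifle_center_is_epicondyle_midpoint(self):
        joints = {j.name: j for j in derive_joint_centers(self.landmarks())}
        assert np.allclose(joints[STIFLE].center, [0, 0, 0])

    def test_hip_center_is_fitted_sphere_center(self):
        joints = {j.name: j for j in derive_joint_centers(self.landmarks())}
        assert np.allclose(joints[HIP].center, [0, 0.1, 1.0], atol=1e-9)

    def test_contact_point_passed_through(self):
        joints = {j.name: j for j in derive_joint_centers(self.landmarks())}
        assert np.allclose(joints[PATELLOFEMORAL].center, [0.1, 0.0, 0.65])

    def test_coincident_epicondyles_warn_but_return_point(self):
        lm = self.landmarks(lateral_epicondyle=(0, 0.05, 0))
        with pytest.warns(UserWarning):
            joints = {j.name: j for j in derive_joint_centers(lm)}
        assert np.allclose(joints[STIFLE].center, [0, 0.05, 0])

    def test_missing_landmark_is_named_error(self):
        lm = self.landmarks()
        del lm["medial_epicondyle"]
        with pytest.raises(GeometryError, match="medial_epicondyle"):
            derive_joint_centers(lm)


class TestEffectiveDirection:
    def mk(self, origin, insertion, override=None):
        return Actuator(name="a", kind="muscle", origin=origin, insertion=insertion,
                        pcsa=1e-3, f_max=100.0, direction_override=override)

    def test_origin_to_insertion_normalized(self):
        assert np.allclose(effective_direction(self.mk([0, 0, 0], [0, 0, 2])), [0, 0, 1])

    def test_override_wins_regardless_of_endpoints(self):
        a = self.mk([0, 0, 0], [0, 0, 2], override=[0, 2, 0])
        assert np.allclose(effective_direction(a), [0, 1, 0])

    def test_zero_length_without_override_errors(self):
        a = self.mk([1, 1, 1], [1, 1, 1])
        with pytest.raises(GeometryError):
            effective_direction(a)

    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6))
    @settings(deadline=None)
    def test_always_unit_norm(self, coords):
        o, i = np.array(coords[:3]), np.array(coords[3:])
        if np.linalg.norm(i - o) < 1e-6:
            return
        d = effective_direction(self.mk(o, i))
        assert abs(np.linalg.norm(d) - 1.0) <= 1e-12


class TestValidation:
    def test_zero_pcsa_muscle_rejected(self):
        with pytest.raises(GeometryError):
            Actuator(name="m", kind="muscle", origin=[0, 0, 0], insertion=[1, 0, 0],
                     pcsa=0.0, f_max=10.0)

    def test_attachment_weights_must_sum_to_one(self):
        with pytest.raises(GeometryError, match="weights"):
            Actuator(name="m", kind="muscle", origin=[0, 0, 0], insertion=[1, 0, 0],
                     pcsa=1e-3, f_max=10.0,
                     attachment_points=(([1, 0, 0], 0.5), ([0, 1, 0], 0.4)))

    def test_span_of_unknown_joint_rejected(self):
        act = Actuator(name="m", kind="muscle", origin=[0, 0, 0], insertion=[1, 0, 0],
                       pcsa=1e-3, f_max=10.0, spans={"hock"})
        with pytest.raises(GeometryError, match="hock"):
            LimbGeometry(joints=[Joint(HIP, [0, 0, 1])], actuators=[act])

    def test_duplicate_joint_names_rejected(self):
        with pytest.raises(GeometryError):
            LimbGeometry(joints=[Joint(HIP, [0, 0, 1]), Joint(HIP, [0, 0, 0])], actuators=[])


@st.composite
def geometries(draw):
    finite = st.floats(-2, 2, allow_nan=False, allow_infinity=False)
    point = st.tuples(finite, finite, finite)
    n_act = draw(st.integers(1, 4))
    joints = [Joint(HIP, draw(point)), Joint(STIFLE, draw(point))]
    acts = []
    for i in range(n_act):
        o, ins = np.array(draw(point)), np.array(draw(point))
        if np.linalg.norm(ins - o) < 1e-3:
            ins = o + np.array([0.1, 0, 0])
        acts.append(Actuator(
            name=f"a{i}",
            kind=draw(st.sampled_from(["muscle", "ligament"])),
            origin=o, insertion=ins,
            pcsa=draw(st.floats(1e-4, 1e-2)),
            f_max=draw(st.floats(10, 5000)),
            spans=draw(st.sets(st.sampled_from([HIP, STIFLE]), max_size=2)),
            attaches_femur=draw(st.booleans()),
            area_label=draw(st.sampled_from(["", "areaA", "areaB"])),
        ))
    segs = [Segment("thigh", draw(st.floats(0, 0.2)), draw(point))]
    return LimbGeometry(joints=joints, actuators=acts, segments=segs,
                        body_mass=draw(st.floats(0, 800)), hoof_contact=draw(point))


class TestGeometryIO:
    def test_minimal_file_round_trip(self, toy_geometry, tmp_path):
        path = tmp_path / "geom.yaml"
        write_geometry(toy_geometry, path)
        back = read_geometry(path)
        assert back.joint_names == toy_geometry.joint_names
        assert [a.name for a in back.actuators] == [a.name for a in toy_geometry.actuators]
        for a, b in zip(toy_geometry.actuators, back.actuators):
            assert np.allclose(a.origin, b.origin)
            assert np.allclose(a.insertion, b.insertion)
            assert a.spans == b.spans and a.pcsa == b.pcsa and a.f_max == b.f_max

    @given(geom=geometries())
    @settings(deadline=None, max_examples=25)
    def test_read_write_identity_property(self, tmp_path_factory, geom):
        path = tmp_path_factory.mktemp("io") / "g.yaml"
        write_geometry(geom, path)
        back = read_geometry(path)
        assert back.body_mass == pytest.approx(geom.body_mass)
        assert np.allclose(back.hoof_contact, geom.hoof_contact)
        for a, b in zip(geom.actuators, back.actuators):
            assert a.name == b.name and a.kind == b.kind and a.spans == b.spans
            assert a.attaches_femur == b.attaches_femur and a.area_label == b.area_label
            assert np.allclose(a.origin, b.origin) and np.allclose(a.insertion, b.insertion)
            assert a.pcsa == pytest.approx(b.pcsa) and a.f_max == pytest.approx(b.f_max)
        for s, t in zip(geom.segments, back.segments):
            assert s.name == t.name and s.mass_fraction == pytest.approx(t.mass_fraction)

    def test_invalid_row_names_field(self, toy_geometry, tmp_path):
        path = tmp_path / "geom.yaml"
        write_geometry(toy_geometry, path)
        text = path.read_text().replace("pcsa_m2: 0.002", "pcsa_m2: 0.0")
        path.write_text(text)
        with pytest.raises(SchemaError, match="pcsa"):
            read_geometry(path)

    def test_non_geometry_document_rejected(self, tmp_path):
        path = tmp_path / "nope.yaml"
        path.write_text("hello: world\n")
        with pytest.raises(SchemaError):
            read_geometry(path)
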