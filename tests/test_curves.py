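"""Force-curve data model, TSV round-trips, baseline and contact-point tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

import dfskit as dk
from dfskit.curves import MANDATORY_KEYS


def test_thermal_energy_at_room_temperature():
    assert dk.thermal_energy(293.15) == pytest.approx(4.0475, rel=1e-3)


def test_metadata_validation():
    with pytest.raises(dk.CurveValidationError):
        dk.CurveMetadata(curve_id="x", spring_constant=-1.0, retract_speed=1.0)
    with pytest.raises(dk.CurveValidationError):
        dk.CurveMetadata(curve_id="x", spring_constant=10.0, retract_speed=0.0)
    with pytest.warns(UserWarning, match="spring_constant"):
        dk.CurveMetadata(curve_id="x", spring_constant=5000.0, retract_speed=1.0)


def test_non_monotone_time_rejected(metadata):
    t = np.array([0.0, 1.0, 0.5, 2.0])
    with pytest.raises(dk.CurveValidationError, match="strictly increasing"):
        dk.ForceCurve(
            metadata=metadata,
            time=t,
            height=np.zeros(4),
            force=np.zeros(4),
            segment=np.array(["retract"] * 4),
        )


class TestCurveIO:
    def test_round_trip_two_segments(self, flat_curve, tmp_path):
        path = tmp_path / "c.tsv"
        dk.write_curve(flat_curve, path)
        back = dk.read_curve(path)
        assert back.n_samples() == 1024
        assert back.n_samples("approach") == 512
        assert back.n_samples("retract") == 512
        assert back.metadata == flat_curve.metadata

    @pytest.mark.parametrize("key", MANDATORY_KEYS)
    def test_missing_mandatory_key_named_in_error(self, flat_curve, tmp_path, key):
        path = tmp_path / "c.tsv"
        dk.write_curve(flat_curve, path)
        lines = [
            ln for ln in path.read_text().splitlines() if not ln.startswith(f"# {key}\t")
        ]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(dk.CurveFormatError, match=key):
            dk.read_curve(path)

    def test_empty_retract_refused(self, metadata, tmp_path):
        curve = dk.ForceCurve(
            metadata=metadata,
            time=np.arange(20.0),
            height=np.linspace(100, 0, 20),
            force=np.zeros(20),
            segment=np.array(["approach"] * 20),
        )
        with pytest.raises(dk.CurveValidationError, match="retract"):
            dk.write_curve(curve, tmp_path / "c.tsv")

    @settings(
        max_examples=30,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(seed=st.integers(0, 10_000), n=st.integers(16, 200))
    def test_random_curves_round_trip(self, tmp_path, metadata, seed, n):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 1, 2 * n))
        t += np.arange(2 * n) * 1e-9  # break ties
        curve = dk.ForceCurve(
            metadata=metadata,
            time=t,
            height=rng.uniform(-50, 600, 2 * n),
            force=rng.normal(0, 100, 2 * n),
            segment=np.array(["approach"] * n + ["retract"] * n),
        )
        path = tmp_path / f"r{seed}.tsv"
        dk.write_curve(curve, path)
        back = dk.read_curve(path)
        for attr in ("time", "height", "force"):
            np.testing.assert_allclose(
                getattr(back, attr), getattr(curve, attr), rtol=1e-9, atol=1e-12
            )
        assert (back.segment == curve.segment).all()


class TestBaseline:
    @staticmethod
    def _tilted(flat_curve, tilt=0.05, offset=20.0, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        force = flat_curve.force + tilt * flat_curve.height + offset
        if sigma > 0:
            force = force + rng.normal(0, sigma, force.size)
        return dk.ForceCurve(
            metadata=flat_curve.metadata,
            time=flat_curve.time,
            height=flat_curve.height,
            force=force,
            segment=flat_curve.segment,
        )

    def test_tilt_and_offset_removed(self, flat_curve):
        curve = self._tilted(flat_curve, tilt=0.05, offset=20.0, sigma=1.0)
        corrected = dk.correct_baseline(curve)
        _, h, f = corrected.segment_arrays("retract")
        far = f[h > 400]
        assert abs(far.mean()) < 0.5

    def test_idempotent(self, flat_curve):
        curve = self._tilted(flat_curve, sigma=3.0)
        once = dk.correct_baseline(curve)
        twice = dk.correct_baseline(once)
        np.testing.assert_allclose(twice.force, once.force, atol=1e-6)

    def test_noise_sd_preserved(self, flat_curve):
        curve = self._tilted(flat_curve, tilt=0.0, offset=0.0, sigma=5.0, seed=7)
        corrected = dk.correct_baseline(curve)
        _, h, f = corrected.segment_arrays("retract")
        tail = f[-150:]
        assert tail.std() == pytest.approx(5.0, rel=0.25)
        assert dk.estimate_noise_sigma(corrected) == pytest.approx(5.0, rel=0.25)

    def test_bad_tail_fraction(self, flat_curve):
        with pytest.raises(ValueError):
            dk.correct_baseline(flat_curve, tail_fraction=0.7)


class TestContactPoint:
    def test_recovers_contact_at_origin(self):
        curve, _ = dk.synthesize_curve(seed=11, events=())
        corrected = dk.correct_baseline(curve)
        assert dk.find_contact_point(corrected) == pytest.approx(0.0, abs=2.0)

    def test_no_contact_on_noise_only(self, flat_curve):
        rng = np.random.default_rng(3)
        noisy = dk.ForceCurve(
            metadata=flat_curve.metadata,
            time=flat_curve.time,
            height=flat_curve.height,
            force=rng.normal(0, 5.0, flat_curve.force.size),
            segment=flat_curve.segment,
        )
        with pytest.raises(dk.NoContactError, match="no contact"):
            dk.find_contact_point(noisy)

    @pytest.mark.parametrize("shift", [-50.0, 100.0, 250.0])
    def test_translation_equivariance(self, shift):
        ref, _ = dk.synthesize_curve(seed=5)
        moved, _ = dk.synthesize_curve(seed=5, contact_height=shift)
        c0 = dk.find_contact_point(dk.correct_baseline(ref))
        c1 = dk.find_contact_point(dk.correct_baseline(moved))
        assert c1 - c0 == pytest.approx(shift, abs=1e-6)


class TestGrid:
    def test_index_round_trip(self, tmp_path):
        grid = dk.ForceVolumeGrid(
            4, 4, {(r, c): f"px-{r}-{c}" for r in range(4) for c in range(4)},
            curve_paths={f"px-{r}-{c}": f"px-{r}-{c}.tsv" for r in range(4) for c in range(4)},
        )
        assert grid.complete
        path = tmp_path / "index.csv"
        dk.write_grid_index(grid, path)
        back = dk.read_grid_index(path)
        assert back.n_rows == 4 and back.n_cols == 4
        assert back.pixel_curves == grid.pixel_curves

    def test_out_of_bounds_pixel(self):
        with pytest.raises(dk.CurveValidationError):
            dk.ForceVolumeGrid(2, 2, {(2, 0): "a"})

    def test_duplicate_curve_id(self):
        with pytest.raises(dk.CurveValidationError):
            dk.ForceVolumeGrid(2, 2, {(0, 0): "a", (0, 1): "a"})
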