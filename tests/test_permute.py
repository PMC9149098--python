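"""Signal permutation engine: conservation laws, schedules, filtering."""

import json

import numpy as np
import pandas as pd
import pytest

from tomoperm.io import ParticleTable, VoxelVolume, read_volume, write_volume
from tomoperm.masks import BinaryMask, grow_mask_shells, make_cylinder_mask, make_sphere_mask
from tomoperm.permute import (
    OutlierFilter,
    PermutationSchedule,
    filter_outliers,
    permute_outside_mask,
    signal_permute_particles,
)


def _full_mask(n):
    return BinaryMask(np.ones((n, n, n), bool), 1.0)


def _empty_mask(n):
    return BinaryMask(np.zeros((n, n, n), bool), 1.0)


class TestSchedule:
    def test_default_linear_ramp(self):
        s = PermutationSchedule(step=2, n_shells=5)
        assert s.fractions == pytest.approx(tuple(k / 6 for k in range(1, 6)))

    def test_rejects_decreasing(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            PermutationSchedule(step=2, n_shells=2, fractions=(0.8, 0.2))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            PermutationSchedule(step=2, n_shells=1, fractions=(1.5,))


class TestPermuteOutsideMask:
    def test_all_ones_mask_identity(self, small_noise_volume):
        out = permute_outside_mask(
            small_noise_volume, _full_mask(32), PermutationSchedule(), seed=3
        )
        assert np.array_equal(out.data, small_noise_volume.data)

    def test_empty_mask_full_permutation(self, small_noise_volume):
        """With no mask the whole volume is one permutation pool: sorted
        values (hence mean and SD) are exactly preserved."""
        out = permute_outside_mask(
            small_noise_volume,
            _empty_mask(32),
            PermutationSchedule(step=1, n_shells=0),
            seed=3,
        )
        assert not np.array_equal(out.data, small_noise_volume.data)
        a = np.sort(out.data, axis=None)
        b = np.sort(small_noise_volume.data, axis=None)
        assert np.array_equal(a, b)
        # identical sorted values => identical mean and SD (summed in the
        # same order so the equality is bitwise)
        assert a.mean() == b.mean() and a.std() == b.std()

    def test_multiset_conserved_with_shells(self, noise_volume):
        mask = make_cylinder_mask(64, 40, 20)
        out = permute_outside_mask(
            noise_volume, mask, PermutationSchedule(step=2, n_shells=5), seed=9
        )
        assert np.array_equal(
            np.sort(out.data, axis=None), np.sort(noise_volume.data, axis=None)
        )

    def test_masked_region_bit_identical(self, noise_volume):
        mask = make_sphere_mask(64, 30.0, 1.0)
        out = permute_outside_mask(
            noise_volume, mask, PermutationSchedule(step=2, n_shells=3), seed=1
        )
        assert np.array_equal(out.data[mask.data], noise_volume.data[mask.data])

    def test_per_shell_moved_fraction_binomial(self):
        """Across 20 seeds, the per-shell count of permuted voxels tracks
        f_k * shell_size within 4 binomial standard deviations."""
        box = 48
        mask = make_sphere_mask(box, 16.0, 1.0)
        fractions = (0.25, 0.5, 0.75)
        sched = PermutationSchedule(step=2, n_shells=3, fractions=fractions)
        shells, _ = grow_mask_shells(mask, 2, 3)
        # permuting an index volume reveals exactly which voxels moved
        idx_vol = VoxelVolume(
            np.arange(box**3, dtype=np.float64).reshape(box, box, box), 1.0
        )
        n_seeds = 20
        moved = np.zeros(3)
        for seed in range(n_seeds):
            out = permute_outside_mask(idx_vol, mask, sched, seed=seed)
            changed = out.data != idx_vol.data
            for k, shell in enumerate(shells):
                moved[k] += changed[shell.data].sum()
        for k, shell in enumerate(shells):
            n, f = shell.count(), fractions[k]
            expect = n_seeds * n * f
            sd = np.sqrt(n_seeds * n * f * (1 - f))
            assert abs(moved[k] - expect) < 4 * sd

    def test_displacement_nondecreasing_across_shells(self):
        """Mean voxel displacement grows with shell index (information
        decays with distance from the mask)."""
        box = 48
        mask = make_sphere_mask(box, 16.0, 1.0)
        sched = PermutationSchedule(step=2, n_shells=3)
        shells, _ = grow_mask_shells(mask, 2, 3)
        idx_vol = VoxelVolume(
            np.arange(box**3, dtype=np.float64).reshape(box, box, box), 1.0
        )
        grid = np.indices((box, box, box)).reshape(3, -1).T.astype(float)
        disp_sums = np.zeros(3)
        counts = np.array([s.count() for s in shells], float)
        for seed in range(20):
            out = permute_outside_mask(idx_vol, mask, sched, seed=seed)
            src = out.data.reshape(-1).astype(np.int64)
            d = np.linalg.norm(grid - grid[src], axis=1).reshape(box, box, box)
            for k, shell in enumerate(shells):
                disp_sums[k] += d[shell.data].sum()
        means = disp_sums / (20 * counts)
        assert means[0] < means[1] < means[2]

    def test_shape_mismatch(self, small_noise_volume):
        with pytest.raises(ValueError, match="differ"):
            permute_outside_mask(
                small_noise_volume, _full_mask(16), PermutationSchedule(), 0
            )


class TestOutlierFilter:
    def test_huge_thresholds_identity(self, small_noise_volume):
        filt = OutlierFilter(w=1e9, b=1e9)
        out = filter_outliers(small_noise_volume, _empty_mask(32), filt, 5)
        assert np.array_equal(out.data, small_noise_volume.data)

    def test_planted_spikes_replaced_outside_only(self, rng):
        box = 32
        data = rng.standard_normal((box, box, box))
        mask = make_sphere_mask(box, 12.0, 1.0)
        outside = np.argwhere(~mask.data)
        inside = np.argwhere(mask.data)
        pick_out = outside[rng.choice(len(outside), 100, replace=False)]
        pick_in = inside[rng.choice(len(inside), 10, replace=False)]
        for p in pick_out:
            data[tuple(p)] = 10.0 * data.std()
        for p in pick_in:
            data[tuple(p)] = 10.0 * data.std()
        vol = VoxelVolume(data, 1.0)
        out = filter_outliers(vol, mask, OutlierFilter(w=3, b=3), seed=0)
        for p in pick_out:
            assert out.data[tuple(p)] != data[tuple(p)]
        for p in pick_in:
            assert out.data[tuple(p)] == data[tuple(p)]

    def test_mean_stays_near_zero(self):
        """Filtering a z-scored volume leaves the mean within sampling
        error of zero (20 seeds)."""
        means = []
        for seed in range(20):
            r = np.random.default_rng(seed + 100)
            data = r.standard_normal((32, 32, 32))
            data = (data - data.mean()) / data.std()
            out = filter_outliers(
                VoxelVolume(data, 1.0), _empty_mask(32), OutlierFilter(), seed
            )
            means.append(out.data.mean())
        # ~0.27% of voxels replaced; SE of the volume mean ~ 1/sqrt(n)
        assert abs(np.mean(means)) < 3.0 / np.sqrt(20 * 32**3)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            OutlierFilter(w=-1.0)


class TestBatchDriver:
    @pytest.fixture
    def dataset(self, tmp_path, rng):
        from tomoperm.phantoms import PhantomSpec, generate_interface_phantom

        spec = PhantomSpec(box=32, n_particles=3, noise_sd=1.0, seed=6,
                           membrane_gap=12, peak_sep=4.0, sigma=1.0,
                           density_radius=2.0, density_length=6.0)
        ds = generate_interface_phantom(spec)
        paths = []
        for i, vol in enumerate(ds.volumes):
            p = tmp_path / f"p{i}.mrc"
            write_volume(vol, p)
            paths.append(str(p))
        ds.table.df["rlnImageName"] = paths
        return ds

    def test_masked_fidelity_and_sidecar(self, dataset, tmp_path):
        from tomoperm.geometry import RigidTransform, matrix_from_euler
        from tomoperm.masks import transform_mask

        out_dir = tmp_path / "out"
        table = signal_permute_particles(
            dataset.table, dataset.mask, PermutationSchedule(step=1, n_shells=2),
            None, seed=4, output_dir=out_dir,
        )
        assert len(table) == 3
        for i, rec in enumerate(table.records()):
            permuted = read_volume(rec.image_path)
            original = read_volume(dataset.table.record(i).image_path)
            A = matrix_from_euler(*dataset.table.eulers()[i])
            placed = transform_mask(
                dataset.mask, RigidTransform(A.T, dataset.table.origins()[i])
            )
            assert np.array_equal(
                permuted.data[placed.data], original.data[placed.data]
            )
        log = json.loads((out_dir / "permutation_log.json").read_text())
        assert log["seed"] == 4 and len(log["particles"]) == 3

    def test_byte_identical_reruns(self, dataset, tmp_path):
        kw = dict(
            masks=dataset.mask,
            sched=PermutationSchedule(step=1, n_shells=1),
            filt=OutlierFilter(),
            seed=11,
        )
        signal_permute_particles(dataset.table, output_dir=tmp_path / "a", **kw)
        signal_permute_particles(dataset.table, output_dir=tmp_path / "b", **kw)
        for i in range(3):
            a = (tmp_path / "a" / f"permuted_{i:06d}.mrc").read_bytes()
            b = (tmp_path / "b" / f"permuted_{i:06d}.mrc").read_bytes()
            assert a == b

    def test_mask_centroid_tracks_updated_angles(self, dataset, tmp_path):
        """Repeat rounds: an off-center mask placed via refined angles
        lands where the rotation sends the mask center."""
        from scipy import ndimage

        from tomoperm.geometry import RigidTransform, matrix_from_euler
        from tomoperm.masks import make_sphere_mask, transform_mask

        box = 32
        center_off = np.array([16.0, 16.0, 22.0])  # 6 voxels above center
        m = make_sphere_mask(box, 8.0, 1.0, center=center_off)
        for euler in ((0.0, 90.0, 0.0), (30.0, 45.0, -60.0)):
            A = matrix_from_euler(*euler)
            placed = transform_mask(m, RigidTransform(A.T, np.zeros(3)))
            c = box // 2
            expected = A @ (center_off - c) + c
            got = np.array(ndimage.center_of_mass(placed.data))
            assert np.abs(got - expected).max() < 1.0

    def test_missing_angles_rejected(self, dataset, tmp_path):
        bad = dataset.table.copy()
        bad.df = bad.df.drop(columns=["rlnAngleRot"])
        with pytest.raises(ValueError, match="angles"):
            signal_permute_particles(
                bad, dataset.mask, PermutationSchedule(), None, 0, tmp_path / "x"
            )

    def test_unknown_class_rejected(self, dataset, tmp_path):
        t = dataset.table.copy()
        t.df["rlnClassNumber"] = [1, 2, 3]
        with pytest.raises(KeyError, match="class"):
            signal_permute_particles(
                t, {1: dataset.mask}, PermutationSchedule(), None, 0,
                tmp_path / "y",
            )
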