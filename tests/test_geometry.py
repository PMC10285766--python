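"""Centroid construction and quadrant/band partition, checked against
brute-force per-voxel and per-boundary-point oracles."""

import math

import numpy as np
import pytest

import discquant as dq
from discquant.containers import CAVITY, NP
from discquant.geometry import (
    QUADRANTS,
    build_disc_frame,
    extract_mid_transverse_mask,
    find_landmarks,
    landmarks_from_points,
    localize_removed_volume,
    localize_volume,
    partition_regions,
)
from conftest import circle_mask

# ---------------------------------------------------------------------------
# independent oracles (plain loops, no shared code with the implementation)
# ---------------------------------------------------------------------------


def brute_force_boundary(mask):
    """4-neighborhood boundary pixels via an explicit loop."""
    out = []
    nx, ny = mask.shape
    for i in range(nx):
        for j in range(ny):
            if not mask[i, j]:
                continue
            nb = [
                mask[i - 1, j] if i > 0 else False,
                mask[i + 1, j] if i < nx - 1 else False,
                mask[i, j - 1] if j > 0 else False,
                mask[i, j + 1] if j < ny - 1 else False,
            ]
            if not all(nb):
                out.append((i, j))
    return out


def brute_force_frame(mask, spacing):
    """Rectangle/centroid construction re-derived with explicit scans."""
    dx, dy = spacing
    pts = [(i * dx, j * dy) for i, j in brute_force_boundary(mask)]
    occupied = [(i, j) for i in range(mask.shape[0]) for j in range(mask.shape[1]) if mask[i, j]]
    cx = sum(i for i, _ in occupied) / len(occupied) * dx
    left = [p for p in pts if p[0] < cx]
    right = [p for p in pts if p[0] >= cx]
    p1 = min(left, key=lambda p: (p[1], p[0]))
    p5 = min(right, key=lambda p: (p[1], -p[0]))
    if abs(p1[1] - p5[1]) <= 1.0001 * dy:
        ux, uy = 1.0, 0.0
    else:
        norm = math.hypot(p5[0] - p1[0], p5[1] - p1[1])
        ux, uy = (p5[0] - p1[0]) / norm, (p5[1] - p1[1]) / norm
        if ux < 0:
            ux, uy = -ux, -uy
    vx, vy = -uy, ux
    if vy < 0:
        vx, vy = -vx, -vy
    s = [px * ux + py * uy for px, py in pts]
    t = [px * vx + py * vy for px, py in pts]
    if abs(p1[1] - p5[1]) <= 1.0001 * dy:
        t1 = min(t)  # tangent at the posterior pole
    else:
        t1 = p1[0] * vx + p1[1] * vy
    s2, s3, t4 = min(s), max(s), max(t)
    c = (
        (s2 + s3) / 2 * ux + (t1 + t4) / 2 * vx,
        (s2 + s3) / 2 * uy + (t1 + t4) / 2 * vy,
    )
    return {"centroid": c, "width": s3 - s2, "u": (ux, uy)}


def brute_force_regions(volume, frame, fractions, entry_side="left"):
    """Per-voxel (quadrant, band) classification by explicit looping."""
    dx, dy, _ = volume.spacing
    radii = [f * 0.5 * frame.width for f in fractions]
    ux, uy = frame.u
    vx, vy = frame.v
    cs = frame.centroid[0] * ux + frame.centroid[1] * uy
    ct = frame.centroid[0] * vx + frame.centroid[1] * vy
    nx, ny, nz = volume.voxels.shape
    quad = np.empty((nx, ny), dtype=np.int8)
    band = np.empty((nx, ny), dtype=np.int8)
    for i in range(nx):
        for j in range(ny):
            x, y = i * dx, j * dy
            s = x * ux + y * uy - cs
            t = x * vx + y * vy - ct
            r = math.hypot(s, t)
            b = 0
            for rad in radii:
                if r >= rad:
                    b += 1
            band[i, j] = b
            anterior = t >= 0.0
            if entry_side == "left":
                left = s <= 0.0
            else:
                left = s < 0.0
            quad[i, j] = (0 if left else 1) if anterior else (2 if left else 3)
    return quad, band


# ---------------------------------------------------------------------------
# mid-slice and landmarks
# ---------------------------------------------------------------------------


class TestMidSlice:
    def test_mid_slice_at_disc_midheight(self, small_phantom):
        disc = small_phantom.disc_mask()
        zs = np.flatnonzero(disc.any(axis=(0, 1)))
        mask, zi = extract_mid_transverse_mask(small_phantom)
        assert abs(zi - (zs.min() + zs.max()) / 2) <= 1
        area = mask.sum() * 0.25
        assert area == pytest.approx(math.pi * 20 * 15, rel=0.02)

    def test_single_slice_disc(self):
        vox = np.zeros((20, 20, 1), dtype=np.int16)
        vox[5:15, 5:15, 0] = NP
        vol = dq.LabelVolume(voxels=vox, spacing=(1, 1, 1))
        _, zi = extract_mid_transverse_mask(vol)
        assert zi == 0

    def test_no_disc_rejected(self):
        vol = dq.LabelVolume(voxels=np.zeros((4, 4, 4), dtype=np.int16), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="no disc"):
            extract_mid_transverse_mask(vol)


class TestLandmarks:
    def test_circle_uses_tangent_fallback(self):
        mask = circle_mask(10.0, 0.25)
        frame = build_disc_frame(find_landmarks(mask, (0.25, 0.25)))
        assert frame.used_tangent_fallback
        assert frame.width == pytest.approx(20.0, abs=0.5)
        center = (np.array(mask.shape) - 1) / 2 * 0.25
        assert np.allclose(frame.centroid, center, atol=0.25)
        assert frame.rotation_deg == 0.0

    def test_ellipse_width_and_center(self, small_phantom):
        mask, _ = extract_mid_transverse_mask(small_phantom)
        frame = build_disc_frame(find_landmarks(mask, (0.5, 0.5)))
        assert frame.width == pytest.approx(40.0, abs=0.5)
        grid_center = (np.array(mask.shape) - 1) / 2 * 0.5
        assert np.allclose(frame.centroid, grid_center, atol=0.25)

    def test_bean_tilts_line_one_and_matches_brute_force(self, bean_phantom):
        mask, _ = extract_mid_transverse_mask(bean_phantom)
        lm = find_landmarks(mask, (0.5, 0.5))
        frame = build_disc_frame(lm)
        assert not frame.used_tangent_fallback
        assert not np.allclose(lm["P1"], lm["P5"])
        assert abs(frame.rotation_deg) > 1.0
        oracle = brute_force_frame(mask, (0.5, 0.5))
        assert np.allclose(frame.centroid, oracle["centroid"], atol=1e-9)
        assert frame.width == pytest.approx(oracle["width"], abs=1e-9)

    def test_translation_equivariance(self, bean_phantom):
        """Shifting the mask by whole voxels shifts the centroid exactly."""
        mask, _ = extract_mid_transverse_mask(bean_phantom)
        mask = np.pad(mask, 10)  # room so the roll never wraps content
        f0 = build_disc_frame(find_landmarks(mask, (0.5, 0.5)))
        shifted = np.roll(mask, (6, -4), axis=(0, 1))
        f1 = build_disc_frame(find_landmarks(shifted, (0.5, 0.5)))
        assert np.allclose(f1.centroid - f0.centroid, (3.0, -2.0), atol=1e-9)
        assert f1.width == pytest.approx(f0.width, abs=1e-9)

    def test_rotation_equivariance(self):
        """An ellipse with a flat posterior chop generated at 10 degrees
        tilts line 1 by exactly the chop angle and keeps W measured along
        the tilted axis (not the grid axis)."""

        def chopped_ellipse(angle_deg):
            sp = 0.25
            n = int(2 * 23 / sp)
            xs = (np.arange(n) - (n - 1) / 2) * sp
            X, Y = np.meshgrid(xs, xs, indexing="ij")
            c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
            Xr, Yr = c * X + s * Y, -s * X + c * Y
            return ((Xr / 20) ** 2 + (Yr / 15) ** 2 <= 1) & (Yr > -12)

        f0 = build_disc_frame(find_landmarks(chopped_ellipse(0.0), (0.25, 0.25)))
        f10 = build_disc_frame(find_landmarks(chopped_ellipse(10.0), (0.25, 0.25)))
        assert f0.rotation_deg == pytest.approx(0.0, abs=1.0)
        assert f10.rotation_deg == pytest.approx(10.0, abs=1.5)
        # W is the full lateral extent (2a) measured along line 1 either way
        assert f0.width == pytest.approx(40.0, abs=0.5)
        assert f10.width == pytest.approx(f0.width, rel=0.02)

    def test_thin_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, :] = True
        with pytest.raises(ValueError, match="thin"):
            find_landmarks(mask, (1.0, 1.0))

    def test_degenerate_rectangle_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        lm = landmarks_from_points(pts, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            build_disc_frame(lm)


# ---------------------------------------------------------------------------
# partition and localization
# ---------------------------------------------------------------------------


class TestPartition:
    def test_innermost_circle_area_fraction(self):
        """For a centered disc of radius 0.5W the innermost circle (radius
        0.1W) holds (0.1/0.5)^2 = 4% of the disc area."""
        sp = 0.25
        mask = circle_mask(10.0, sp)
        frame = build_disc_frame(find_landmarks(mask, (sp, sp)))
        vol = dq.LabelVolume(
            voxels=np.where(mask, NP, 0).astype(np.int16)[:, :, None],
            spacing=(sp, sp, sp),
        )
        part = partition_regions(frame, vol)
        iv = part.intact_volumes
        frac = iv[iv.band == 0]["intact_mm3"].sum() / iv["intact_mm3"].sum()
        assert 100 * frac == pytest.approx(4.0, abs=0.5)

    def test_conservation_exact(self, shaver_phantom):
        table, _, part = localize_volume(shaver_phantom)
        disc_total = dq.removed_volume(shaver_phantom).disc_mm3
        assert table["intact_mm3"].sum() == pytest.approx(disc_total, abs=1e-9)

    def test_every_voxel_assigned(self, shaver_phantom):
        _, _, part = localize_volume(shaver_phantom)
        assert part.quadrant.min() >= 0 and part.quadrant.max() <= 3
        assert part.band.min() >= 0 and part.band.max() <= len(part.fractions)

    def test_axis_tie_break_deterministic(self):
        """Voxel centers exactly on the quadrant axes are assigned, never
        dropped: anterior on the lateral axis, entry side on the AP axis."""
        mask = circle_mask(5.0, 1.0)
        frame = build_disc_frame(find_landmarks(mask, (1.0, 1.0)))
        vol = dq.LabelVolume(
            voxels=np.where(mask, NP, 0).astype(np.int16)[:, :, None], spacing=(1, 1, 1)
        )
        part = partition_regions(frame, vol, entry_side="left")
        i0 = int(round(frame.centroid[0]))
        j0 = int(round(frame.centroid[1]))
        assert QUADRANTS[part.quadrant[i0, j0, 0]] == "anterior-left"
        # on the AP axis, anterior side: tie goes to the entry (left) side
        assert QUADRANTS[part.quadrant[i0, j0 + 2, 0]] == "anterior-left"
        # on the lateral axis, right side: tie goes anterior
        assert QUADRANTS[part.quadrant[i0 + 2, j0, 0]] == "anterior-right"

    def test_bad_fractions_rejected(self, small_phantom):
        mask, _ = extract_mid_transverse_mask(small_phantom)
        frame = build_disc_frame(find_landmarks(mask, (0.5, 0.5)))
        with pytest.raises(ValueError, match="increasing"):
            partition_regions(frame, small_phantom, fractions=(0.4, 0.2))

    def test_radius_mode_doubles_radii(self, small_phantom):
        mask, _ = extract_mid_transverse_mask(small_phantom)
        frame = build_disc_frame(find_landmarks(mask, (0.5, 0.5)))
        pd_ = partition_regions(frame, small_phantom, radius_mode="diameter")
        pr = partition_regions(frame, small_phantom, radius_mode="radius")
        assert np.allclose(pr.radii, 2 * pd_.radii)


class TestLocalization:
    def test_central_sphere_all_in_band0_and_balanced(self):
        """A small central cavity sits 100% in band 0, ~25% per quadrant."""
        spec = dq.PhantomSpec(a=20, b=15, h=10, spacing=(0.25, 0.25, 0.25))
        vol = dq.gen_disc_volume(spec)
        mask, _ = extract_mid_transverse_mask(vol)
        frame = build_disc_frame(find_landmarks(mask, (0.25, 0.25)))
        # carve a sphere of radius 0.05 W centered at the centroid
        r_sph = 0.05 * frame.width
        nx, ny, nz = vol.voxels.shape
        X = (np.arange(nx) * 0.25)[:, None, None]
        Y = (np.arange(ny) * 0.25)[None, :, None]
        Z = (np.arange(nz) * 0.25)[None, None, :]
        cz = (nz - 1) / 2 * 0.25
        inside = (
            (X - frame.centroid[0]) ** 2 + (Y - frame.centroid[1]) ** 2 + (Z - cz) ** 2
            <= r_sph**2
        )
        vox = vol.voxels.copy()
        vox[inside & (vox == NP)] = CAVITY
        carved = dq.LabelVolume(voxels=vox, spacing=vol.spacing)
        part = partition_regions(frame, carved)
        table, summary = localize_removed_volume(part, carved)
        band0 = table[table.band == 0]["pct_of_removed"].sum()
        assert band0 == pytest.approx(100.0, abs=1e-9)
        # the documented tie-break sends whole voxel planes on the axes to
        # the anterior/entry side, so balance holds to axis-plane tolerance
        per_quadrant = table.groupby("quadrant")["pct_of_removed"].sum()
        assert per_quadrant.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(per_quadrant, 25.0, atol=5.5)

    def test_laser_track_within_40pct_boundary(self, laser_phantom):
        """The whole laser cavity lies within 0.4 W of the centroid."""
        _, summary, _ = localize_volume(laser_phantom)
        assert summary["pct_within_0.4W"] == pytest.approx(100.0, abs=1e-9)

    def test_norm_a_sums_to_100(self, shaver_phantom):
        table, _, _ = localize_volume(shaver_phantom)
        assert table["pct_of_removed"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_offset_cavity_matches_brute_force_exactly(self, small_phantom):
        """Region volumes equal an independent per-voxel classification."""
        cav = dq.CavitySpec(
            technique="shaver", target_volume_mm3=250.0, center_offset_frac=(0.15, 0.1)
        )
        carved = dq.carve_cavity(small_phantom, cav, seed=5)
        mask, _ = extract_mid_transverse_mask(carved)
        frame = build_disc_frame(find_landmarks(mask, (0.5, 0.5)))
        part = partition_regions(frame, carved)
        quad_o, band_o = brute_force_regions(carved, frame, part.fractions)
        np.testing.assert_array_equal(part.quadrant[:, :, 0], quad_o)
        np.testing.assert_array_equal(part.band[:, :, 0], band_o)
        # and the aggregated removed volumes agree exactly
        table, _ = localize_removed_volume(part, carved)
        n_bands = part.n_bands
        cavm = carved.voxels == CAVITY
        for qi, qname in enumerate(QUADRANTS):
            for bi in range(n_bands):
                manual = 0
                idx = np.argwhere(cavm)
                sel = (quad_o[idx[:, 0], idx[:, 1]] == qi) & (
                    band_o[idx[:, 0], idx[:, 1]] == bi
                )
                manual = sel.sum() * carved.voxel_volume
                got = table[(table.quadrant == qname) & (table.band == bi)][
                    "removed_mm3"
                ].iloc[0]
                assert got == pytest.approx(manual, abs=1e-9)

    def test_monotonicity_under_cavity_growth(self, small_phantom):
        """Enlarging the cavity never shrinks any region's removed volume."""
        small = dq.carve_cavity(
            small_phantom, dq.CavitySpec(target_volume_mm3=150.0), seed=2
        )
        # grow: relabel additional NP voxels of the same phantom
        big = dq.carve_cavity(
            small_phantom, dq.CavitySpec(target_volume_mm3=400.0), seed=2
        )
        assert np.all((small.voxels == CAVITY) <= (big.voxels == CAVITY))
        t_small, _, _ = localize_volume(small)
        t_big, _, _ = localize_volume(big)
        assert np.all(
            t_big["removed_mm3"].to_numpy() >= t_small["removed_mm3"].to_numpy() - 1e-9
        )

    def test_translation_invariance_of_percentages(self, shaver_phantom):
        padded = dq.LabelVolume(
            voxels=np.pad(shaver_phantom.voxels, ((10, 10), (10, 10), (0, 0))),
            spacing=shaver_phantom.spacing,
        )
        t0, s0, _ = localize_volume(padded)
        rolled = dq.LabelVolume(
            voxels=np.roll(padded.voxels, (4, -6, 0), axis=(0, 1, 2)),
            spacing=padded.spacing,
        )
        t1, s1, _ = localize_volume(rolled)
        np.testing.assert_allclose(
            t0["pct_of_removed"].to_numpy(), t1["pct_of_removed"].to_numpy(), atol=1e-9
        )
        assert s0["pct_within_0.4W"] == pytest.approx(s1["pct_within_0.4W"], abs=1e-9)

    def test_zero_cavity_warns_not_raises(self, small_phantom):
        with pytest.warns(UserWarning, match="no cavity"):
            table, summary, _ = localize_volume(small_phantom)
        assert table["removed_mm3"].sum() == 0
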