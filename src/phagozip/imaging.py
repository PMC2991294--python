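"""Synthetic two-channel confocal stacks and the image-analysis pipeline.

Renders a simulation scene into a confocal-like z-series (channel 1 =
particle/IgG shell, channel 2 = membrane/receptor) with the acquisition
geometry of the experiments this model is compared against: 0.4 um z-step,
~0.1 um xy pixels, optional Gaussian blur and Poisson shot noise.  The
analysis half mirrors the quantification applied to real stacks: receptor
masking by the particle channel, circular-Hough particle detection,
engulfed-fraction estimation inside a sphere S0 of radius 4R/3, 24-segment
height profiles, and the equator-plane intensity variability alternative.
Because rendered stacks come from meshes with known ground truth, the whole
pipeline can be validated without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
import tifffile

from .cup import CupProfile, N_SEGMENTS


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition emulation parameters.

    z_step 0.4 um matches the confocal z-series spacing; the stack covers
    the particle plus one particle radius of margin on every side.
    """

    z_step: float = 0.4
    xy_pixel: float = 0.1
    psf_sigma: float = 0.0          # um; 0 disables blur
    noise: str = "none"             # "none" | "poisson"
    noise_scale: float = 30.0       # mean photon count at unit intensity
    shell_half_width: float = 0.08  # um, rendered surface half-thickness

    def __post_init__(self):
        if self.z_step <= 0 or self.xy_pixel <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


@dataclass
class Stack:
    """Two-channel 3D image with voxel geometry and ground-truth metadata."""

    ch1: np.ndarray                 # (nz, ny, nx) particle/IgG shell
    ch2: np.ndarray                 # (nz, ny, nx) membrane/receptor
    origin: np.ndarray              # world coords of voxel (0,0,0) center
    z_step: float
    xy_pixel: float
    meta: dict = field(default_factory=dict)

    def voxel_centers_plane(self, k: int):
        ny, nx = self.ch1.shape[1:]
        x = self.origin[0] + np.arange(nx) * self.xy_pixel
        y = self.origin[1] + np.arange(ny) * self.xy_pixel
        return x, y, self.origin[2] + k * self.z_step

    def world_to_voxel(self, p):
        p = np.asarray(p, dtype=np.float64)
        return np.array([
            (p[2] - self.origin[2]) / self.z_step,
            (p[1] - self.origin[1]) / self.xy_pixel,
            (p[0] - self.origin[0]) / self.xy_pixel,
        ])

    def copy(self) -> "Stack":
        return Stack(self.ch1.copy(), self.ch2.copy(), self.origin.copy(),
                     self.z_step, self.xy_pixel, dict(self.meta))


@dataclass
class DetectedParticle:
    """Particle located in a stack by the Hough search."""

    center: np.ndarray              # world coords, um
    radius: float                   # um
    engulfed_pct: float = 0.0
    profile: CupProfile | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")


# -- rendering ------------------------------------------------------------


def render_stack(mesh, shape, config: ImagingConfig,
                 rng: np.random.Generator | None = None,
                 max_voxels: int = 40_000_000) -> Stack:
    """Rasterise a membrane mesh + particle scene into a two-channel stack.

    ch1 is the particle surface shell from the signed distance; ch2 is the
    membrane surface from dense area-uniform triangle sampling.  Optional
    Gaussian blur is applied before Poisson noise.  ``mesh`` or ``shape``
    may be None for partial scenes.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    # stack bounds: particle plus one radius margin (or mesh bounds)
    if shape is not None:
        pts, _ = shape.surface_points_weighted(2000)
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        margin = max((hi - lo).max() / 2, 3 * config.z_step)
        lo = lo - margin
        hi = hi + margin
    elif mesh is not None:
        lo = mesh.vertices.min(axis=0) - 3 * config.z_step
        hi = mesh.vertices.max(axis=0) + 3 * config.z_step
    else:
        lo = np.zeros(3)
        hi = np.ones(3)
    nx = int(np.ceil((hi[0] - lo[0]) / config.xy_pixel)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / config.xy_pixel)) + 1
    nz = int(np.ceil((hi[2] - lo[2]) / config.z_step)) + 1
    if nx * ny * nz > max_voxels:
        raise ValueError(f"stack size {nx * ny * nz} voxels over budget")
    origin = lo
    ch1 = np.zeros((nz, ny, nx), dtype=np.float64)
    ch2 = np.zeros_like(ch1)

    if shape is not None:
        xs = origin[0] + np.arange(nx) * config.xy_pixel
        ys = origin[1] + np.arange(ny) * config.xy_pixel
        zs = origin[2] + np.arange(nz) * config.z_step
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        sdf = shape.signed_distance(pts).reshape(nz, ny, nx)
        ch1[np.abs(sdf) < config.shell_half_width] = 1.0

    if mesh is not None:
        from .geometry import triangle_areas_normals

        areas, _ = triangle_areas_normals(mesh.vertices, mesh.triangles)
        density = 4.0 / config.xy_pixel ** 2  # samples per um^2
        n_per_tri = np.maximum(1, np.ceil(areas * density)).astype(int)
        tri_idx = np.repeat(np.arange(len(areas)), n_per_tri)
        n_tot = len(tri_idx)
        u = rng.random(n_tot)
        v = rng.random(n_tot)
        flip = u + v > 1
        u[flip] = 1 - u[flip]
        v[flip] = 1 - v[flip]
        t = mesh.triangles[tri_idx]
        p = (mesh.vertices[t[:, 0]] * (1 - u - v)[:, None]
             + mesh.vertices[t[:, 1]] * u[:, None]
             + mesh.vertices[t[:, 2]] * v[:, None])
        ii = np.round((p[:, 2] - origin[2]) / config.z_step).astype(int)
        jj = np.round((p[:, 1] - origin[1]) / config.xy_pixel).astype(int)
        kk = np.round((p[:, 0] - origin[0]) / config.xy_pixel).astype(int)
        ok = ((ii >= 0) & (ii < nz) & (jj >= 0) & (jj < ny)
              & (kk >= 0) & (kk < nx))
        np.add.at(ch2, (ii[ok], jj[ok], kk[ok]), 1.0)
        if ch2.max() > 0:
            ch2 /= ch2.max()

    if config.psf_sigma > 0:
        sig = (config.psf_sigma / config.z_step,
               config.psf_sigma / config.xy_pixel,
               config.psf_sigma / config.xy_pixel)
        ch1 = ndimage.gaussian_filter(ch1, sig)
        ch2 = ndimage.gaussian_filter(ch2, sig)
    if config.noise == "poisson":
        s = config.noise_scale
        ch1 = rng.poisson(ch1 * s).astype(np.float64) / s
        ch2 = rng.poisson(ch2 * s).astype(np.float64) / s

    meta = {"z_step": config.z_step, "xy_pixel": config.xy_pixel,
            "origin": origin.tolist()}
    if shape is not None:
        meta["particle"] = shape.to_dict()
    return Stack(ch1, ch2, np.asarray(origin, dtype=np.float64),
                 config.z_step, config.xy_pixel, meta)


def mask_receptor_channel(stack: Stack) -> Stack:
    """Zero the receptor channel wherever the particle channel is null
    (the acquisition-time masking convention).  Idempotent."""
    out = stack.copy()
    out.ch2[out.ch1 == 0] = 0.0
    return out


def save_stack(stack: Stack, path, sidecar=None):
    """Channel-interleaved multi-page TIFF plus a YAML sidecar of voxel
    geometry and ground truth."""
    import yaml

    nz = stack.ch1.shape[0]
    pages = np.empty((2 * nz,) + stack.ch1.shape[1:], dtype=np.float32)
    pages[0::2] = stack.ch1
    pages[1::2] = stack.ch2
    tifffile.imwrite(str(path), pages)
    side = str(path) + ".yaml" if sidecar is None else str(sidecar)
    with open(side, "w") as fh:
        yaml.safe_dump(stack.meta, fh)


def load_stack(path, sidecar=None) -> Stack:
    import yaml

    pages = tifffile.imread(str(path)).astype(np.float64)
    side = str(path) + ".yaml" if sidecar is None else str(sidecar)
    with open(side) as fh:
        meta = yaml.safe_load(fh)
    ch1 = pages[0::2]
    ch2 = pages[1::2]
    return Stack(ch1, ch2, np.asarray(meta["origin"], dtype=np.float64),
                 float(meta["z_step"]), float(meta["xy_pixel"]), meta)


# -- thresholds -----------------------------------------------------------


def _positive(img: np.ndarray) -> np.ndarray:
    """Signal mask: > 0 for clean synthetic stacks, Otsu otherwise.

    Synthetic renders (including our Poisson model, which has no dark
    counts) have an exactly-zero background, for which > 0 is the correct
    threshold; Otsu is the fallback for images with a continuous
    background, where it separates signal from noise floor.
    """
    if img.max() <= 0:
        return np.zeros_like(img, dtype=bool)
    if (img == 0).mean() > 0.5:
        return img > 0
    vals = img[img > 0]
    if vals.min() == vals.max():
        return img > 0
    from skimage.filters import threshold_otsu

    try:
        t = threshold_otsu(img)
    except ValueError:
        return img > 0
    if t <= 0:
        return img > 0
    return img > t


# -- particle detection ---------------------------------------------------


def detect_particles(stack: Stack, expected_radius_range,
                     plane_stride: int = 3, min_planes: int = 3):
    """Locate spherical particles by a per-plane circular Hough transform.

    Circles are accumulated every ``plane_stride`` planes over the pixel
    radius range, grouped by lateral center clustering (tolerance R/4) and
    fitted to a sphere: for circles of radius r_i in planes z_i,
    r_i^2 + z_i^2 is linear in z_i with slope 2*z_c.  Returns a list of
    :class:`DetectedParticle`.
    """
    from skimage.transform import hough_circle, hough_circle_peaks

    r_lo, r_hi = expected_radius_range
    pix = stack.xy_pixel
    radii_px = np.arange(max(3, int(r_lo / pix)), int(np.ceil(r_hi / pix)) + 1)
    pos1 = _positive(stack.ch1)
    circles = []  # (z_um, cx_um, cy_um, r_um, strength)
    nz = stack.ch1.shape[0]
    stride = max(1, min(plane_stride, nz // 6))
    for k in range(0, nz, stride):
        plane = pos1[k]
        if plane.sum() < 8:
            continue
        acc = hough_circle(plane, radii_px)
        accums, cxs, cys, rs = hough_circle_peaks(acc, radii_px,
                                                  total_num_peaks=4,
                                                  threshold=0.3)
        for a, cx, cy, r in zip(accums, cxs, cys, rs):
            circles.append((stack.origin[2] + k * stack.z_step,
                            stack.origin[0] + cx * pix,
                            stack.origin[1] + cy * pix,
                            r * pix, a))
    if not circles:
        return []
    circles = np.array(circles)
    # cluster by lateral center
    tol = max(0.25 * 0.5 * (r_lo + r_hi), 2 * pix)
    used = np.zeros(len(circles), dtype=bool)
    out = []
    strengths = []
    order = np.argsort(-circles[:, 4])
    for i in order:
        if used[i]:
            continue
        d = np.hypot(circles[:, 1] - circles[i, 1],
                     circles[:, 2] - circles[i, 2])
        grp = (~used) & (d < tol)
        used |= grp
        g = circles[grp]
        if len(g) < min_planes:
            continue
        z = g[:, 0]
        if len(np.unique(z)) < 2:
            continue
        r2z2 = g[:, 3] ** 2 + z ** 2
        b, a = np.polyfit(z, r2z2, 1)
        zc = b / 2.0
        R2 = a + zc * zc
        if R2 <= 0:
            continue
        R = float(np.sqrt(R2))
        if not (0.5 * r_lo <= R <= 2.0 * r_hi):
            continue
        w = g[:, 4]
        center = np.array([np.average(g[:, 1], weights=w),
                           np.average(g[:, 2], weights=w), zc])
        out.append(DetectedParticle(center=center, radius=R))
        strengths.append(float(w.sum()))
    if out:
        best = max(strengths)
        out = [d for d, st_ in zip(out, strengths) if st_ >= 0.4 * best]
    return out


# -- engulfment from stacks -----------------------------------------------


def engulfed_fraction_stack(stack: Stack, particle: DetectedParticle,
                            R: float | None = None,
                            coloc_voxels: int = 1) -> float:
    """Engulfed surface percentage from channel co-localisation.

    Within the sphere S0 of radius 4R/3 about the particle center, each
    particle-shell (ch1) voxel counts as engulfed if any receptor-positive
    (ch2) voxel lies within ``coloc_voxels`` xy-pixels of it in the same
    imaging plane.  The default reach of one pixel was calibrated on
    noiseless rendered half-cups against mesh ground truth; axial reach
    (a full 0.4 um z-step) or wider lateral reach systematically
    overestimates uptake.  Raises if no shell voxel falls inside S0.
    """
    R = particle.radius if R is None else R
    pos1 = _positive(stack.ch1)
    pos2 = _positive(stack.ch2)
    nz, ny, nx = stack.ch1.shape
    xs = stack.origin[0] + np.arange(nx) * stack.xy_pixel
    ys = stack.origin[1] + np.arange(ny) * stack.xy_pixel
    zs = stack.origin[2] + np.arange(nz) * stack.z_step
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    c = particle.center
    inside = ((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
              <= (4.0 * R / 3.0) ** 2)
    shell = pos1 & inside
    if not np.any(shell):
        raise ValueError("no particle-shell voxels inside S0")
    lateral = np.zeros((1, 3, 3), dtype=bool)
    lateral[0] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    near2 = ndimage.binary_dilation(pos2, lateral,
                                    iterations=coloc_voxels)
    return float(100.0 * (shell & near2).sum() / shell.sum())


# -- height profiles from stacks ------------------------------------------


def height_profile_stack(stack: Stack, particle: DetectedParticle,
                         annulus_px: int = 3) -> CupProfile:
    """24-segment membrane height profile from a masked stack.

    For each angular segment, the highest plane in which receptor signal is
    present in the particle's immediate neighborhood (an annulus
    ``annulus_px`` xy-pixels outside the particle's cross-section circle in
    each plane).  Heights are plane counts above the bottom contact plane,
    times the z-step.
    """
    masked = mask_receptor_channel(stack)
    pos2 = _positive(masked.ch2)
    pos1 = _positive(stack.ch1)
    c = particle.center
    R = particle.radius
    nz, ny, nx = stack.ch1.shape
    # bottom contact plane: lowest plane with particle signal
    planes_with = np.flatnonzero(pos1.any(axis=(1, 2)))
    if not len(planes_with):
        return CupProfile(np.zeros(N_SEGMENTS), particle=particle,
                          flagged=True)
    k_bottom = planes_with[0]
    xs = stack.origin[0] + np.arange(nx) * stack.xy_pixel
    ys = stack.origin[1] + np.arange(ny) * stack.xy_pixel
    xx, yy = np.meshgrid(xs, ys, indexing="xy")
    rho = np.hypot(xx - c[0], yy - c[1])
    ang = np.arctan2(yy - c[1], xx - c[0])
    seg_of = np.clip(((ang + np.pi) / (2 * np.pi) * N_SEGMENTS).astype(int),
                     0, N_SEGMENTS - 1)
    best_plane = np.full(N_SEGMENTS, -1, dtype=int)
    for k in range(nz):
        dz = stack.origin[2] + k * stack.z_step - c[2]
        if abs(dz) >= R:
            r_plane = 0.0
        else:
            r_plane = np.sqrt(R * R - dz * dz)
        annulus = (pos2[k]
                   & (rho >= r_plane)
                   & (rho <= r_plane + annulus_px * stack.xy_pixel))
        if not annulus.any():
            continue
        segs = np.unique(seg_of[annulus])
        best_plane[segs] = np.maximum(best_plane[segs], k)
    heights = np.where(best_plane >= 0,
                       (best_plane - k_bottom + 1) * stack.z_step, 0.0)
    heights = np.maximum(heights, 0.0)
    flagged = bool(np.all(best_plane < 0))
    prof = CupProfile(heights, particle=particle, flagged=flagged)
    prof.engulfed_pct = float(100.0 * heights.mean() / (2 * R))
    return prof


def equator_intensity_variability(stack: Stack, particle: DetectedParticle,
                                  annulus_px: int = 3,
                                  uptake_pct: float | None = None) -> float:
    """Angular variability of receptor intensity in the equator plane.

    The alternative (less accurate) cup-variability measure: the particle's
    equator plane is cut into 24 angular segments in an annulus just
    outside the particle circle; the statistic is the standard deviation of
    per-segment summed intensity divided by the mean.  Only particles with
    uptake between 30 and 70% are analysed.
    """
    pct = particle.engulfed_pct if uptake_pct is None else uptake_pct
    if not (30.0 <= pct <= 70.0):
        raise ValueError(
            f"uptake {pct:.1f}% outside the 30-70% analysis window")
    masked = mask_receptor_channel(stack)
    c = particle.center
    R = particle.radius
    k_eq = int(round((c[2] - stack.origin[2]) / stack.z_step))
    k_eq = np.clip(k_eq, 0, stack.ch1.shape[0] - 1)
    nz, ny, nx = stack.ch1.shape
    xs = stack.origin[0] + np.arange(nx) * stack.xy_pixel
    ys = stack.origin[1] + np.arange(ny) * stack.xy_pixel
    xx, yy = np.meshgrid(xs, ys, indexing="xy")
    rho = np.hypot(xx - c[0], yy - c[1])
    ang = np.arctan2(yy - c[1], xx - c[0])
    seg_of = np.clip(((ang + np.pi) / (2 * np.pi) * N_SEGMENTS).astype(int),
                     0, N_SEGMENTS - 1)
    annulus = (rho >= R) & (rho <= R + annulus_px * stack.xy_pixel)
    intens = np.zeros(N_SEGMENTS)
    np.add.at(intens, seg_of[annulus], masked.ch2[k_eq][annulus])
    mean = intens.mean()
    if mean <= 0:
        return 0.0
    return float(intens.std() / mean)
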