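"""Seeded synthetic enamel orientation fields.

Real inner enamel consists of ~5-um-wide rods of morphologically parallel
apatite nanocrystals whose c-axes are *not* co-oriented: the orientation
drifts gradually from crystal to crystal, with adjacent-crystal
mis-orientations of mostly 1-30 degrees and an overall within-rod angle
spread between 30 and 90 degrees (never zero).  The space-filling interrod
is a single, co-oriented continuum (c' = +30 degrees from vertical in the
maps this generator emulates), rods are partly wrapped in a non-dichroic
organic sheath, and in inner enamel rods decussate: alternating bands run
in-plane and out-of-plane (Hunter-Schreger bands).

This module generates orientation fields with that statistical structure,
fully reproducible from a config + seed, to serve as ground truth for the
dichroism forward/inverse model and the mis-orientation statistics.

Two drift models are provided.  :func:`generate_rod_orientations` is a
bounded random walk on the director sphere (for 1D scans and line
profiles): each step rotates the previous director by a Gaussian-magnitude
angle about a uniformly random axis, reflected back when the walk strays
more than a target spread from the start.  :func:`generate_field` fills
rod interiors with an isotropic smooth 2D tangent-displacement field
instead, so that orientation changes gradually in *both* image directions
-- the property the stride-doubling histograms probe.  In either case the
field phenomenology is the target, not any claim about amelogenesis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .dichroism import PICMap
from .orientation import angles_to_director, fold_c_prime, hsb_to_rgb, angles_to_hsb

__all__ = [
    "EnamelConfig",
    "GroundTruth",
    "generate_rod_orientations",
    "generate_field",
    "render",
    "director_to_angles",
]

SHEATH_LABEL = -1
INTERROD_LABEL = 0


@dataclass
class EnamelConfig:
    """Parameters of the synthetic field.

    image_shape : (rows, cols) in pixels.
    pixel_size_nm : physical pixel size; 60 nm matches the survey maps.
    rod_diameter_um : rod head diameter (circular heads), default 5 um.
    interrod_c_prime_deg / interrod_gamma_deg : the single co-oriented
        interrod orientation (+30 in-plane by default).
    interrod_jitter_deg : half-width of the clipped per-pixel jitter on the
        interrod c' angle (keeps any interrod pair within 2*jitter).
    sheath_thickness_px : thickness of the masked organic sheath ring.
    sheath_coverage : fraction of each rod's boundary wrapped in sheath;
        < 1 leaves unsheathed rod-interrod contacts whose large
        mis-orientations produce the 30-60 degree histogram spikes.
    blend_fraction : fraction of the unsheathed boundary arc over which the
        rod orientation blends gradually into the interrod (the head-to-tail
        transition); the rest of the arc is an abrupt contact.
    blend_ring_px : width of that blend ring, in pixels.
    step_sigma_deg : sd of the per-pixel random-walk rotation.
    min_spread_deg / target_spread_deg : per-rod target spreads are drawn
        uniformly in [min_spread_deg + 10, target_spread_deg] so that long
        walks (which reach at least 80% of their target) realise spreads in
        the reported 30-90 degree range and never zero.
    decussation : per-band rod-axis mode, "in-plane" or "out-of-plane";
        the image is split into len(decussation) equal horizontal bands.
    seed : generation seed; the whole field is a pure function of (cfg).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 60.0
    rod_diameter_um: float = 5.0
    interrod_c_prime_deg: float = 30.0
    interrod_gamma_deg: float = 0.0
    interrod_jitter_deg: float = 1.0
    sheath_thickness_px: int = 2
    sheath_coverage: float = 0.8
    blend_fraction: float = 0.5
    blend_ring_px: int = 3
    step_sigma_deg: float = 2.0
    min_spread_deg: float = 30.0
    target_spread_deg: float = 90.0
    n_rods: int | None = None
    decussation: tuple[str, ...] = ("in-plane",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rod_diameter_um <= 0:
            raise ValueError("rod_diameter_um must be positive")
        if self.step_sigma_deg <= 0:
            raise ValueError("step_sigma_deg must be positive")
        if not (30.0 <= self.target_spread_deg <= 90.0):
            raise ValueError("target_spread_deg must lie in [30, 90]")
        if not (0.0 <= self.sheath_coverage <= 1.0):
            raise ValueError("sheath_coverage must lie in [0, 1]")
        for mode in self.decussation:
            if mode not in ("in-plane", "out-of-plane"):
                raise ValueError(f"unknown decussation mode {mode!r}")
        rod_px = self.rod_diameter_um * 1000.0 / self.pixel_size_nm
        if self.n_rods != 0 and rod_px > min(self.image_shape):
            raise ValueError("rod diameter exceeds the image")

    @property
    def rod_radius_px(self) -> float:
        return self.rod_diameter_um * 1000.0 / self.pixel_size_nm / 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["decussation"] = list(self.decussation)
        return d


@dataclass
class GroundTruth:
    """A generated field: the PIC map, rod labels, and realised spreads.

    rod_labels : integer grid; 0 = interrod, k >= 1 = rod k, -1 = sheath.
    rod_spreads_deg : realised max-pairwise angle spread per rod label.
    """

    pic_map: PICMap
    rod_labels: np.ndarray
    rod_spreads_deg: dict[int, float]
    config: EnamelConfig

    def __post_init__(self) -> None:
        if self.rod_labels.shape != self.pic_map.shape:
            raise ValueError("rod_labels and pic_map must be congruent")


def director_to_angles(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`enamelpic.orientation.angles_to_director`.

    Chooses the antipode with gamma >= 0 (the director convention).
    """
    d = np.asarray(d, dtype=float)
    flip = d[..., 1] < 0
    d = np.where(flip[..., None], -d, d)
    gamma = np.degrees(np.arcsin(np.clip(d[..., 1], -1.0, 1.0)))
    c_prime = fold_c_prime(np.degrees(np.arctan2(d[..., 0], d[..., 2])))
    return c_prime, gamma


def _rotate_about(vec: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of a single 3-vector."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return vec * c + np.cross(axis, vec) * s + axis * np.dot(axis, vec) * (1.0 - c)


def _great_circle_toward(vec: np.ndarray, target: np.ndarray, angle_rad: float) -> np.ndarray:
    """Move ``vec`` along the great circle toward ``target`` by ``angle_rad``."""
    axis = np.cross(vec, target)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        return vec
    return _rotate_about(vec, axis / n, angle_rad)


def generate_rod_orientations(
    n_pixels: int,
    start_c_prime_deg: float,
    start_gamma_deg: float,
    step_sigma_deg: float,
    target_spread_deg: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Bounded random walk of directors; returns (c_prime_deg, gamma_deg) arrays.

    Each step rotates the previous director by an angle ~ N(0, step_sigma)
    about a uniformly random axis.  The walk is confined to a spherical cap
    of *radius* ``target_spread_deg / 2`` around the start (reflected back
    across the boundary when it strays further), so consecutive
    mis-orientations stay small and the realised max-pairwise spread -- the
    cap diameter -- is at most ``target_spread_deg`` (and, for long walks,
    at least ~80% of it).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = angles_to_director(start_c_prime_deg, start_gamma_deg)
    target = np.deg2rad(target_spread_deg / 2.0)
    out = np.empty((n_pixels, 3))
    cur = start.copy()
    out[0] = cur
    axes = rng.normal(size=(n_pixels, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    steps = np.deg2rad(rng.normal(0.0, step_sigma_deg, size=n_pixels))
    for k in range(1, n_pixels):
        nxt = _rotate_about(cur, axes[k], steps[k])
        # director distance from the start (sign-invariant)
        d = np.arccos(np.clip(abs(np.dot(nxt, start)), 0.0, 1.0))
        if d > target:
            # reflect across the spherical cap boundary, toward the start
            ref = start if np.dot(nxt, start) >= 0 else -start
            nxt = _great_circle_toward(nxt, ref, 2.0 * (d - target))
        cur = nxt / np.linalg.norm(nxt)
        out[k] = cur
    return director_to_angles(out)


def _max_pairwise_spread(directors: np.ndarray, rng: np.random.Generator, exact_limit: int = 5000) -> float:
    """Max pairwise director distance; subsampled above ``exact_limit`` points."""
    n = directors.shape[0]
    if n < 2:
        return 0.0
    if n > exact_limit:
        idx = rng.choice(n, size=exact_limit, replace=False)
        directors = directors[idx]
        n = exact_limit
    max_cos = 1.0
    for i0 in range(0, n, 512):
        blk = directors[i0 : i0 + 512]
        dots = np.abs(blk @ directors.T)
        max_cos = min(max_cos, float(dots.min()))
    return float(np.degrees(np.arccos(np.clip(max_cos, -1.0, 1.0))))


def _tangent_basis(v0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the tangent plane at director ``v0``."""
    helper = np.array([1.0, 0.0, 0.0]) if abs(v0[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross(v0, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v0, e1)
    return e1, e2


def _smooth_rod_field(
    inside: np.ndarray,
    start: np.ndarray,
    target_spread_deg: float,
    min_spread_deg: float,
    correlation_px: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Directors for a rod's pixels from an isotropic smooth displacement field.

    Two Gaussian random fields (correlation length ``correlation_px``) give
    tangent-plane displacement components; they are scaled so the max
    pairwise tangent distance over the rod equals the target spread, then
    the start director is rotated along each pixel's tangent direction.
    Returns (directors (n, 3), realised max-pairwise spread in degrees).
    """
    from scipy.ndimage import gaussian_filter

    h, w = inside.shape
    sel = inside.ravel()
    n = int(sel.sum())
    for attempt in range(5):
        f1 = gaussian_filter(rng.standard_normal((h, w)), correlation_px, mode="nearest").ravel()[sel]
        f2 = gaussian_filter(rng.standard_normal((h, w)), correlation_px, mode="nearest").ravel()[sel]
        pts = np.column_stack([f1, f2])
        pts -= pts.mean(axis=0)
        # pairwise diameter of the 2D point cloud, via its convex hull
        if n >= 4:
            from scipy.spatial import ConvexHull

            hull = pts[ConvexHull(pts).vertices]
        else:
            hull = pts
        diam = 0.0
        for p in hull:
            diam = max(diam, float(np.hypot(*(hull - p).T).max()))
        if diam <= 0:
            continue
        scale = target_spread_deg / diam
        alpha, beta = pts[:, 0] * scale, pts[:, 1] * scale
        rho = np.hypot(alpha, beta)
        rho_clamped = np.minimum(rho, 88.0)  # keep each pixel < 90 deg from start
        safe = np.where(rho > 0, rho, 1.0)
        e1, e2 = _tangent_basis(start)
        tangent = (alpha / safe)[:, None] * e1 + (beta / safe)[:, None] * e2
        rad = np.deg2rad(rho_clamped)
        dirs = np.cos(rad)[:, None] * start + np.sin(rad)[:, None] * tangent
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        spread = _max_pairwise_spread(dirs, rng)
        if spread >= min_spread_deg or n < 50:
            return dirs, spread
    return dirs, spread


def _hex_rod_centers(shape: tuple[int, int], radius_px: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice of rod centers covering the image."""
    h, w = shape
    pitch = 2.0 * radius_px * 1.12  # slightly spaced so interrod percolates
    rows = []
    y = radius_px * 0.9
    row_i = 0
    while y < h - radius_px * 0.3:
        x0 = radius_px * 0.9 + (pitch / 2.0 if row_i % 2 else 0.0)
        x = x0
        while x < w - radius_px * 0.3:
            rows.append((y, x))
            x += pitch
        y += pitch * np.sqrt(3.0) / 2.0
        row_i += 1
    centers = np.asarray(rows, dtype=float)
    if len(centers):
        centers += rng.uniform(-0.15 * radius_px, 0.15 * radius_px, size=centers.shape)
    return centers


def generate_field(cfg: EnamelConfig) -> GroundTruth:
    """Generate a full synthetic enamel field from the config.

    Circular rod heads are placed on a jittered hexagonal lattice; each rod
    is filled with an isotropic smooth orientation field whose max pairwise
    spread is drawn per rod (see class docs).  Interrod pixels carry the single interrod
    orientation with a small clipped jitter; partial sheath rings are
    masked; rods in out-of-plane decussation bands start with gamma near 90
    and render dark (red-to-black).
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    radius = cfg.rod_radius_px

    c_prime = np.full((h, w), cfg.interrod_c_prime_deg, dtype=float)
    gamma = np.full((h, w), cfg.interrod_gamma_deg, dtype=float)
    mask = np.ones((h, w), dtype=bool)
    labels = np.zeros((h, w), dtype=int)

    # clipped interrod jitter: any interrod pair stays within 2*jitter degrees
    jit = np.clip(
        rng.normal(0.0, cfg.interrod_jitter_deg, size=(h, w)),
        -cfg.interrod_jitter_deg,
        cfg.interrod_jitter_deg,
    )
    c_prime += jit
    gamma = np.clip(gamma, 0.0, 90.0)

    centers = _hex_rod_centers((h, w), radius, rng) if cfg.n_rods != 0 else np.empty((0, 2))
    if cfg.n_rods is not None and len(centers) > cfg.n_rods:
        centers = centers[: cfg.n_rods]

    n_bands = len(cfg.decussation)
    band_height = h / n_bands
    yy, xx = np.mgrid[0:h, 0:w]
    rod_spreads: dict[int, float] = {}

    for k, (cy, cx) in enumerate(centers, start=1):
        band = min(int(cy // band_height), n_bands - 1)
        mode = cfg.decussation[band]
        dist = np.hypot(yy - cy, xx - cx)
        inside = dist <= radius
        if not inside.any():
            continue
        phi = np.arctan2(yy - cy, xx - cx)  # (-pi, pi]

        # per-rod walk parameters
        if mode == "in-plane":
            start_cp = float(rng.uniform(-90.0, 90.0))
            start_g = float(rng.uniform(0.0, 15.0))
        else:  # out-of-plane: axis near the beam, dark red-to-black pixels
            start_cp = float(rng.uniform(-90.0, 90.0))
            start_g = float(rng.uniform(65.0, 88.0))
        lo = min(cfg.min_spread_deg + 10.0, cfg.target_spread_deg)
        target = float(rng.uniform(lo, cfg.target_spread_deg))

        ridx = np.flatnonzero(inside.ravel())
        dirs, spread = _smooth_rod_field(
            inside,
            angles_to_director(start_cp, start_g),
            target,
            cfg.min_spread_deg,
            max(radius / 2.0, 2.0),
            rng,
        )
        cps, gs = director_to_angles(dirs)
        rod_spreads[k] = spread
        c_prime.ravel()[ridx] = cps
        gamma.ravel()[ridx] = gs
        labels[inside] = k

        # boundary arcs: sheath (masked), blend (gradual head-to-tail), abrupt
        phi0 = rng.uniform(-np.pi, np.pi)
        arc = np.mod(phi - phi0, 2.0 * np.pi) / (2.0 * np.pi)  # position on circle [0,1)
        sheath_ring = (
            (dist > radius)
            & (dist <= radius + cfg.sheath_thickness_px)
            & (arc < cfg.sheath_coverage)
        )
        mask[sheath_ring] = False
        labels[sheath_ring] = SHEATH_LABEL

        if cfg.blend_ring_px > 0 and cfg.blend_fraction > 0:
            rest = 1.0 - cfg.sheath_coverage
            blend_arc = (arc >= cfg.sheath_coverage) & (
                arc < cfg.sheath_coverage + cfg.blend_fraction * rest
            )
            ring = inside & blend_arc & (dist > radius - cfg.blend_ring_px)
            if ring.any():
                wgt = ((radius - dist[ring]) / cfg.blend_ring_px)[:, None]  # 0 at edge
                d_rod = angles_to_director(c_prime[ring], gamma[ring])
                d_ir = angles_to_director(cfg.interrod_c_prime_deg, cfg.interrod_gamma_deg)
                # sign-align the interrod director with each rod director
                sgn = np.sign(d_rod @ d_ir)
                sgn[sgn == 0] = 1.0
                blended = wgt * d_rod + (1.0 - wgt) * sgn[:, None] * d_ir[None, :]
                blended /= np.linalg.norm(blended, axis=1, keepdims=True)
                bc, bg = director_to_angles(blended)
                c_prime[ring] = bc
                gamma[ring] = bg

    c_prime = fold_c_prime(c_prime)
    gamma = np.clip(gamma, 0.0, 90.0)
    c_prime[~mask] = np.nan
    gamma[~mask] = np.nan
    pic = PICMap(c_prime, gamma, mask, cfg.pixel_size_nm)
    return GroundTruth(pic, labels, rod_spreads, cfg)


def render(gt: GroundTruth | PICMap) -> np.ndarray:
    """Render a field as an 8-bit RGB image with the standard legend.

    Hue encodes c' (cyan vertical, green +30, ...), brightness encodes the
    off-plane angle; masked (sheath) pixels are black.  Deterministic.
    """
    pic = gt.pic_map if isinstance(gt, GroundTruth) else gt
    cp = np.where(pic.mask, pic.c_prime_deg, 0.0)
    g = np.where(pic.mask, pic.gamma_deg, 90.0)  # brightness 0 -> black
    hue, sat, bri = angles_to_hsb(cp, g)
    bri = np.where(pic.mask, bri, 0.0)
    return hsb_to_rgb(hue, sat, bri)
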