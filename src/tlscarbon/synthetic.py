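"""Synthetic per-tree point clouds with closed-form structural ground truth.

The generator emulates leaf-off woody clouds of tall open-grown conifers
(giant sequoia-like): a tapered near-conical trunk with a basal buttress
flare, a deep crown of branch and crown-envelope points, metre units, z-up.
Every quantity a downstream estimator recovers — height, the three stem
diameters, crown volume, woody volume — is available analytically, so the
whole pipeline is testable without any field data.

Geometry
--------
The trunk is a surface of revolution.  Below breast height (1.3 m) the
profile radius is constant at ``r_b``; above it tapers as

    r(h) = r_b * ((H - h) / (H - 1.3)) ** taper_exponent,

and everywhere a buttress flare ``B * (1 - h/F)**2`` (zero above the flare
height ``F``) is added.  ``r_b`` is chosen so that the total diameter at
1.3 m equals the requested ``dbh_true``.  Trunk volume is the closed-form
integral of ``pi * r(h)**2``.

Branches are explicit cylinders inside the crown whose summed volume is a
stated fraction of trunk volume (default 15%), keeping the woody-volume
truth analytic.  Crown-envelope points sample the surface and interior of a
conoid, paraboloid or prolate spheroid, whose volumes are classical solids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from .pointcloud_io import PointCloud, TreeRecord

BREAST_HEIGHT = 1.3

CrownShape = Literal["conoid", "paraboloid", "prolate_spheroid"]

#: crown solid volume as a multiple of pi * R^2 * L (R = max radius, L = depth)
_CROWN_VOLUME_FACTOR = {
    "conoid": 1.0 / 3.0,
    "paraboloid": 1.0 / 2.0,
    "prolate_spheroid": 2.0 / 3.0,
}


@dataclass(frozen=True)
class SyntheticTreeSpec:
    """Parameters of one synthetic tree.  All lengths in metres."""

    total_height: float = 45.0
    dbh_true: float = 1.6
    buttress_extra_radius: float = 0.25
    flare_height: float = 3.0
    taper_exponent: float = 1.0
    crown_base_height: float = 6.0
    crown_shape: CrownShape = "conoid"
    crown_max_radius: float = 4.5
    point_spacing: float = 0.05
    noise_sd: float = 0.005
    occlusion_fraction: float = 0.0
    lean_deg: float = 0.0
    branch_volume_fraction: float = 0.15
    n_branches: int = 30
    seed: int = 0

    def validate(self) -> None:
        if not (self.total_height > self.crown_base_height):
            raise ValueError("total_height must exceed crown_base_height")
        if not (self.crown_base_height > self.flare_height):
            raise ValueError("crown_base_height must exceed flare_height")
        if not (self.flare_height > 1.4):
            raise ValueError("flare_height must exceed 1.4 m")
        if not (0.0 <= self.occlusion_fraction < 1.0):
            raise ValueError("occlusion_fraction must lie in [0, 1)")
        if not (self.point_spacing > 0):
            raise ValueError("point_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dbh_true <= 0:
            raise ValueError("dbh_true must be positive")
        if self.crown_shape not in _CROWN_VOLUME_FACTOR:
            raise ValueError(f"unknown crown_shape {self.crown_shape!r}")
        if not (0.0 <= self.branch_volume_fraction < 1.0):
            raise ValueError("branch_volume_fraction must lie in [0, 1)")
        if self.buttress_extra_radius < 0:
            raise ValueError("buttress_extra_radius must be non-negative")
        if self._breast_radius() <= 0:
            raise ValueError(
                "dbh_true too small for the requested buttress flare at 1.3 m"
            )

    # -- radius profile ----------------------------------------------------

    def _flare(self, h: np.ndarray | float) -> np.ndarray | float:
        B, F = self.buttress_extra_radius, self.flare_height
        frac = np.clip(1.0 - np.asarray(h, dtype=float) / F, 0.0, None)
        return B * frac**2

    def _breast_radius(self) -> float:
        return self.dbh_true / 2.0 - float(self._flare(BREAST_HEIGHT))

    def trunk_radius(self, h: np.ndarray | float) -> np.ndarray:
        """Total profile radius (taper + flare) at height(s) ``h``."""
        h = np.asarray(h, dtype=float)
        H, t = self.total_height, self.taper_exponent
        rb = self._breast_radius()
        base = np.where(
            h <= BREAST_HEIGHT,
            rb,
            rb * (np.clip(H - h, 0.0, None) / (H - BREAST_HEIGHT)) ** t,
        )
        return base + self._flare(h)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic counterparts of the TLS-derived structural metrics."""

    height_true: float
    dbh_true: float
    dtb_true: float
    fdbh_true: float
    trunk_volume_true: float
    crown_volume_true: float
    branch_volume_true: float

    @property
    def woody_volume_true(self) -> float:
        return self.trunk_volume_true + self.branch_volume_true


# ---------------------------------------------------------------------------
# closed-form trunk volume
# ---------------------------------------------------------------------------

def _trunk_volume_closed_form(spec: SyntheticTreeSpec) -> float:
    """pi * integral of trunk_radius(h)^2 over [0, H], in closed form.

    The profile is piecewise: constant + flare on [0, 1.3], taper + flare on
    [1.3, F], pure taper on [F, H].  The flare factor (1 - h/F)^k integrates
    as a polynomial; the cross term with the taper power expands via
    (1 - h/F) = ((H - h) - (H - F)) / F into pure powers of (H - h).
    """
    H, F, t = spec.total_height, spec.flare_height, spec.taper_exponent
    B = spec.buttress_extra_radius
    rb = spec._breast_radius()
    bh = BREAST_HEIGHT

    def flare_poly_int(lo: float, hi: float, k: int) -> float:
        # integral of (1 - h/F)^k dh over [lo, hi]
        return F / (k + 1) * ((1 - lo / F) ** (k + 1) - (1 - hi / F) ** (k + 1))

    # [0, 1.3]: (rb + B(1-h/F)^2)^2
    seg_a = (
        rb**2 * bh
        + 2 * rb * B * flare_poly_int(0.0, bh, 2)
        + B**2 * flare_poly_int(0.0, bh, 4)
    )

    scale = (H - bh) ** t  # taper denominator

    def power_int(lo: float, hi: float, s: float) -> float:
        # integral of (H - h)^s dh over [lo, hi]
        return ((H - lo) ** (s + 1) - (H - hi) ** (s + 1)) / (s + 1)

    # [1.3, F]: rb^2 u^2t + 2 rb B u^t (1-h/F)^2 + B^2 (1-h/F)^4, u = (H-h)/(H-1.3)
    hf = H - F
    seg_b = (
        rb**2 / scale**2 * power_int(bh, F, 2 * t)
        + 2 * rb * B / (scale * F**2) * (
            power_int(bh, F, t + 2)
            - 2 * hf * power_int(bh, F, t + 1)
            + hf**2 * power_int(bh, F, t)
        )
        + B**2 * flare_poly_int(bh, F, 4)
    )

    # [F, H]: pure taper
    seg_c = rb**2 / scale**2 * power_int(F, H, 2 * t)

    return math.pi * (seg_a + seg_b + seg_c)


def _crown_radius_profile(spec: SyntheticTreeSpec, h: np.ndarray) -> np.ndarray:
    """Crown envelope radius at height(s) h within [crown_base, H]."""
    cb, H, R = spec.crown_base_height, spec.total_height, spec.crown_max_radius
    L = H - cb
    rel = np.clip((H - np.asarray(h, dtype=float)) / L, 0.0, 1.0)
    if spec.crown_shape == "conoid":
        return R * rel
    if spec.crown_shape == "paraboloid":
        return R * np.sqrt(rel)
    # prolate spheroid: vertical semi-axis L/2 centred at cb + L/2
    u = (np.asarray(h, dtype=float) - cb - L / 2) / (L / 2)
    return R * np.sqrt(np.clip(1.0 - u**2, 0.0, 1.0))


def ground_truth(spec: SyntheticTreeSpec) -> GroundTruth:
    """Closed-form structural truth for ``spec`` (upright, noise-free tree)."""
    spec.validate()
    H, cb, R = spec.total_height, spec.crown_base_height, spec.crown_max_radius
    L = H - cb
    trunk_v = _trunk_volume_closed_form(spec)
    crown_v = _CROWN_VOLUME_FACTOR[spec.crown_shape] * math.pi * R**2 * L
    dbh = 2.0 * float(spec.trunk_radius(BREAST_HEIGHT))
    dtb = 2.0 * float(spec.trunk_radius(4.25))  # midpoint of the 4.0-4.5 m slice
    return GroundTruth(
        height_true=H,
        dbh_true=dbh,
        dtb_true=dtb,
        fdbh_true=dbh,  # circular cross-section: equivalent-area diameter = DBH
        trunk_volume_true=trunk_v,
        crown_volume_true=crown_v,
        branch_volume_true=spec.branch_volume_fraction * trunk_v,
    )


# ---------------------------------------------------------------------------
# point sampling
# ---------------------------------------------------------------------------

def _sample_surface_of_revolution(
    rng: np.random.Generator,
    heights: np.ndarray,
    radii: np.ndarray,
    spacing: float,
) -> np.ndarray:
    """Rings of points on a surface of revolution, ~one point per spacing^2."""
    pts = []
    for h, r in zip(heights, radii):
        if r <= 0:
            continue
        n = max(3, int(round(2 * math.pi * r / spacing)))
        theta = rng.uniform(0, 2 * math.pi) + np.arange(n) * (2 * math.pi / n)
        pts.append(
            np.column_stack([r * np.cos(theta), r * np.sin(theta), np.full(n, h)])
        )
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def _sample_branches(
    rng: np.random.Generator, spec: SyntheticTreeSpec, target_volume: float
) -> tuple[np.ndarray, float]:
    """Explicit cylinder branches inside the crown; returns (points, volume)."""
    if target_volume <= 0 or spec.n_branches == 0:
        return np.empty((0, 3)), 0.0
    cb, H = spec.crown_base_height, spec.total_height
    n = spec.n_branches
    h0 = rng.uniform(cb, cb + 0.9 * (H - cb), size=n)
    azim = rng.uniform(0, 2 * math.pi, size=n)
    droop = rng.uniform(-0.35, 0.1, size=n)  # radians below horizontal
    # keep branch tips inside the crown envelope: radial reach from the stem
    # surface must not exceed the local crown radius
    trunk_r = spec.trunk_radius(h0)
    max_len = np.maximum(0.3, _crown_radius_profile(spec, h0) - trunk_r)
    lengths = np.maximum(0.3, rng.uniform(0.5, 0.95, size=n) * max_len)
    weights = rng.uniform(0.5, 1.5, size=n)
    vols = target_volume * weights / weights.sum()
    radii = np.sqrt(vols / (math.pi * lengths))
    spacing = 3.0 * spec.point_spacing
    pts = []
    for i in range(n):
        r0 = float(spec.trunk_radius(h0[i]))
        axis = np.array(
            [
                math.cos(azim[i]) * math.cos(droop[i]),
                math.sin(azim[i]) * math.cos(droop[i]),
                math.sin(droop[i]),
            ]
        )
        origin = np.array([r0 * math.cos(azim[i]), r0 * math.sin(azim[i]), h0[i]])
        n_axial = max(2, int(lengths[i] / spacing))
        n_circ = max(3, int(round(2 * math.pi * radii[i] / spacing)))
        s = np.linspace(0, lengths[i], n_axial)
        phi = rng.uniform(0, 2 * math.pi) + np.arange(n_circ) * 2 * math.pi / n_circ
        # orthonormal frame around the branch axis
        ref = np.array([0.0, 0.0, 1.0])
        u = np.cross(axis, ref)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        ring = radii[i] * (np.outer(np.cos(phi), u) + np.outer(np.sin(phi), v))
        centres = origin + np.outer(s, axis)
        pts.append((centres[:, None, :] + ring[None, :, :]).reshape(-1, 3))
    return np.vstack(pts), float(vols.sum())


def _sample_crown_envelope(
    rng: np.random.Generator, spec: SyntheticTreeSpec
) -> np.ndarray:
    """Points on (and sparsely inside) the crown solid."""
    cb, H = spec.crown_base_height, spec.total_height
    spacing = 3.0 * spec.point_spacing
    heights = np.arange(cb, H, spacing)
    radii = _crown_radius_profile(spec, heights)
    surface = _sample_surface_of_revolution(rng, heights, radii, spacing)
    # sparse interior fill (twigs): uniform in the solid at ~1/20 surface density
    n_fill = max(50, len(surface) // 20)
    hz = rng.uniform(cb, H, size=n_fill)
    rmax = _crown_radius_profile(spec, hz)
    rr = rmax * np.sqrt(rng.uniform(size=n_fill))
    th = rng.uniform(0, 2 * math.pi, size=n_fill)
    interior = np.column_stack([rr * np.cos(th), rr * np.sin(th), hz])
    return np.vstack([surface, interior])


def generate_tree_cloud(spec: SyntheticTreeSpec) -> tuple[PointCloud, GroundTruth]:
    """Generate one synthetic tree cloud and its analytic ground truth.

    Points are sampled on the trunk surface of revolution (including the
    buttress flare), on explicit branch cylinders and on the crown envelope;
    Gaussian noise of sd ``noise_sd`` is added per coordinate, and an
    azimuthal sector of angular fraction ``occlusion_fraction`` is removed
    from the trunk points.  Deterministic for a fixed seed.
    """
    spec.validate()
    truth = ground_truth(spec)
    rng = np.random.default_rng(spec.seed)

    heights = np.arange(0.0, spec.total_height, spec.point_spacing)
    trunk = _sample_surface_of_revolution(
        rng, heights, spec.trunk_radius(heights), spec.point_spacing
    )
    if spec.occlusion_fraction > 0:
        theta0 = rng.uniform(0, 2 * math.pi)
        ang = np.mod(np.arctan2(trunk[:, 1], trunk[:, 0]) - theta0, 2 * math.pi)
        trunk = trunk[ang >= 2 * math.pi * spec.occlusion_fraction]

    branches, _ = _sample_branches(rng, spec, truth.branch_volume_true)
    crown = _sample_crown_envelope(rng, spec)
    pts = np.vstack([trunk, branches, crown])

    if spec.lean_deg != 0.0:
        a = math.radians(spec.lean_deg)
        rot = np.array(
            [[math.cos(a), 0, math.sin(a)], [0, 1, 0], [-math.sin(a), 0, math.cos(a)]]
        )
        pts = pts @ rot.T

    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)

    cloud = PointCloud(
        pts, source_id=f"synthetic_seed{spec.seed}", attributes={}
    )
    return cloud, truth


# ---------------------------------------------------------------------------
# site generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteTemplate:
    """A cohort of similar trees with a known planting date."""

    site: str
    n_trees: int
    planting_year: int
    scan_year: int
    spec_template: SyntheticTreeSpec = field(default_factory=SyntheticTreeSpec)
    jitter_frac: float = 0.10
    tree_prefix: str = "T"


def generate_site(
    n_trees: int,
    planting_year: int,
    scan_year: int,
    spec_template: Optional[SyntheticTreeSpec] = None,
    jitter_frac: float = 0.10,
    seed: int = 0,
    site: str = "synthetic",
    tree_prefix: str = "T",
) -> tuple[list[PointCloud], list[TreeRecord], list[GroundTruth]]:
    """Generate a cohort of jittered trees with metadata records.

    Each tree's size parameters (height, DBH, crown radius/base, flare) are
    multiplied by independent Gaussian factors of sd ``jitter_frac``
    (truncated at ±2.5 sd to keep specs valid); ``TreeRecord.age`` is
    ``scan_year - planting_year`` for every tree.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if scan_year <= planting_year:
        raise ValueError("scan_year must be after planting_year")
    template = spec_template or SyntheticTreeSpec()
    rng = np.random.default_rng(seed)
    clouds, records, truths = [], [], []
    for i in range(n_trees):
        def jit() -> float:
            return 1.0 + float(np.clip(rng.normal(0.0, jitter_frac), -2.5 * jitter_frac, 2.5 * jitter_frac)) if jitter_frac > 0 else 1.0

        spec = replace(
            template,
            total_height=template.total_height * jit(),
            dbh_true=template.dbh_true * jit(),
            crown_max_radius=template.crown_max_radius * jit(),
            crown_base_height=template.crown_base_height * jit(),
            buttress_extra_radius=template.buttress_extra_radius * jit(),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cloud, truth = generate_tree_cloud(spec)
        tree_id = f"{tree_prefix}{i + 1:03d}"
        cloud.source_id = f"{site}_{tree_id}"
        clouds.append(cloud)
        records.append(TreeRecord(site, tree_id, planting_year, scan_year))
        truths.append(truth)
    return clouds, records, truths
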