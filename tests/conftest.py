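"""Shared fixtures: small synthetic trees and simple geometric clouds."""

import math

import numpy as np
import pytest

from tlscarbon import PointCloud, SyntheticTreeSpec, generate_tree_cloud


@pytest.fixture(scope="session")
def small_tree_spec() -> SyntheticTreeSpec:
    """A modest synthetic conifer: fast to generate, all features present."""
    return SyntheticTreeSpec(
        total_height=20.0,
        dbh_true=0.9,
        buttress_extra_radius=0.15,
        flare_height=2.0,
        taper_exponent=1.0,
        crown_base_height=5.0,
        crown_max_radius=2.5,
        point_spacing=0.04,
        noise_sd=0.003,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_tree(small_tree_spec):
    """(cloud, truth) for the shared fixture tree."""
    return generate_tree_cloud(small_tree_spec)


def make_cylinder(radius: float = 1.0, height: float = 10.0,
                  spacing: float = 0.03, noise_sd: float = 0.0,
                  seed: int = 0) -> PointCloud:
    """Noise-free (or noisy) points on a vertical cylinder surface."""
    rng = np.random.default_rng(seed)
    pts = []
    for z in np.arange(0.0, height, spacing):
        n = max(3, int(round(2 * math.pi * radius / spacing)))
        theta = np.arange(n) * 2 * math.pi / n
        pts.append(np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.full(n, z)]
        ))
    arr = np.vstack(pts)
    if noise_sd > 0:
        arr = arr + rng.normal(0, noise_sd, arr.shape)
    return PointCloud(arr, source_id="cylinder")


def make_cone(base_radius: float = 0.5, height: float = 30.0,
              spacing: float = 0.03) -> PointCloud:
    """Noise-free points on a cone surface (apex up, base at z=0)."""
    pts = []
    for z in np.arange(0.0, height, spacing):
        r = base_radius * (height - z) / height
        n = max(3, int(round(2 * math.pi * r / spacing)))
        if n < 3 or r <= 0:
            continue
        theta = np.arange(n) * 2 * math.pi / n
        pts.append(np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), np.full(n, z)]
        ))
    return PointCloud(np.vstack(pts), source_id="cone")


def circle_points(cx: float, cy: float, r: float, n: int,
                  arc: float = 2 * math.pi, noise_sd: float = 0.0,
                  seed: int = 0) -> np.ndarray:
    """(n, 2) points on a circular arc, optionally with isotropic noise."""
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, arc, n, endpoint=False)
    xy = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    if noise_sd > 0:
        xy = xy + rng.normal(0, noise_sd, xy.shape)
    return xy
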