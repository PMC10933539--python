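"""Per-tree structural metrics from segmented, leaf-off point clouds.

Height is the vertical extent of the cloud.  Stem diameters come from
horizontal cross-sections measured relative to the cloud's lowest point:
DBH from the 1.2-1.4 m slice, DTB (diameter at top of buttress) from the
4.0-4.5 m slice, each via a geometric least-squares circle; the functional
DBH (fDBH) is the diameter of a circle with the same area as the convex
hull of the breast-height section.  Crown volume is the 3-D convex hull of
all points above the crown base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import (
    DegenerateCrownError,
    EmptyCloudError,
    FitError,
    InsufficientPointsError,
)
from .pointcloud_io import MIN_METRIC_POINTS, PointCloud

BREAST_SLICE = (1.2, 1.4)
BUTTRESS_SLICE = (4.0, 4.5)
MIN_SLICE_POINTS = 20


@dataclass(frozen=True)
class CrossSection:
    """Planar (x, y) points of a horizontal slab [z_low, z_high) of a cloud."""

    z_low: float
    z_high: float
    points: np.ndarray  # (n, 2)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class CircleFit:
    """A fitted circle: centre, radius, RMS orthogonal residual."""

    cx: float
    cy: float
    radius: float
    rms_residual: float
    n_points: int

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class StructuralMetrics:
    """Per-tree structural summary.  Missing metrics are ``None``."""

    tree_id: str = ""
    height: Optional[float] = None
    dbh: Optional[float] = None
    dtb: Optional[float] = None
    fdbh: Optional[float] = None
    crown_volume: Optional[float] = None
    woody_volume: Optional[float] = None
    volume_sd: Optional[float] = None
    errors: dict = field(default_factory=dict)


def tree_height(cloud: PointCloud) -> float:
    """Vertical extent of the cloud: max(z) - min(z)."""
    if len(cloud) == 0:
        raise EmptyCloudError("cannot compute height of an empty cloud")
    return float(cloud.z.max() - cloud.z.min())


def slice_cloud(cloud: PointCloud, z_low: float, z_high: float,
                min_points: int = MIN_SLICE_POINTS) -> CrossSection:
    """Extract the horizontal slab [z_low, z_high) above the lowest point.

    Heights are relative to the cloud minimum; the interval is half-open, so
    a point exactly at ``z_high`` is excluded.  Points are flattened onto
    the (x, y) plane.
    """
    if z_high <= z_low:
        raise ValueError("z_high must exceed z_low")
    rel = cloud.z - cloud.z.min()
    mask = (rel >= z_low) & (rel < z_high)
    n = int(mask.sum())
    if n < min_points:
        raise InsufficientPointsError(
            f"slice [{z_low}, {z_high}) m holds {n} points "
            f"(minimum {min_points})",
            count=n,
        )
    return CrossSection(z_low, z_high, cloud.points[mask, :2].copy())


# ---------------------------------------------------------------------------
# circle fitting
# ---------------------------------------------------------------------------

def fit_circle_algebraic(xy: np.ndarray) -> tuple[float, float, float]:
    """Kåsa algebraic circle fit; used to initialise the geometric fit.

    Solves the linear least-squares problem for the circle equation
    x² + y² = 2 cx·x + 2 cy·y + (r² − cx² − cy²).
    """
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise FitError(f"algebraic circle fit failed: {exc}") from exc
    if rank < 3:
        raise FitError("degenerate section: points are collinear or coincident")
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        raise FitError("degenerate section: no real circle fits these points")
    return float(cx), float(cy), float(np.sqrt(r2))


def fit_circle_ls(section: CrossSection | np.ndarray,
                  max_iter: int = 100, step_tol: float = 1e-10) -> CircleFit:
    """Geometric (orthogonal-distance) least-squares circle.

    Minimises Σ (dᵢ − r)² with dᵢ the distance of point i to the centre,
    by Gauss-Newton with analytic Jacobian, initialised from the Kåsa
    algebraic fit.  Converged when the parameter step falls below
    ``step_tol`` (metres) or after ``max_iter`` iterations.
    """
    xy = section.points if isinstance(section, CrossSection) else np.asarray(section, float)
    if xy.shape[0] < 3:
        raise InsufficientPointsError(
            f"circle fit needs >= 3 points, got {xy.shape[0]}", count=xy.shape[0]
        )
    cx, cy, r = fit_circle_algebraic(xy)
    params = np.array([cx, cy, r])
    lam = 0.0  # Levenberg damping, raised only if a step increases the cost

    def residuals(p: np.ndarray) -> np.ndarray:
        d = np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1])
        return d - p[2]

    res = residuals(params)
    cost = float(res @ res)
    for _ in range(max_iter):
        dx = xy[:, 0] - params[0]
        dy = xy[:, 1] - params[1]
        d = np.hypot(dx, dy)
        d = np.where(d < 1e-12, 1e-12, d)
        J = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
        JTJ = J.T @ J
        g = J.T @ res
        for _ in range(20):
            try:
                step = np.linalg.solve(JTJ + lam * np.eye(3), -g)
            except np.linalg.LinAlgError:
                raise FitError("singular normal equations in circle fit")
            trial = params + step
            tres = residuals(trial)
            tcost = float(tres @ tres)
            if tcost <= cost or np.linalg.norm(step) < step_tol:
                break
            lam = max(lam * 10.0, 1e-8)
        else:  # pragma: no cover - pathological sections
            raise FitError("circle fit failed to find a descent step")
        params, res, cost = trial, tres, tcost
        lam /= 10.0
        if np.linalg.norm(step) < step_tol:
            break
    if params[2] <= 0 or not np.all(np.isfinite(params)):
        raise FitError("circle fit diverged to a non-positive radius")
    rms = float(np.sqrt(cost / xy.shape[0]))
    return CircleFit(float(params[0]), float(params[1]), float(params[2]),
                     rms, xy.shape[0])


def estimate_dbh(cloud: PointCloud,
                 slice_interval: tuple[float, float] = BREAST_SLICE) -> float:
    """DBH: diameter of the least-squares circle in the 1.2-1.4 m slab."""
    section = slice_cloud(cloud, *slice_interval)
    return fit_circle_ls(section).diameter


def estimate_dtb(cloud: PointCloud,
                 slice_interval: tuple[float, float] = BUTTRESS_SLICE) -> float:
    """DTB: as DBH but from the 4.0-4.5 m slab, above any buttress flare."""
    section = slice_cloud(cloud, *slice_interval)
    return fit_circle_ls(section).diameter


def estimate_fdbh(cloud: PointCloud,
                  slice_interval: tuple[float, float] = BREAST_SLICE) -> float:
    """Functional DBH: equivalent-area diameter of the breast-height section.

    A convex hull is fitted to the section's planar coordinates; the
    returned diameter is that of a circle with the hull's area,
    2·sqrt(A/π).
    """
    section = slice_cloud(cloud, *slice_interval)
    try:
        hull = ConvexHull(section.points)
    except QhullError as exc:
        raise FitError(f"degenerate breast-height hull: {exc}") from None
    area = hull.volume  # 2-D hull: 'volume' is the enclosed area
    if area <= 0:
        raise FitError("degenerate breast-height hull: zero area")
    return float(2.0 * np.sqrt(area / np.pi))


# ---------------------------------------------------------------------------
# crown volume
# ---------------------------------------------------------------------------

def detect_crown_base(cloud: PointCloud, slice_height: float = 0.5,
                      spread_factor: float = 1.5) -> float:
    """Lowest height at which the horizontal point spread exceeds
    ``spread_factor`` x the buttress-slice (DTB) radius.

    Spread is the 95th percentile of horizontal distance from the slice
    centroid, robust to stray points.  Returns a height relative to the
    cloud's lowest point.
    """
    dtb_radius = estimate_dtb(cloud) / 2.0
    rel = cloud.z - cloud.z.min()
    height = float(rel.max())
    z = BUTTRESS_SLICE[1]
    while z < height:
        mask = (rel >= z) & (rel < z + slice_height)
        if mask.sum() >= 5:
            xy = cloud.points[mask, :2]
            centroid = xy.mean(axis=0)
            spread = float(np.percentile(np.hypot(*(xy - centroid).T), 95))
            if spread > spread_factor * dtb_radius:
                return z
        z += slice_height
    raise DegenerateCrownError("no crown detected: spread never exceeds threshold")


def crown_volume(cloud: PointCloud, crown_base: float | str = "auto") -> float:
    """Volume of the 3-D convex hull of all points above ``crown_base``.

    ``crown_base`` is a height in metres above the lowest point, or
    ``"auto"`` to detect it from the horizontal spread profile.
    """
    if crown_base == "auto":
        crown_base = detect_crown_base(cloud)
    rel = cloud.z - cloud.z.min()
    pts = cloud.points[rel >= crown_base]
    if pts.shape[0] < 4:
        raise DegenerateCrownError(
            f"only {pts.shape[0]} points above crown base {crown_base:.2f} m"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateCrownError(f"degenerate crown hull: {exc}") from None
    return float(hull.volume)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class MetricsConfig:
    breast_slice: tuple[float, float] = BREAST_SLICE
    buttress_slice: tuple[float, float] = BUTTRESS_SLICE
    crown_base: float | str = "auto"
    estimate_volume: bool = True
    volume_config: Optional[object] = None  # volume.VolumeConfig
    volume_seed: int = 0


def compute_all_metrics(cloud: PointCloud, config: Optional[MetricsConfig] = None,
                        tree_id: str = "") -> StructuralMetrics:
    """Run every estimator on one cloud; failures are recorded, not imputed.

    Each metric that cannot be computed is left ``None`` with the reason in
    ``StructuralMetrics.errors``; clouds below the minimum size get every
    diameter marked missing but still report a height.
    """
    config = config or MetricsConfig()
    m = StructuralMetrics(tree_id=tree_id or cloud.source_id)

    def attempt(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            m.errors[name] = f"{type(exc).__name__}: {exc}"
            return None

    m.height = attempt("height", lambda: tree_height(cloud))
    if len(cloud) < MIN_METRIC_POINTS:
        reason = f"cloud has {len(cloud)} points (< {MIN_METRIC_POINTS})"
        for name in ("dbh", "dtb", "fdbh", "crown_volume", "woody_volume"):
            m.errors[name] = reason
        return m
    m.dbh = attempt("dbh", lambda: estimate_dbh(cloud, config.breast_slice))
    m.dtb = attempt("dtb", lambda: estimate_dtb(cloud, config.buttress_slice))
    m.fdbh = attempt("fdbh", lambda: estimate_fdbh(cloud, config.breast_slice))
    m.crown_volume = attempt(
        "crown_volume", lambda: crown_volume(cloud, config.crown_base)
    )
    if config.estimate_volume:
        from .volume import VolumeConfig, estimate_volume

        def run_volume():
            vc = config.volume_config or VolumeConfig()
            est = estimate_volume(cloud, vc, seed=config.volume_seed)
            m.volume_sd = est.volume_sd
            return est.volume_mean

        m.woody_volume = attempt("woody_volume", run_volume)
    return m


METRICS_COLUMNS = ("tree_id", "H_m", "DBH_m", "DTB_m", "fDBH_m",
                   "CV_m3", "V_m3", "V_sd_m3")

_FIELD_FOR_COLUMN = {
    "H_m": "height", "DBH_m": "dbh", "DTB_m": "dtb", "fDBH_m": "fdbh",
    "CV_m3": "crown_volume", "V_m3": "woody_volume", "V_sd_m3": "volume_sd",
}


def write_metrics_table(metrics: list[StructuralMetrics], path) -> None:
    """Write per-tree metrics as CSV (missing metrics become empty cells)."""
    rows = []
    for m in metrics:
        rows.append([m.tree_id] + [getattr(m, _FIELD_FOR_COLUMN[c])
                                   for c in METRICS_COLUMNS[1:]])
    pd.DataFrame(rows, columns=list(METRICS_COLUMNS)).to_csv(path, index=False)


def read_metrics_table(path) -> list[StructuralMetrics]:
    """Read a per-tree metrics CSV (e.g. externally computed QSM volumes).

    Only ``tree_id`` is mandatory; other columns map onto
    :class:`StructuralMetrics` fields, with blank cells left as ``None``.
    """
    df = pd.read_csv(path)
    if "tree_id" not in df.columns:
        from .errors import SchemaError
        raise SchemaError(f"{path}: missing required column 'tree_id'")
    out = []
    for row in df.itertuples(index=False):
        m = StructuralMetrics(tree_id=str(getattr(row, "tree_id")))
        for col, fld in _FIELD_FOR_COLUMN.items():
            if col in df.columns:
                v = getattr(row, col)
                if v is not None and np.isfinite(v):
                    setattr(m, fld, float(v))
        out.append(m)
    return out
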