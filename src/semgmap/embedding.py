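"""Low-dimensional geometry of the pooled map cloud.

Every activation map is a 64-dimensional pixel vector. All maps of all
conditions are pooled and embedded into 3-D; the per-condition point
clouds are then summarized by

* the volume of their 3-D convex hull ("polyhedron"), normalized across
  conditions to a maximum of one, and
* the Shannon entropy of the point-count distribution over a 16^3
  voxelization of the cloud's bounding box (occupancy entropy, bits) —
  a measure of how heterogeneously the condition fills its polyhedron.

Two embedding backends are exposed. ``manifold`` delegates to UMAP with
the configured hyperparameters (stochastic, seeded). ``linear`` is a
deterministic orthogonal projection onto the top three principal axes,
used wherever exact reproducibility matters more than manifold structure
(the whole test suite runs on it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class EmbeddingConfig:
    n_neighbors: int = 10
    min_dist: float = 0.7
    n_components: int = 3
    metric: str = "euclidean"
    n_epochs: int = 200
    learning_rate: float = 1.0
    local_connectivity: float = 1.0
    repulsion_strength: float = 1.0
    spread: float = 1.0
    set_op_mix_ratio: float = 1.0
    negative_sample_rate: int = 5
    seed: int = 0
    backend: str = "manifold"

    def __post_init__(self) -> None:
        if self.n_components != 3:
            raise ValidationError("the geometry stage requires a 3-D embedding")
        if self.backend not in ("manifold", "linear"):
            raise ValidationError(f"unknown backend {self.backend!r}")
        if min(self.learning_rate, self.repulsion_strength, self.spread) <= 0:
            raise ValidationError("rates must be positive")


@dataclass(frozen=True)
class EmbeddedCloud:
    points: np.ndarray  # (n, 3)
    labels: np.ndarray | None = None  # condition label per point


@dataclass(frozen=True)
class PolyhedronSummary:
    condition: object
    volume_raw: float
    entropy_bits: float
    n_points: int
    degenerate: bool = False
    volume_norm: float = float("nan")


def _linear_embed(x: np.ndarray, n_components: int) -> np.ndarray:
    """Orthogonal projection onto the top principal axes, sign-fixed."""
    centered = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    basis = vt[:n_components]
    # deterministic sign: largest-magnitude loading of each axis positive
    for i, row in enumerate(basis):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            basis[i] = -row
    return centered @ basis.T


def embed(
    maps: np.ndarray,
    cfg: EmbeddingConfig | None = None,
    labels: np.ndarray | None = None,
) -> EmbeddedCloud:
    """Embed an (n, d) pixel matrix into 3-D with the configured backend."""
    cfg = cfg or EmbeddingConfig()
    x = np.asarray(maps, dtype=float)
    if x.ndim != 2:
        raise ValidationError("maps must be a 2-D (n, d) matrix")
    if x.shape[0] < cfg.n_neighbors + 1:
        raise ValidationError(
            f"need at least n_neighbors+1 = {cfg.n_neighbors + 1} points, "
            f"got {x.shape[0]}"
        )
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != x.shape[0]:
            raise ValidationError("labels must align with points")
    if cfg.backend == "linear":
        pts = _linear_embed(x, cfg.n_components)
    else:
        import umap

        reducer = umap.UMAP(
            n_neighbors=cfg.n_neighbors,
            min_dist=cfg.min_dist,
            n_components=cfg.n_components,
            metric=cfg.metric,
            n_epochs=cfg.n_epochs,
            learning_rate=cfg.learning_rate,
            local_connectivity=cfg.local_connectivity,
            repulsion_strength=cfg.repulsion_strength,
            spread=cfg.spread,
            set_op_mix_ratio=cfg.set_op_mix_ratio,
            negative_sample_rate=cfg.negative_sample_rate,
            random_state=cfg.seed,
        )
        pts = np.asarray(reducer.fit_transform(x), dtype=float)
    return EmbeddedCloud(points=pts, labels=labels)


def voxel_occupancy_entropy(points: np.ndarray, grid_size: int = 16) -> float:
    """Shannon entropy (bits) of point counts over a bounding-box voxel grid."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] == 0:
        return 0.0
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    idx = np.minimum(
        ((pts - lo) / span * grid_size).astype(int), grid_size - 1
    )
    flat = np.ravel_multi_index(idx.T, (grid_size,) * pts.shape[1])
    counts = np.bincount(flat)
    p = counts[counts > 0] / pts.shape[0]
    return float(-(p * np.log2(p)).sum())


def hull_summary(
    points: np.ndarray,
    condition: object = None,
    voxel_grid: int = 16,
) -> PolyhedronSummary:
    """Convex-hull volume and occupancy entropy of one condition's cloud.

    Fewer than four points, or a coplanar/coincident set, yields volume 0
    with the degenerate flag (the embedding stage can legitimately produce
    clouds with no 3-D extent — "no simplex" conditions).
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 4:
        return PolyhedronSummary(condition, 0.0, 0.0, n, degenerate=True)
    try:
        hull = ConvexHull(pts)
        volume = float(hull.volume)
    except QhullError:
        return PolyhedronSummary(condition, 0.0, 0.0, n, degenerate=True)
    ent = voxel_occupancy_entropy(pts, voxel_grid)
    return PolyhedronSummary(condition, volume, ent, n, degenerate=False)


def condition_summaries(
    cloud: EmbeddedCloud, voxel_grid: int = 16
) -> list[PolyhedronSummary]:
    """Per-condition hull summaries of a labeled pooled embedding."""
    if cloud.labels is None:
        raise ValidationError("cloud has no condition labels")
    out = []
    for cond in _stable_unique(cloud.labels):
        mask = cloud.labels == cond
        out.append(hull_summary(cloud.points[mask], cond, voxel_grid))
    return normalize_volumes(out)


def _stable_unique(labels: np.ndarray):
    seen: dict = {}
    for item in labels.tolist():
        seen.setdefault(item, None)
    return list(seen)


def normalize_volumes(summaries: list[PolyhedronSummary]) -> list[PolyhedronSummary]:
    """Scale volumes so the largest condition has volume_norm == 1."""
    if not summaries:
        raise ValidationError("no summaries to normalize")
    peak = max(s.volume_raw for s in summaries)
    if peak <= 0:
        raise DegenerateInputError("all condition volumes are zero")
    return [replace(s, volume_norm=s.volume_raw / peak) for s in summaries]


@dataclass(frozen=True)
class FitResult:
    coefficients: np.ndarray  # highest degree first
    r_squared: float
    zero_crossings: tuple[float, ...]  # real roots inside the x-range
    x: np.ndarray
    y_z: np.ndarray  # z-scored response actually fitted


def fit_trend(x, y, degree: int = 3) -> FitResult:
    """Least-squares polynomial trend of the z-scored response.

    Z-scoring centers the response so its zero-crossings mark where the
    summary passes through its own mean — the transition points between
    "inflated" and "deflated" regimes along the factor axis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and aligned")
    if x.size < degree + 1:
        raise ValidationError(
            f"need at least {degree + 1} points for a degree-{degree} fit"
        )
    sd = y.std()
    y_z = (y - y.mean()) / sd if sd > 0 else y - y.mean()
    coeffs = np.polyfit(x, y_z, degree)
    fitted = np.polyval(coeffs, x)
    ss_res = float(((y_z - fitted) ** 2).sum())
    ss_tot = float(((y_z - y_z.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    inside = sorted(float(r) for r in real if x.min() - 1e-9 <= r <= x.max() + 1e-9)
    return FitResult(
        coefficients=coeffs,
        r_squared=r2,
        zero_crossings=tuple(inside),
        x=x,
        y_z=y_z,
    )
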