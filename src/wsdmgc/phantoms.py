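"""Seeded synthetic datasets with known cluster structure.

Two generators are provided:

* :func:`generate_phantom_dataset` renders nodule-like grayscale image
  patches — a soft-edged elliptical blob on a noisy background, with
  per-cluster radius, peak intensity and texture frequency. A single
  ``separation`` knob spreads the cluster parameter records apart:
  at 0 every cluster draws from identical distributions (chance-level
  difficulty), at ~3 clusters are visually distinct.
* :func:`generate_feature_dataset` draws isotropic Gaussian clouds around
  centres spaced along orthogonal axes — the minimal geometry for testing
  the graph-clustering and propagation stages in isolation.

Both are fully labeled (use :func:`wsdmgc.datasets.mask_labels` to create
the weak-supervision setting) and bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DataValidationError, SampleSet


@dataclass
class ClusterParams:
    """Rendering parameters of one phantom cluster."""

    radius_mean: float
    radius_sd: float
    intensity_mean: float
    intensity_sd: float
    noise_sd: float
    texture_freq: float


@dataclass
class PhantomSpec:
    """Specification of a phantom image dataset.

    ``separation >= 0`` controls how far apart the per-cluster parameter
    records (blob radius, peak intensity, texture frequency) are placed;
    explicit ``clusters`` override the derived records.
    """

    n_clusters: int = 5
    per_cluster: int = 200
    image_size: int = 32
    separation: float = 2.0
    seed: int = 0
    clusters: list[ClusterParams] | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise DataValidationError("n_clusters must be >= 2")
        if self.per_cluster < 1:
            raise DataValidationError("per_cluster must be >= 1")
        if self.separation < 0:
            raise DataValidationError("separation must be >= 0")
        if self.image_size < 8:
            raise DataValidationError(
                "image_size must be >= 8 (blob cannot be rendered)")

    def cluster_params(self) -> list[ClusterParams]:
        if self.clusters is not None:
            if len(self.clusters) != self.n_clusters:
                raise DataValidationError(
                    "clusters list length must equal n_clusters")
            return self.clusters
        n, s = self.n_clusters, self.separation
        scale = self.image_size / 32.0
        # Three parameter axes, each traversed in a different cluster order so
        # no two clusters coincide on every axis once separation > 0.
        t = np.arange(n) / (n - 1)                     # radius order
        u = (np.arange(n) * 2 % n) / (n - 1)           # intensity order
        v = (np.arange(n) * 3 % n) / (n - 1)           # texture order
        params = []
        for c in range(n):
            params.append(ClusterParams(
                radius_mean=float(np.clip((5.0 + 2.0 * s * (t[c] - 0.5)) * scale,
                                          1.5 * scale, 0.38 * self.image_size)),
                radius_sd=0.4 * scale,
                intensity_mean=float(np.clip(0.55 + 0.12 * s * (u[c] - 0.5),
                                             0.15, 0.95)),
                intensity_sd=0.04,
                noise_sd=0.05,
                texture_freq=float(1.0 + s * v[c]),
            ))
        return params


def _render_blob(size: int, rng: np.random.Generator,
                 p: ClusterParams) -> np.ndarray:
    """One background-noise image plus one soft-edged textured ellipse."""
    radius = max(1.0, rng.normal(p.radius_mean, p.radius_sd))
    intensity = float(np.clip(rng.normal(p.intensity_mean, p.intensity_sd),
                              0.05, 1.0))
    aspect = rng.uniform(0.75, 1.3)
    phi = rng.uniform(0, np.pi)
    jitter = size / 10.67  # +-3 px on a 32-px patch
    cx, cy = size / 2 + rng.uniform(-jitter, jitter, size=2)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    # normalized elliptical radius: 1 on the blob boundary
    r = np.sqrt((xr / (radius * aspect)) ** 2 + (yr / (radius / aspect)) ** 2)
    blob = intensity / (1.0 + np.exp((r - 1.0) / 0.15))

    theta = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    carrier = (xx * np.cos(theta) + yy * np.sin(theta)) / size
    blob *= 1.0 + 0.25 * np.sin(2 * np.pi * p.texture_freq * carrier + phase)

    img = 0.1 + rng.normal(0.0, p.noise_sd, size=(size, size)) + blob
    return np.clip(img, 0.0, 1.0)


def generate_phantom_dataset(spec: PhantomSpec) -> SampleSet:
    """Render ``n_clusters * per_cluster`` labeled phantom patches."""
    rng = np.random.default_rng(spec.seed)
    params = spec.cluster_params()
    images, labels, ids = [], [], []
    for c in range(spec.n_clusters):
        for j in range(spec.per_cluster):
            images.append(_render_blob(spec.image_size, rng, params[c]))
            labels.append(c)
            ids.append(f"c{c}_{j:04d}")
    return SampleSet(
        ids=np.array(ids, dtype=object),
        X=np.stack(images),
        y=np.array(labels, dtype=np.int64),
        labeled=np.ones(len(ids), dtype=bool),
        label_names={c: f"cluster{c}" for c in range(spec.n_clusters)},
    )


def generate_feature_dataset(n_clusters: int, per_cluster: int, dim: int,
                             centre_spacing: float, noise_sd: float,
                             seed: int) -> SampleSet:
    """Isotropic Gaussian clouds around orthogonally spaced centres.

    Centre ``c`` sits at ``centre_spacing`` along coordinate axis ``c``;
    ``dim`` must therefore be at least ``n_clusters``.
    """
    if n_clusters < 1 or per_cluster < 1:
        raise DataValidationError("counts must be >= 1")
    if dim < 1:
        raise DataValidationError("dim must be >= 1")
    if dim < n_clusters:
        raise DataValidationError("dim must be >= n_clusters "
                                  "(one orthogonal axis per centre)")
    if noise_sd < 0:
        raise DataValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    X, labels, ids = [], [], []
    for c in range(n_clusters):
        centre = np.zeros(dim)
        centre[c] = centre_spacing
        pts = centre + rng.normal(0.0, noise_sd, size=(per_cluster, dim))
        X.append(pts)
        labels.extend([c] * per_cluster)
        ids.extend(f"c{c}_{j:04d}" for j in range(per_cluster))
    return SampleSet(
        ids=np.array(ids, dtype=object),
        X=np.concatenate(X),
        y=np.array(labels, dtype=np.int64),
        labeled=np.ones(len(ids), dtype=bool),
    )
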