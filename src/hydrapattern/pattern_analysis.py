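"""Quantitative readouts of simulated expression patterns.

Turns a final field state into countable quantities — organizer (Wnt3)
spots, body axes, tentacle spots, ring scores for azimuthally symmetric
bands — and classifies the run into one of six phenotypes: single-organizer,
ectopic-tentacles, secondary-axis, secondary-axis-with-tentacles,
broadened-organizer, or no-pattern.  All thresholds are operational
definitions of readouts that the underlying biology reports only as images;
they are exposed as parameters and documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from hydrapattern.geometry import SurfaceMesh
from hydrapattern.model import SPECIES, FieldState

#: s3 threshold separating the hypostome/tentacle zone from the body column
BODY_S3_MAX = 0.3

PHENOTYPES = ("single-organizer", "ectopic-tentacles", "secondary-axis",
              "secondary-axis-with-tentacles", "broadened-organizer",
              "no-pattern")


@dataclass
class Spot:
    """One connected high-expression component."""

    seed_vertex: int          # vertex of peak value
    members: np.ndarray       # vertex indices of the component
    peak_value: float
    area: float               # summed lumped vertex areas


@dataclass
class SpotSet:
    """Disjoint high-expression components of one field."""

    species: str
    spots: list
    rel_threshold: float
    cv: float                 # spatial coefficient of variation of the field

    def __len__(self):
        return len(self.spots)

    def seed_vertices(self) -> np.ndarray:
        return np.array([s.seed_vertex for s in self.spots], dtype=int)


@dataclass
class PatternSummary:
    """Countable pattern readouts plus the phenotype call."""

    wnt3_spot_count: int
    axis_count: int
    tentacle_spot_count: int
    body_tentacle_spot_count: int
    tentacle_ring_score: float
    has_ring_score: float
    has_body_level: float
    wnt3_spot_area: float
    phenotype: str
    details: dict = field(default_factory=dict)


def spatial_cv(values: np.ndarray, areas: np.ndarray) -> float:
    """Area-weighted spatial coefficient of variation of a field."""
    w = areas / areas.sum()
    mean = float(values @ w)
    if mean == 0.0:
        return 0.0
    var = float(((values - mean) ** 2) @ w)
    return float(np.sqrt(var) / mean)


def _field(state: FieldState, species: str) -> np.ndarray:
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}")
    return getattr(state, species)


def detect_spots(state: FieldState, species: str, mesh: SurfaceMesh,
                 rel_threshold: float = 0.5, cv_min: float = 0.2,
                 min_area_vertices: int = 3) -> SpotSet:
    """Connected components of the super-threshold region of a field.

    The field is thresholded at ``rel_threshold * max`` (scale-invariant),
    components are taken on the mesh edge graph, and components smaller than
    ``min_area_vertices`` are discarded.  A near-uniform field (spatial CV
    below ``cv_min``) yields no spots: a uniform elevation is not a pattern.
    """
    values = _field(state, species)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"field {species!r} contains non-finite values")
    cv = spatial_cv(values, mesh.vertex_areas)
    if cv < cv_min or values.max() <= 0:
        return SpotSet(species=species, spots=[], rel_threshold=rel_threshold,
                       cv=cv)
    mask = values >= rel_threshold * values.max()
    idx = np.nonzero(mask)[0]
    sub = mesh.edge_graph()[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    spots = []
    for c in range(n_comp):
        members = idx[labels == c]
        if members.size < min_area_vertices:
            continue
        seed = members[int(np.argmax(values[members]))]
        spots.append(Spot(seed_vertex=int(seed), members=members,
                          peak_value=float(values[seed]),
                          area=float(mesh.vertex_areas[members].sum())))
    spots.sort(key=lambda s: -s.peak_value)
    return SpotSet(species=species, spots=spots, rel_threshold=rel_threshold,
                   cv=cv)


def count_axes(wnt3_spots: SpotSet, mesh: SurfaceMesh,
               min_separation: float | None = None) -> int:
    """Number of organizer clusters separated by a geodesic margin.

    Single-linkage clustering of spot seed vertices with link threshold
    ``min_separation`` (default a quarter of the mesh's geodesic diameter):
    nearby Wnt3 spots belong to one organizer, well-separated clusters mark
    distinct body axes.
    """
    seeds = wnt3_spots.seed_vertices()
    k = len(seeds)
    if k == 0:
        return 0
    if min_separation is None:
        min_separation = 0.25 * mesh.graph_diameter()
    if k == 1:
        return 1
    dist = mesh.geodesic_distances(seeds)[:, seeds]
    adj = sp.csr_matrix(dist <= min_separation)
    n_clusters, _ = connected_components(adj, directed=False)
    return int(n_clusters)


def ring_score(state: FieldState, species: str, mesh: SurfaceMesh,
               band_center_s3: float, band_width: float,
               n_azimuthal_bins: int = 12) -> float:
    """How ring-like a field is within an axial band, in [0, 1].

    The score is (fraction of total field mass inside the band
    s3 in [center - width/2, center + width/2]) times the band's azimuthal
    uniformity, 1 - cv of per-azimuthal-bin mass densities.  An ideal
    azimuthally uniform ring confined to the band scores ~1; an off-band or
    single-spot pattern scores low.
    """
    values = _field(state, species)
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValueError(f"field {species!r} must be finite and non-negative")
    s3 = mesh.sphere_coords[:, 2]
    lo, hi = band_center_s3 - band_width / 2, band_center_s3 + band_width / 2
    in_band = (s3 >= lo) & (s3 <= hi)
    if not in_band.any():
        raise ValueError(f"band [{lo:g}, {hi:g}] contains no vertices")
    mass = values * mesh.vertex_areas
    total = mass.sum()
    if total <= 0:
        return 0.0
    band_fraction = float(mass[in_band].sum() / total)

    azimuth = np.arctan2(mesh.sphere_coords[in_band, 1],
                         mesh.sphere_coords[in_band, 0])
    bins = np.floor((azimuth + np.pi) / (2 * np.pi) * n_azimuthal_bins)
    bins = np.clip(bins.astype(int), 0, n_azimuthal_bins - 1)
    bin_mass = np.bincount(bins, weights=mass[in_band],
                           minlength=n_azimuthal_bins)
    bin_area = np.bincount(bins, weights=mesh.vertex_areas[in_band],
                           minlength=n_azimuthal_bins)
    ok = bin_area > 0
    density = bin_mass[ok] / bin_area[ok]
    mean = density.mean()
    if mean <= 0:
        return 0.0
    uniformity = max(0.0, 1.0 - float(density.std() / mean))
    return float(band_fraction * uniformity)


def body_mean(state: FieldState, species: str, mesh: SurfaceMesh,
              s3_max: float = BODY_S3_MAX) -> float:
    """Area-weighted mean of a field over the body column (s3 < s3_max)."""
    values = _field(state, species)
    sel = mesh.sphere_coords[:, 2] < s3_max
    w = mesh.vertex_areas[sel]
    return float((values[sel] @ w) / w.sum())


def _body_spot_count(spots: SpotSet, mesh: SurfaceMesh,
                     s3_max: float = BODY_S3_MAX) -> int:
    s3 = mesh.sphere_coords[:, 2]
    return sum(1 for s in spots.spots if s3[s.seed_vertex] < s3_max)


def classify_phenotype(wnt3_spot_count: int, axis_count: int,
                       tentacle_spot_count: int,
                       body_tentacle_spot_count: int,
                       wnt3_spot_area: float,
                       reference_spot_area: float | None = None,
                       broadened_factor: float = 2.0) -> str:
    """Deterministic rule table mapping counts to a phenotype label.

    * no-pattern: no Wnt3 spot and no tentacle spots;
    * secondary-axis(+tentacles): >= 2 organizer clusters, split by the
      presence of body-column tentacle spots;
    * broadened-organizer: single axis whose Wnt3 domain area exceeds
      ``broadened_factor`` times the unperturbed reference area;
    * ectopic-tentacles: single axis with body-column tentacle spots;
    * single-organizer: everything else with one axis.
    """
    if wnt3_spot_count == 0 and tentacle_spot_count == 0:
        return "no-pattern"
    if axis_count >= 2:
        if body_tentacle_spot_count > 0:
            return "secondary-axis-with-tentacles"
        return "secondary-axis"
    if wnt3_spot_count == 0:
        # tentacle pattern without an organizer: ectopic if on the body
        return ("ectopic-tentacles" if body_tentacle_spot_count > 0
                else "single-organizer")
    if (reference_spot_area is not None and reference_spot_area > 0
            and wnt3_spot_area > broadened_factor * reference_spot_area):
        return "broadened-organizer"
    if body_tentacle_spot_count > 0:
        return "ectopic-tentacles"
    return "single-organizer"


def summarize_state(state: FieldState, mesh: SurfaceMesh,
                    rel_threshold: float = 0.5, cv_min: float = 0.2,
                    min_area_vertices: int = 3,
                    min_separation: float | None = None,
                    reference_spot_area: float | None = None,
                    broadened_factor: float = 2.0,
                    has_band_center: float = 0.55,
                    has_band_width: float = 0.5) -> PatternSummary:
    """Full pattern quantification of one final state."""
    wnt3_spots = detect_spots(state, "wnt3", mesh, rel_threshold, cv_min,
                              min_area_vertices)
    tent_spots = detect_spots(state, "tent", mesh, rel_threshold, cv_min,
                              min_area_vertices)
    axes = count_axes(wnt3_spots, mesh, min_separation)
    body_tent = _body_spot_count(tent_spots, mesh)
    wnt3_area = max((s.area for s in wnt3_spots.spots), default=0.0)
    tent_ring = ring_score(state, "tent", mesh, band_center_s3=0.75,
                           band_width=0.4)
    has_ring = ring_score(state, "has", mesh, band_center_s3=has_band_center,
                          band_width=has_band_width)
    phenotype = classify_phenotype(
        wnt3_spot_count=len(wnt3_spots), axis_count=axes,
        tentacle_spot_count=len(tent_spots),
        body_tentacle_spot_count=body_tent, wnt3_spot_area=wnt3_area,
        reference_spot_area=reference_spot_area,
        broadened_factor=broadened_factor)
    return PatternSummary(
        wnt3_spot_count=len(wnt3_spots), axis_count=axes,
        tentacle_spot_count=len(tent_spots),
        body_tentacle_spot_count=body_tent,
        tentacle_ring_score=tent_ring, has_ring_score=has_ring,
        has_body_level=body_mean(state, "has", mesh),
        wnt3_spot_area=wnt3_area, phenotype=phenotype,
        details={"wnt3_cv": wnt3_spots.cv, "tent_cv": tent_spots.cv,
                 "wnt3_spot_s3": (
                     float(mesh.sphere_coords[wnt3_spots.spots[0].seed_vertex,
                                              2])
                     if wnt3_spots.spots else float("nan"))})
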