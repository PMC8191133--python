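"""Initial fields: stochastic molecular species and the deterministic
source-density gradient.

Only two things are prescribed at t = 0: uniform random noise in the eight
molecular species (de novo patterning from near-homogeneous data) and an
exponential apical-to-basal gradient in the source density,

    SD(t=0) = sd_offset + sd_amplitude * exp(s3) / exp(1),

so SD equals ``sd_amplitude`` (+ offset) at the apical pole s3 = 1.  The
offset (default 0) models a systemic rise of head-forming potential under
GSK-3beta inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hydrapattern.geometry import SurfaceMesh
from hydrapattern.model import SPECIES, SPECIES_INDEX, FieldState


@dataclass
class InitialConditionSpec:
    """Bounds and seed for the stochastic initial data.

    noise_low/noise_high bound the per-vertex i.i.d. uniform draw used for
    every molecular species (all but the source density); the published model
    states uniform randomness without a range, and O(1) values lie in the
    basin of the patterned attractor, hence the (0, 1) default.
    """

    noise_low: float = 0.0
    noise_high: float = 1.0
    sd_amplitude: float = 4.0
    sd_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_low < 0:
            raise ValueError("noise_low must be >= 0")
        if self.noise_high <= self.noise_low:
            raise ValueError("noise_high must exceed noise_low")
        if self.sd_amplitude <= 0:
            raise ValueError("sd_amplitude must be > 0")
        if self.sd_offset < 0:
            raise ValueError("sd_offset must be >= 0")


def source_density_profile(mesh: SurfaceMesh,
                           spec: InitialConditionSpec) -> np.ndarray:
    """Deterministic exponential source-density gradient over mesh vertices."""
    s3 = mesh.sphere_coords[:, 2]
    return spec.sd_offset + spec.sd_amplitude * np.exp(s3) / np.e


def random_fields(mesh: SurfaceMesh, spec: InitialConditionSpec) -> FieldState:
    """Full initial state: uniform random molecular species, gradient SD.

    The eight molecular species are drawn i.i.d. per vertex from
    Uniform(noise_low, noise_high) with a PCG64 generator, so identical seeds
    give bit-identical states on any platform.
    """
    rng = np.random.default_rng(spec.seed)
    n = mesh.n_vertices
    values = np.empty((len(SPECIES), n))
    for i, name in enumerate(SPECIES):
        if name == "sd":
            continue
        values[i] = rng.uniform(spec.noise_low, spec.noise_high, size=n)
    values[SPECIES_INDEX["sd"]] = source_density_profile(mesh, spec)
    state = FieldState(values, time=0.0)
    state.validate()
    return state
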