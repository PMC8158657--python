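"""Synthetic 4-modality phantoms with nested tumor compartments.

Each phantom is a brain ellipsoid (zero background, i.e. "skull-stripped")
holding three concentric tumor compartments: an enhancing core (ET), a
necrotic/non-enhancing shell (NCR/NET) and an edema shell (ED), so the derived
hierarchical regions nest ET < TC < WT by construction. The default contrast
table plants complementary information into the two modality pairs: edema (and
hence the WT extent) is conspicuous only on T2/FLAIR (pair g2), while the
enhancing core is conspicuous only on T1c (pair g1).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume_io import DEFAULT_CODES, MultiModalStudy, SubCompartmentLabels

#: additive intensity per modality for (brain, ed, ncr_net, et), arbitrary units
DEFAULT_CONTRAST = {
    "t1":    {"brain": 1.00, "ed": -0.05, "ncr_net": -0.40, "et": -0.10},
    "t1c":   {"brain": 1.00, "ed": -0.05, "ncr_net": -0.40, "et": 0.80},
    "t2":    {"brain": 0.90, "ed": 0.60, "ncr_net": 0.55, "et": 0.50},
    "flair": {"brain": 0.80, "ed": 0.80, "ncr_net": 0.70, "et": 0.70},
}


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic study (seed-deterministic)."""

    grid_shape: tuple = (32, 32, 32)
    brain_axes: tuple = (13.0, 12.0, 11.0)  # ellipsoid semi-axes, voxels
    tumor_center_jitter: float = 2.0        # max |offset| of tumor center per axis
    wt_radius: float = 7.5
    tc_radius: float = 5.0
    et_radius: float = 3.2
    radius_jitter: float = 0.08             # per-axis relative jitter of each radius
    contrast: dict = dataclasses.field(default_factory=lambda: {
        m: dict(v) for m, v in DEFAULT_CONTRAST.items()})
    noise_sd: float = 0.05
    bias_field_amplitude: float = 0.05
    seed: int = 0

    @classmethod
    def for_grid(cls, grid_shape, **overrides) -> "PhantomSpec":
        """Default geometry scaled from the 32^3 reference to another grid."""
        grid_shape = tuple(int(s) for s in grid_shape)
        f = min(grid_shape) / 32.0
        spec = cls(grid_shape=grid_shape,
                   brain_axes=tuple(round(a * f, 2) for a in (13.0, 12.0, 11.0)),
                   tumor_center_jitter=2.0 * f, wt_radius=7.5 * f,
                   tc_radius=5.0 * f, et_radius=3.2 * f)
        return dataclasses.replace(spec, **overrides) if overrides else spec

    def validate(self):
        center = tuple((s - 1) / 2.0 for s in self.grid_shape)
        if any(a > c for a, c in zip(self.brain_axes, center)):
            raise ValueError(
                f"brain semi-axes {self.brain_axes} exceed grid {self.grid_shape}")
        if not (self.et_radius < self.tc_radius < self.wt_radius):
            raise ValueError(
                f"radii must strictly decrease: et {self.et_radius} < tc "
                f"{self.tc_radius} < wt {self.wt_radius} required")
        max_r = self.wt_radius * (1.0 + self.radius_jitter)
        reach = max_r + self.tumor_center_jitter
        if any(reach > ax for ax in self.brain_axes):
            raise ValueError(
                f"tumor (reach {reach:.1f} vox) can exceed brain semi-axes {self.brain_axes}")


def _ellipsoid_dist(shape, center, axes):
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    q = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, axes):
        q += ((g - c) / a) ** 2
    return np.sqrt(q)  # <= 1 inside


def _bias_field(shape, amplitude, rng):
    """Smooth low-order polynomial field in [-amplitude, amplitude]-ish."""
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    c = rng.normal(0.0, 1.0, size=7)
    field = (c[0] * gx + c[1] * gy + c[2] * gz
             + c[3] * gx * gy + c[4] * gy * gz + c[5] * gx * gz
             + c[6] * gx * gy * gz)
    peak = np.abs(field).max()
    if peak > 0:
        field *= amplitude / peak
    return field


def generate_phantom(spec: PhantomSpec) -> tuple[MultiModalStudy, SubCompartmentLabels]:
    """Build one study + sub-compartment labels from a spec (fully seeded)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    brain_center = tuple((s - 1) / 2.0 for s in shape)

    brain = _ellipsoid_dist(shape, brain_center, spec.brain_axes) <= 1.0

    center = tuple(bc + rng.uniform(-spec.tumor_center_jitter, spec.tumor_center_jitter)
                   for bc in brain_center)

    def compartment(base_r):
        axes = base_r * (1.0 + rng.uniform(-spec.radius_jitter, spec.radius_jitter, size=3))
        return _ellipsoid_dist(shape, center, axes) <= 1.0

    wt = compartment(spec.wt_radius) & brain
    tc = compartment(spec.tc_radius) & wt
    et = compartment(spec.et_radius) & tc

    codes = dict(DEFAULT_CODES)
    labels = np.zeros(shape, dtype=np.int64)
    labels[wt] = codes["ed"]
    labels[tc] = codes["ncr_net"]
    labels[et] = codes["et"]

    region_of = {codes["ed"]: "ed", codes["ncr_net"]: "ncr_net", codes["et"]: "et"}
    bias = _bias_field(shape, spec.bias_field_amplitude, rng)
    vols = {}
    for m, table in spec.contrast.items():
        vol = np.zeros(shape, dtype=np.float64)
        vol[brain] = table["brain"]
        for code, region in region_of.items():
            vol[labels == code] = table["brain"] + table[region]
        vol += bias
        if spec.noise_sd > 0:
            vol += rng.normal(0.0, spec.noise_sd, size=shape)
        vol[~brain] = 0.0
        vols[m] = vol

    study = MultiModalStudy(spacing=(1.0, 1.0, 1.0),
                            subject_id=f"phantom_{spec.seed:08d}", **vols)
    return study, SubCompartmentLabels(labels, codes)


def generate_cohort(n: int, spec: PhantomSpec | None = None,
                    master_seed: int = 0) -> list[tuple[MultiModalStudy, SubCompartmentLabels]]:
    """n phantoms with per-subject seeds spawned deterministically from master_seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec if spec is not None else PhantomSpec()
    seeds = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    cohort = []
    for i in range(n):
        sub = dataclasses.replace(
            spec, contrast={m: dict(v) for m, v in spec.contrast.items()},
            seed=int(seeds[i]))
        study, labels = generate_phantom(sub)
        study.subject_id = f"phantom_{i:03d}"
        cohort.append((study, labels))
    return cohort
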