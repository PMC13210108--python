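"""Seeded 4D digital phantoms and phase-resolved signals with known truth.

The phantom is a saccular aneurysm idealised as a sphere riding on a
cylindrical parent vessel, voxelised per cardiac phase. Programmable
features mirror what gated CT of a pulsating aneurysm produces:

* global radial pulsation of the sac (fractional amplitude ``alpha``),
* an optional focal patch bulging with a raised-cosine taper (the analogue
  of a locally compliant wall region),
* seeded Gaussian jitter of the segmented boundary (segmentation noise),
* repeated-measurement pairs for repeatability / minimum-detectable-change
  analysis.

Everything is a pure function of (spec, seed): identical inputs give
bit-identical outputs, which the test-suite relies on.

The generator does NOT emulate CT physics (beam hardening, contrast
dynamics, reconstruction texture) — only the geometry and the boundary
uncertainty that the downstream pipeline has to survive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dynamics import PhaseSeries

__all__ = [
    "PhantomSpec",
    "SignalSpec",
    "PhaseVolume4D",
    "SignalSample",
    "generate_phantom",
    "generate_signal",
    "generate_repeatability_pairs",
    "sphere_volume",
    "spherical_cap_volume",
    "focal_patch_area",
    "analytic_sac_volume",
    "write_phantom_nrrd",
    "write_signal_csv",
    "read_signal_csv",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and dynamics of the sphere-on-vessel phantom.

    The parent vessel is a cylinder through the origin along
    ``parent_axis``; the sac is a sphere at ``sac_center`` (mm). At phase t
    of ``n_phases`` the sac radius is
    ``sac_radius * (1 + alpha * sin(2*pi*t/n + phase_offset))``. The focal
    patch, if present, adds ``extra_amplitude * taper(theta) * sin(...)``
    of radial displacement inside ``angular_radius`` of its centre
    direction, with a raised-cosine taper to zero at the rim.
    """

    sac_radius: float = 3.0
    sac_center: tuple = (0.0, 0.0, 4.0)
    parent_radius: float = 1.5
    parent_axis: tuple = (1.0, 0.0, 0.0)
    parent_half_length: float | None = None
    extra_branch_axis: tuple | None = None   # adds a third branch (Y junction)
    voxel_spacing: float = 0.25
    n_phases: int = 20
    global_pulsation_fraction: float = 0.0   # alpha, dimensionless
    pulsation_phase_offset: float = 0.0      # radians
    # one dict or a list of dicts: center_direction, angular_radius,
    # extra_amplitude, optional phase_offset (radians; pi gives a patch in
    # counter-phase, i.e. shape change without net volume change)
    focal_patch: dict | list | None = None
    boundary_noise_sd: float = 0.0           # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sac_radius > self.parent_radius > 0):
            raise ValueError("require sac_radius > parent_radius > 0")
        if self.n_phases < 4:
            raise ValueError("need at least 4 phases")
        if self.global_pulsation_fraction < 0:
            raise ValueError("pulsation fraction must be >= 0")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.boundary_noise_sd < 0:
            raise ValueError("boundary noise SD must be >= 0")

    @property
    def half_length(self) -> float:
        return self.parent_half_length if self.parent_half_length is not None else 3.0 * self.sac_radius

    def sac_radius_at(self, t: int) -> float:
        return self.sac_radius * (
            1.0
            + self.global_pulsation_fraction
            * math.sin(2.0 * math.pi * t / self.n_phases + self.pulsation_phase_offset)
        )

    def patch_list(self) -> list[dict]:
        if self.focal_patch is None:
            return []
        patches = self.focal_patch if isinstance(self.focal_patch, list) else [self.focal_patch]
        return [dict(p) for p in patches]

    def patch_scale_at(self, t: int, phase_offset: float = 0.0) -> float:
        """Phase modulation of a focal patch (zero at the reference phase
        when no offset is applied)."""
        return math.sin(
            2.0 * math.pi * t / self.n_phases + self.pulsation_phase_offset + phase_offset
        )


@dataclass(frozen=True)
class SignalSpec:
    """Ground truth for a synthetic phase-resolved geometric signal."""

    baseline_level: float = 50.0
    harmonic_amplitude: float = 0.0
    harmonic_phase: float = 0.0
    trend_slope: float = 0.0
    noise_sd: float = 0.0
    n_phases: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 4:
            raise ValueError("need at least 4 phases")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass
class PhaseVolume4D:
    """Per-phase binary voxel grids with shared spacing/origin metadata."""

    volumes: np.ndarray            # (n_phases, nx, ny, nz) bool
    spacing: float                 # mm, isotropic
    origin: np.ndarray             # mm, world coordinate of voxel (0,0,0)
    spec: PhantomSpec | None = None

    @property
    def n_phases(self) -> int:
        return self.volumes.shape[0]

    def voxel_volume(self) -> float:
        return self.spacing**3

    def phase_volume_series(self) -> PhaseSeries:
        """Voxel-count volume of each phase (mm^3) as a PhaseSeries."""
        counts = self.volumes.reshape(self.n_phases, -1).sum(axis=1)
        return PhaseSeries(counts * self.voxel_volume(), parameter_name="V_sacpar")


@dataclass(frozen=True)
class SignalSample:
    series: PhaseSeries
    truth_harmonic: np.ndarray
    truth_trend: np.ndarray
    noise: np.ndarray
    spec: SignalSpec


# ---------------------------------------------------------------- analytic

def sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


def spherical_cap_volume(r: float, a: float) -> float:
    """Volume of the spherical cap above a plane at signed distance ``a``
    from the centre of a sphere of radius ``r`` (a in [-r, r])."""
    if a >= r:
        return 0.0
    if a <= -r:
        return sphere_volume(r)
    h = r - a
    return math.pi * h**2 * (3.0 * r - h) / 3.0


def focal_patch_area(r: float, angular_radius: float) -> float:
    """Area of a spherical cap of half-angle ``angular_radius`` on a sphere
    of radius ``r``: 2*pi*r^2*(1 - cos(theta))."""
    return 2.0 * math.pi * r**2 * (1.0 - math.cos(angular_radius))


def analytic_sac_volume(spec: PhantomSpec, phase: int, n_theta: int = 4096) -> float:
    """Closed-form (quadrature) volume of the sac sphere-plus-patch at a phase.

    Integrates r(theta)^3/3 over solid angle, with
    r(theta) = R_t + e * taper(theta) * s(t) inside the patch. Ignores the
    parent-vessel overlap — compare against a sac-only voxelisation.
    """
    r_t = spec.sac_radius_at(phase)
    total = sphere_volume(r_t)
    # per-patch excess over the base sphere (patches assumed non-overlapping)
    for p in spec.patch_list():
        theta0 = p["angular_radius"]
        e = p["extra_amplitude"] * spec.patch_scale_at(phase, p.get("phase_offset", 0.0))
        theta = np.linspace(0.0, theta0, n_theta)
        taper = 0.5 * (1.0 + np.cos(math.pi * theta / theta0))
        r = r_t + e * taper
        excess = ((r**3) - r_t**3) / 3.0 * np.sin(theta)
        total += float(2.0 * math.pi * np.trapezoid(excess, theta))
    return total


# ------------------------------------------------------------- generators

def _grid(spec: PhantomSpec, margin: float) -> tuple[np.ndarray, ...]:
    c = np.asarray(spec.sac_center, dtype=float)
    axis = _unit(spec.parent_axis)
    r_max = spec.sac_radius * (1.0 + spec.global_pulsation_fraction)
    if spec.focal_patch is not None:
        r_max += max(p["extra_amplitude"] for p in spec.patch_list())
    half = spec.half_length
    ends = np.array([axis * half, -axis * half])
    if spec.extra_branch_axis is not None:
        b = _unit(spec.extra_branch_axis)
        ends = np.vstack([ends, b * half])
    lo = np.minimum(c - r_max, ends.min(axis=0) - spec.parent_radius) - margin
    hi = np.maximum(c + r_max, ends.max(axis=0) + spec.parent_radius) + margin
    s = spec.voxel_spacing
    # Snap the grid to the world lattice so symmetric shapes voxelise
    # symmetrically (off-lattice grids create even-width ribbons that 3-D
    # thinning retracts into half-missing centerlines).
    lo = np.floor(lo / s) * s
    xs = np.arange(lo[0], hi[0] + s, s)
    ys = np.arange(lo[1], hi[1] + s, s)
    zs = np.arange(lo[2], hi[2] + s, s)
    return xs, ys, zs


def _sac_signed_excess(spec: PhantomSpec, t: int, pts_shape, q, rho) -> np.ndarray:
    """r(theta, t) - |p - c|: positive inside the (possibly bulged) sac."""
    r_t = spec.sac_radius_at(t)
    r_dir = np.full(pts_shape, r_t)
    for p in spec.patch_list():
        u = _unit(p["center_direction"])
        theta0 = float(p["angular_radius"])
        e = float(p["extra_amplitude"]) * spec.patch_scale_at(t, p.get("phase_offset", 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_t = np.clip(
                np.tensordot(q, u, axes=([3], [0])) / np.where(rho > 0, rho, 1.0), -1, 1
            )
        theta = np.arccos(cos_t)
        taper = np.where(theta < theta0, 0.5 * (1.0 + np.cos(math.pi * theta / theta0)), 0.0)
        r_dir = r_dir + e * taper
    return r_dir - rho


def generate_phantom(
    spec: PhantomSpec, include_parent: bool = True, margin: float = 2.0
) -> PhaseVolume4D:
    """Voxelise the phantom at every cardiac phase.

    ``include_parent=False`` voxelises the sac alone (useful when checking
    against the closed-form sphere-plus-patch volume). Boundary noise is a
    per-voxel, per-phase Gaussian perturbation of the surface position
    (mm), realised by jittering the implicit-surface threshold; it flips
    only voxels within a few SDs of the boundary.
    """
    xs, ys, zs = _grid(spec, margin)
    if min(len(xs), len(ys), len(zs)) < 8:
        raise ValueError("voxel grid too small to contain the phantom; reduce spacing")
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    c = np.asarray(spec.sac_center, dtype=float)
    q = pts - c
    rho = np.linalg.norm(q, axis=-1)

    axis = _unit(spec.parent_axis)
    s_ax = np.tensordot(pts, axis, axes=([3], [0]))
    radial = np.linalg.norm(pts - s_ax[..., None] * axis, axis=-1)
    in_parent = (radial <= spec.parent_radius) & (np.abs(s_ax) <= spec.half_length)
    if spec.extra_branch_axis is not None:
        b = _unit(spec.extra_branch_axis)
        s_b = np.tensordot(pts, b, axes=([3], [0]))
        radial_b = np.linalg.norm(pts - s_b[..., None] * b, axis=-1)
        in_parent |= (radial_b <= spec.parent_radius) & (s_b >= 0) & (s_b <= spec.half_length)

    rng = np.random.default_rng(spec.seed)
    vols = np.empty((spec.n_phases,) + X.shape, dtype=bool)
    for t in range(spec.n_phases):
        excess = _sac_signed_excess(spec, t, X.shape, q, rho)
        if spec.boundary_noise_sd > 0:
            jitter = rng.normal(0.0, spec.boundary_noise_sd, size=X.shape)
        else:
            jitter = 0.0
        in_sac = excess + jitter >= 0.0
        vols[t] = (in_sac | in_parent) if include_parent else in_sac
    origin = np.array([xs[0], ys[0], zs[0]])
    return PhaseVolume4D(vols, spec.voxel_spacing, origin, spec)


def generate_signal(spec: SignalSpec) -> SignalSample:
    """X(t) = baseline + A sin(2*pi*t/n + phi) + slope*t + noise."""
    t = np.arange(spec.n_phases)
    harmonic = spec.harmonic_amplitude * np.sin(
        2.0 * math.pi * t / spec.n_phases + spec.harmonic_phase
    )
    trend = spec.trend_slope * t
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, spec.n_phases) if spec.noise_sd > 0 else np.zeros(spec.n_phases)
    values = spec.baseline_level + harmonic + trend + noise
    return SignalSample(PhaseSeries(values), harmonic, trend, noise, spec)


def generate_repeatability_pairs(
    n_pairs: int, true_value: float, measurement_sd: float, seed: int = 0
) -> np.ndarray:
    """(m1, m2) pairs, each the true value plus independent Gaussian error."""
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    if measurement_sd < 0:
        raise ValueError("measurement SD must be >= 0")
    rng = np.random.default_rng(seed)
    return true_value + rng.normal(0.0, measurement_sd, size=(n_pairs, 2))


# ------------------------------------------------------------------- I/O

def write_phantom_nrrd(vol4d: PhaseVolume4D, out_dir, stem: str = "phase") -> list[Path]:
    """Write one NRRD per phase plus a ground-truth JSON sidecar."""
    from . import _nrrd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(vol4d.n_phases):
        p = out / f"{stem}_{t:02d}.nrrd"
        _nrrd.write_nrrd(p, vol4d.volumes[t].astype(np.uint8), vol4d.spacing, vol4d.origin)
        paths.append(p)
    if vol4d.spec is not None:
        spec = vol4d.spec
        truth = {
            "sac_radius": spec.sac_radius,
            "sac_center": list(spec.sac_center),
            "parent_radius": spec.parent_radius,
            "n_phases": spec.n_phases,
            "global_pulsation_fraction": spec.global_pulsation_fraction,
            "boundary_noise_sd": spec.boundary_noise_sd,
            "focal_patch": spec.focal_patch and {
                **{k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in spec.focal_patch.items()}
            },
            "seed": spec.seed,
            "analytic_sac_volume_per_phase": [
                analytic_sac_volume(spec, t) for t in range(spec.n_phases)
            ],
        }
        (out / f"{stem}_truth.json").write_text(json.dumps(truth, indent=2))
    return paths


def write_signal_csv(sample: SignalSample, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"phase_index": np.arange(sample.series.phase_count), "value": sample.series.values}
    ).to_csv(path, index=False)


def read_signal_csv(path, parameter_name: str = "V_sac") -> PhaseSeries:
    import pandas as pd

    df = pd.read_csv(path).sort_values("phase_index")
    return PhaseSeries(df["value"].to_numpy(dtype=float), parameter_name=parameter_name)
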