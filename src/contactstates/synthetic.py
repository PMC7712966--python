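"""Synthetic conformational-transition trajectories (chomp, heli, glob).

Three geometric toy systems, each a time series of N frames over ~P points
whose contact map evolves slowly and monotonically with time, emulating a
domain motion.  Ground truth is the frame order itself: a good classifier
should carve the trajectory into contiguous time runs.

* **chomp** — two straight arms of unit-spaced points hinged at the origin
  in 2-D; the inter-arm angle closes linearly from 150° to 1°, so
  cross-arm contacts zip up progressively from the hinge outward.  The
  near-complete closure matters: a pair at matching arc length s touches
  once the angle falls below ~2/s radians, so only closing to ~1° lets the
  contact front traverse arms hundreds of points long and keeps the
  benchmark's structure comparable across the whole tested P range.
* **heli** — a unit-spaced line of P points in 3-D rotating rigidly by 180°
  about an axis through its midpoint, plus a static reference line of
  ⌊P/3⌋ points offset 0.5 out of plane (without a fixed reference a rigid
  rotation preserves every internal distance and no contact ever changes).
* **glob** — three ~P/3-point spheres of radius 1.5 at mutual separation
  5.5; the right sphere swings 90° behind the plane and back while the top
  sphere descends 2 units, closing its gap to the others below the contact
  cutoff late in the trajectory.

After the deterministic motion, i.i.d. Gaussian noise of width σ (default
0.1) is added to every coordinate.  Because points sit at unit-ish
spacings, some pairs ride near the cutoff and flip stochastically from
frame to frame; these survive pruning as uninformative noise features, a
deliberate property of the benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contacts import FeatureMatrix, Trajectory, extract_contacts, prune_constant_features

SYSTEMS = ("chomp", "heli", "glob")


@dataclass
class SystemSpec:
    """Which system to generate and under what conditions.

    P is the approximate total particle count (generators round per
    component and report the realized total); geometry constants are
    exposed for variation studies but fixed for the reference benchmark.
    """

    name: str
    P: int = 222
    N: int = 1000
    noise_sigma: float = 0.1
    seed: int = 0
    cutoff: float = 2.0
    # geometry constants
    chomp_angle_start_deg: float = 150.0
    chomp_angle_end_deg: float = 1.0
    heli_rotation_deg: float = 180.0
    heli_offset: float = 0.5
    glob_radius: float = 1.5
    glob_separation: float = 5.5
    glob_top_drop: float = 2.0
    glob_swing_deg: float = 90.0

    def __post_init__(self):
        if self.name not in SYSTEMS:
            raise ValueError(f"unknown system {self.name!r}; choose from {SYSTEMS}")
        if self.P < 6 or self.N < 10 or self.noise_sigma < 0:
            raise ValueError("need P >= 6, N >= 10, noise_sigma >= 0")


def _add_noise(coords: np.ndarray, spec: SystemSpec) -> np.ndarray:
    rng = np.random.default_rng([int(spec.seed), SYSTEMS.index(spec.name)])
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    return coords


def gen_chomp(spec: SystemSpec) -> Trajectory:
    """Closing 2-D hinge: arms of ⌈P/2⌉ and ⌊P/2⌋ unit-spaced points."""
    n1 = (spec.P + 1) // 2
    n2 = spec.P // 2
    half = 0.5 * np.deg2rad(np.linspace(spec.chomp_angle_start_deg,
                                        spec.chomp_angle_end_deg, spec.N))
    r1 = np.arange(1, n1 + 1, dtype=float)
    r2 = np.arange(1, n2 + 1, dtype=float)
    coords = np.empty((spec.N, n1 + n2, 2))
    coords[:, :n1, 0] = np.cos(half)[:, None] * r1
    coords[:, :n1, 1] = np.sin(half)[:, None] * r1
    coords[:, n1:, 0] = np.cos(half)[:, None] * r2
    coords[:, n1:, 1] = -np.sin(half)[:, None] * r2
    return Trajectory(coords=_add_noise(coords, spec))


def gen_heli(spec: SystemSpec) -> Trajectory:
    """Line rotating 180° about its midpoint past a fixed reference line."""
    n_rot, n_fix = spec.P, spec.P // 3
    theta = np.deg2rad(spec.heli_rotation_deg) * np.linspace(0.0, 1.0, spec.N)
    radii = np.arange(n_rot, dtype=float) - (n_rot - 1) / 2.0
    coords = np.zeros((spec.N, n_rot + n_fix, 3))
    coords[:, :n_rot, 0] = np.cos(theta)[:, None] * radii
    coords[:, :n_rot, 1] = np.sin(theta)[:, None] * radii
    fix_x = np.arange(n_fix, dtype=float) - (n_fix - 1) / 2.0
    coords[:, n_rot:, 0] = fix_x
    coords[:, n_rot:, 2] = spec.heli_offset
    return Trajectory(coords=_add_noise(coords, spec))


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n quasi-uniform points on a sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - y * y))
    return radius * np.column_stack([r * np.cos(phi), y, r * np.sin(phi)])


def gen_glob(spec: SystemSpec) -> Trajectory:
    """Three point-spheres: right swings behind and back, top descends."""
    n = spec.P // 3
    s = spec.glob_separation
    pts = _fibonacci_sphere(n, spec.glob_radius)
    t = np.linspace(0.0, 1.0, spec.N)
    left = np.array([-s / 2.0, 0.0, 0.0])
    top0 = np.array([0.0, s * math.sqrt(3.0) / 2.0, 0.0])
    psi = np.deg2rad(spec.glob_swing_deg) * np.sin(math.pi * t)
    right = np.column_stack([(s / 2.0) * np.cos(psi),
                             np.zeros(spec.N),
                             -(s / 2.0) * np.sin(psi)])
    top = top0[None, :] - np.column_stack([np.zeros(spec.N),
                                           spec.glob_top_drop * t,
                                           np.zeros(spec.N)])
    coords = np.empty((spec.N, 3 * n, 3))
    coords[:, :n] = left[None, None, :] + pts[None, :, :]
    coords[:, n:2 * n] = right[:, None, :] + pts[None, :, :]
    coords[:, 2 * n:] = top[:, None, :] + pts[None, :, :]
    return Trajectory(coords=_add_noise(coords, spec))


_GENERATORS = {"chomp": gen_chomp, "heli": gen_heli, "glob": gen_glob}


def gen_system(spec: SystemSpec):
    """Generate a system and featurize it: (Trajectory, pruned FeatureMatrix)."""
    traj = _GENERATORS[spec.name](spec)
    fm = prune_constant_features(extract_contacts(traj, spec.cutoff))
    return traj, fm
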