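"""Binary contact featurization of coordinate trajectories.

A conformational ensemble enters the classifier as an N × M bit matrix: one
row per frame, one column per point pair, a 1 wherever the pair is closer
than a distance cutoff.  Columns that never vary carry no information and
are pruned before modelling (this changes the feature count M that the
model, and hence the Dirichlet concentration α = M + 1, sees).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist


@dataclass
class Trajectory:
    """Time-ordered point coordinates, shape (N frames, P points, d dims)."""

    coords: np.ndarray
    point_labels: list = None
    frame_order: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must have shape (N, P, d)")
        n, p, d = self.coords.shape
        if n < 2 or p < 2 or d not in (2, 3):
            raise ValueError(f"need N >= 2, P >= 2, d in {{2,3}}; got {self.coords.shape}")
        if self.point_labels is None:
            self.point_labels = list(range(p))
        if self.frame_order is None:
            self.frame_order = np.arange(n)
        self.frame_order = np.asarray(self.frame_order)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]


@dataclass
class FeatureMatrix:
    """Binary contact features: x[i, j] = 1 iff pair j touches in frame i.

    ``pairs`` holds the (u, v) point indices (0-based, u < v, lexicographic)
    labelling each column.  ``orig_index`` maps surviving columns back to
    their pre-pruning column index so pruned matrices stay interpretable.
    """

    x: np.ndarray
    pairs: np.ndarray
    cutoff: float
    pruned: bool = False
    orig_index: np.ndarray = None
    point_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.x = np.ascontiguousarray(self.x, dtype=np.uint8)
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if self.x.ndim != 2 or self.x.shape[1] != len(self.pairs):
            raise ValueError("x must be (N, M) with one pair label per column")
        if self.x.size and not np.isin(self.x, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")
        if len(self.pairs) and not (self.pairs[:, 0] < self.pairs[:, 1]).all():
            raise ValueError("pairs must satisfy u < v")
        if self.orig_index is None:
            self.orig_index = np.arange(self.x.shape[1])
        self.orig_index = np.asarray(self.orig_index, dtype=np.int64)

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_features(self) -> int:
        return self.x.shape[1]


def _pair_list(p: int) -> np.ndarray:
    """All (u, v), u < v, in lexicographic order (the pdist convention)."""
    return np.array(list(itertools.combinations(range(p), 2)), dtype=np.int64)


def extract_contacts(traj: Trajectory, cutoff: float) -> FeatureMatrix:
    """Binarize pairwise distances: contact iff d(u, v) < cutoff (strict).

    Strict inequality follows the "less than" convention; with continuous
    noisy coordinates the boundary has measure zero.  Distances are plain
    Euclidean (no periodic boundaries).
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    bad = ~np.isfinite(traj.coords).all(axis=(1, 2))
    if bad.any():
        raise ValueError(f"non-finite coordinates in frame {int(np.nonzero(bad)[0][0])}")
    n, p, _ = traj.coords.shape
    x = np.empty((n, p * (p - 1) // 2), dtype=np.uint8)
    for i in range(n):
        x[i] = pdist(traj.coords[i]) < cutoff
    return FeatureMatrix(x=x, pairs=_pair_list(p), cutoff=float(cutoff),
                         pruned=False, point_labels=list(traj.point_labels))


def prune_constant_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Drop columns that are all-0 or all-1 across frames.

    Idempotent; raises if nothing varies (the model would see M = 0).
    """
    colsum = fm.x.sum(axis=0, dtype=np.int64)
    keep = (colsum > 0) & (colsum < fm.n_frames)
    if not keep.any():
        raise ValueError("no informative features: every contact is constant across frames")
    return replace(fm, x=fm.x[:, keep], pairs=fm.pairs[keep], pruned=True,
                   orig_index=fm.orig_index[keep])


def extract_ca_contacts(structure_file, traj_files=(), cutoff: float = 5.0) -> FeatureMatrix:
    """Cα–Cα contact features from standard structure/trajectory files.

    ``structure_file`` provides the topology (e.g. PDB); ``traj_files`` may
    add coordinate frames (multi-model PDB, DCD, XTC, ... — anything
    MDAnalysis reads).  Contacts use d < cutoff (default 5 Å) on alpha
    carbons only, then constant columns are pruned.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(structure_file), *[str(t) for t in traj_files])
    ca = u.select_atoms("name CA")
    if len(ca) < 2:
        raise ValueError("fewer than 2 Cα atoms found")
    coords = np.array([ca.positions.copy() for _ in u.trajectory], dtype=float)
    traj = Trajectory(coords=coords, point_labels=list(ca.resids))
    return prune_constant_features(extract_contacts(traj, cutoff))


# ---------------------------------------------------------------------------
# on-disk formats

def write_features(path, fm: FeatureMatrix) -> None:
    """Save a feature matrix as a compressed .npz container."""
    np.savez_compressed(
        path, x=fm.x, pairs=fm.pairs, cutoff=np.float64(fm.cutoff),
        pruned=np.bool_(fm.pruned), orig_index=fm.orig_index,
        point_labels=np.asarray(fm.point_labels),
    )


def read_features(path) -> FeatureMatrix:
    with np.load(path, allow_pickle=False) as z:
        return FeatureMatrix(
            x=z["x"], pairs=z["pairs"], cutoff=float(z["cutoff"]),
            pruned=bool(z["pruned"]), orig_index=z["orig_index"],
            point_labels=list(z["point_labels"]),
        )


def write_pair_labels(path, fm: FeatureMatrix) -> None:
    """Plain-text sidecar: one '<u> <v>' pair per column, 0-based."""
    with open(path, "w") as fh:
        for u, v in fm.pairs:
            fh.write(f"{u} {v}\n")


def write_xyz(path, traj: Trajectory) -> None:
    """Multi-frame XYZ text; 2-D trajectories are padded with z = 0."""
    coords = traj.coords
    if coords.shape[2] == 2:
        coords = np.concatenate([coords, np.zeros(coords.shape[:2] + (1,))], axis=2)
    with open(path, "w") as fh:
        for i, frame in enumerate(coords):
            fh.write(f"{frame.shape[0]}\nframe {i}\n")
            for lbl, (px, py, pz) in zip(traj.point_labels, frame):
                fh.write(f"P{lbl} {px:.6f} {py:.6f} {pz:.6f}\n")


def read_xyz(path) -> Trajectory:
    frames, labels = [], None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        nat = int(lines[i])
        block = lines[i + 2:i + 2 + nat]
        labels = [ln.split()[0].lstrip("P") for ln in block]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + nat
    return Trajectory(coords=np.array(frames), point_labels=labels)
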