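"""Core in-memory containers shared across the morphometry pipeline.

World coordinates are RAS millimetres throughout; voxel indices are 0-based and
the NIfTI-style affine is the single source of grid-to-world truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import trimesh


def affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    """Diagonal RAS affine placing voxel (0,0,0) at the world origin."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class LabelVolume:
    """Integer-labeled 3D grid with anisotropic voxel spacing.

    Label 0 is reserved for background. ``label_names`` maps label id to
    structure name (e.g. ``{1: "amygdala_left"}``).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise TypeError("label grid must be integer-typed")
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if (self.grid < 0).any():
            raise ValueError("labels must be non-negative (0 = background)")
        if self.affine is None:
            self.affine = affine_from_spacing(self.spacing)

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return float(dx * dy * dz)

    def voxel_centers_world(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers, optionally restricted to a mask."""
        if mask is None:
            idx = np.stack(
                np.meshgrid(*(np.arange(n) for n in self.grid.shape), indexing="ij"),
                axis=-1,
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(mask)
        homog = np.c_[idx, np.ones(len(idx))]
        return (homog @ self.affine.T)[:, :3]

    def labels_present(self) -> list[int]:
        present = np.unique(self.grid)
        return [int(l) for l in present if l != 0]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.grid.astype(np.int16), self.affine)

    @classmethod
    def from_nifti(cls, path, label_names: dict[int, str] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            grid=np.asarray(img.dataobj).astype(np.int32),
            spacing=zooms,
            affine=np.asarray(img.affine),
            label_names=dict(label_names or {}),
        )


@dataclass
class PETVolume:
    """PET activity grid (Bq/mL) on the same frame as the label volume."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    frame_of_reference: str = "mri"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("PET grid must be 3D")
        if self.affine is None:
            self.affine = affine_from_spacing(self.spacing)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.grid.astype(np.float32), self.affine)


@dataclass
class TriMesh:
    """Oriented triangle surface in world (mm) coordinates."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    # --- geometry -------------------------------------------------------
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals_raw(self) -> np.ndarray:
        """Unnormalized face normals; magnitude equals face area."""
        tri = self.vertices[self.faces]
        return 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def face_areas(self) -> np.ndarray:
        return np.linalg.norm(self.face_normals_raw(), axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted, unit vertex normals."""
        fn = self.face_normals_raw()
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return vn / norms

    def area(self) -> float:
        return float(self.face_areas().sum())

    def enclosed_volume(self) -> float:
        """Signed volume via the divergence theorem (positive if outward-oriented)."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        return TriMesh(vertices=np.asarray(vertices, float), faces=self.faces.copy())

    def flipped(self) -> "TriMesh":
        return TriMesh(vertices=self.vertices.copy(), faces=self.faces[:, ::-1].copy())

    # --- interop --------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriMesh":
        return cls(vertices=np.asarray(tm.vertices, float), faces=np.asarray(tm.faces, np.int64))

    def save_ply(self, path) -> None:
        self.to_trimesh().export(str(path), file_type="ply", encoding="ascii")

    @classmethod
    def load(cls, path) -> "TriMesh":
        return cls.from_trimesh(trimesh.load_mesh(str(path), process=False))

    @classmethod
    def icosphere(cls, subdivisions: int = 3, radius: float = 1.0, center=(0.0, 0.0, 0.0)) -> "TriMesh":
        tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return cls(vertices=np.asarray(tm.vertices) + np.asarray(center, float), faces=np.asarray(tm.faces))


@dataclass
class Atlas:
    """Subregion atlas: labeled grid partitioning a structure, with provenance."""

    labels: LabelVolume
    provenance: str = ""
    boundary_meshes: dict[str, "TriMesh"] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def subregion_volumes(self) -> dict[int, float]:
        vv = self.labels.voxel_volume
        return {
            lab: float((self.labels.grid == lab).sum()) * vv
            for lab in self.labels.labels_present()
        }


@dataclass
class Timepoint:
    """One scan session of a longitudinal series."""

    age: float
    labels: LabelVolume | None = None
    inner_mesh: TriMesh | None = None
    outer_mesh: TriMesh | None = None
    pet: PETVolume | None = None
    structure_meshes: dict[str, TriMesh] = field(default_factory=dict)
    degenerate: bool = False


@dataclass
class LongitudinalSeries:
    """One subject's time-stamped volumes/meshes, the unit of rate estimation."""

    subject_id: str
    timepoints: list[Timepoint]
    group_label: str = ""
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ages = self.ages
        if len(ages) >= 2 and not np.all(np.diff(ages) > 0):
            raise ValueError("timepoint ages must be strictly increasing")

    @property
    def ages(self) -> np.ndarray:
        return np.array([tp.age for tp in self.timepoints], dtype=float)

    def __len__(self) -> int:
        return len(self.timepoints)
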