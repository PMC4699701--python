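"""Domain types shared across the pipeline.

Coordinate conventions
----------------------
The standardized nucleus space is right-handed with x = medio-lateral,
y = dorso-ventral (positive dorsal), z = antero-posterior, all in µm.
V1 injection sites live in a separate 2D space measured in mm relative to
lambda (ap anterior-positive, ml lateral-positive).  The mixed µm/mm units
follow common usage; every order metric downstream is similarity-invariant,
so the unit mismatch between the two spaces is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import trimesh

from ._geometry import contains as _mesh_contains
from .errors import MeshValidationError, MissingInjectionError


class Group(str, Enum):
    """Experimental groups: adult wild type, neonates, β2-nAChR knockout."""

    WT = "WT"
    P6 = "P6"
    P12 = "P12"
    B2KO = "B2KO"


class Tracer(str, Enum):
    red = "red"
    green = "green"


@dataclass(frozen=True)
class CellRecord:
    """One retrogradely labelled soma in the group standardized space (µm)."""

    animal_id: str
    group: Group
    tracer: Tracer
    x_um: float
    y_um: float
    z_um: float


@dataclass(frozen=True)
class InjectionRecord:
    """V1 injection site, mm relative to lambda; volume in nl (optional)."""

    animal_id: str
    ap_mm: float
    ml_mm: float
    volume_nl: float | None = None


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [c.animal_id for c in cells],
            "group": [c.group.value for c in cells],
            "tracer": [c.tracer.value for c in cells],
            "x_um": [c.x_um for c in cells],
            "y_um": [c.y_um for c in cells],
            "z_um": [c.z_um for c in cells],
        }
    )


def cell_coordinates(cells: list[CellRecord]) -> np.ndarray:
    """(n, 3) array of cell coordinates in µm."""
    return np.array([[c.x_um, c.y_um, c.z_um] for c in cells], dtype=float)


class NucleusMesh:
    """Closed triangulated nucleus boundary with a designated pial cap.

    Parameters
    ----------
    vertices : (V, 3) float array, µm
    faces : (F, 3) int array
    pial_faces : 1D int array of face indices forming the pial surface;
        must be a non-empty proper subset of all faces.
    """

    def __init__(self, vertices, faces, pial_faces):
        mesh = trimesh.Trimesh(
            vertices=np.asarray(vertices, dtype=float),
            faces=np.asarray(faces, dtype=np.int64),
            process=False,
        )
        self._mesh = mesh
        self.pial_faces = np.unique(np.asarray(pial_faces, dtype=np.int64))
        self.validate()
        # normalize orientation: outward normals <=> positive enclosed volume
        if self._mesh.volume < 0:
            self._mesh.invert()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        m = self._mesh
        if len(m.faces) == 0 or m.faces.shape[1] != 3:
            raise MeshValidationError("mesh has no triangular faces")
        if not m.is_watertight:
            raise MeshValidationError("mesh not closed (open edges present)")
        if not m.is_winding_consistent:
            raise MeshValidationError("mesh winding inconsistent (non-manifold)")
        n_faces = len(m.faces)
        if self.pial_faces.size == 0:
            raise MeshValidationError("pial face set is empty")
        if self.pial_faces.min() < 0 or self.pial_faces.max() >= n_faces:
            raise MeshValidationError("pial face index out of range")
        if self.pial_faces.size >= n_faces:
            raise MeshValidationError("pial face set must be a proper subset")

    # -- accessors -------------------------------------------------------
    @property
    def trimesh(self) -> trimesh.Trimesh:
        return self._mesh

    @property
    def vertices(self) -> np.ndarray:
        return self._mesh.vertices.view(np.ndarray)

    @property
    def faces(self) -> np.ndarray:
        return self._mesh.faces.view(np.ndarray)

    @property
    def volume_um3(self) -> float:
        return float(abs(self._mesh.volume))

    def is_pial_face(self, face_index: int) -> bool:
        return bool(np.isin(face_index, self.pial_faces))

    def contains_within(self, points: np.ndarray, tol_um: float = 0.0) -> np.ndarray:
        """True for points inside or within ``tol_um`` of the surface."""
        points = np.atleast_2d(points)
        inside = _mesh_contains(self.vertices, self.faces, points)
        if tol_um > 0 and not inside.all():
            outside = ~inside
            _, dist, _ = trimesh.proximity.closest_point_naive(self._mesh, points[outside])
            inside[outside.nonzero()[0][dist <= tol_um]] = True
        return inside


@dataclass
class Dataset:
    """One group's cells, injection sites and nucleus mesh."""

    cells: list[CellRecord]
    injections: list[InjectionRecord]
    mesh: NucleusMesh
    group: Group
    animal_ids: list[str] = field(init=False)

    def __post_init__(self):
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.animal_id, None)
        self.animal_ids = list(seen)

    def validate(self, containment_tol_um: float = 150.0) -> None:
        """Check the cells/injections/mesh invariants.

        Every animal with cells must have exactly one injection record, and
        all cells must lie inside or within ``containment_tol_um`` of the
        mesh (tracer scatter can sit marginally outside the fitted surface).
        """
        inj_ids = [i.animal_id for i in self.injections]
        if len(set(inj_ids)) != len(inj_ids):
            dupes = sorted({a for a in inj_ids if inj_ids.count(a) > 1})
            raise MissingInjectionError(f"duplicate injection records: {dupes}")
        missing = [a for a in self.animal_ids if a not in inj_ids]
        if missing:
            raise MissingInjectionError(f"animals without injection record: {missing}")
        coords = cell_coordinates(self.cells)
        if len(coords):
            ok = self.mesh.contains_within(coords, tol_um=containment_tol_um)
            if not ok.all():
                n_bad = int((~ok).sum())
                raise MeshValidationError(
                    f"{n_bad} cells lie > {containment_tol_um} µm outside the mesh"
                )

    def cells_for(self, animal_id: str) -> np.ndarray:
        return cell_coordinates([c for c in self.cells if c.animal_id == animal_id])

    def injection_for(self, animal_id: str) -> InjectionRecord:
        for rec in self.injections:
            if rec.animal_id == animal_id:
                return rec
        raise MissingInjectionError(f"no injection record for {animal_id!r}")
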