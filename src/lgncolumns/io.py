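"""Reading and writing of cell tables, injection tables and nucleus meshes.

Tables are comma-delimited UTF-8 with a mandatory header.  Cell coordinates
are µm in the standardized space; injection coordinates are mm relative to
lambda.  Meshes are OFF or PLY triangle meshes with a sidecar text file
listing the 0-based pial face indices, one per line.

Floats are written with ``repr`` (shortest round-trip form) so that
``write_cells(read_cells(p))`` reproduces a file previously written by
:func:`write_cells` byte for byte.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import trimesh

from .core import CellRecord, Group, InjectionRecord, NucleusMesh, Tracer
from .errors import MeshValidationError, TableParseError

CELL_COLUMNS = ["animal_id", "group", "tracer", "x_um", "y_um", "z_um"]
INJECTION_COLUMNS = ["animal_id", "ap_mm", "ml_mm", "volume_nl"]


def _parse_float(text: str, column: str, path, line: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise TableParseError(
            f"column {column!r}: unparseable number {text!r}", path, line
        ) from None
    if not np.isfinite(value):
        raise TableParseError(f"column {column!r}: non-finite value {text!r}", path, line)
    return value


def _parse_enum(text: str, enum_cls, column: str, path, line: int):
    try:
        return enum_cls(text)
    except ValueError:
        allowed = [e.value for e in enum_cls]
        raise TableParseError(
            f"column {column!r}: unknown value {text!r} (allowed: {allowed})",
            path,
            line,
        ) from None


def _open_table(path, required: list[str]):
    path = Path(path)
    handle = path.open(newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    header = reader.fieldnames or []
    missing = [c for c in required if c not in header]
    if missing:
        handle.close()
        raise TableParseError(f"missing column(s) {missing}", path, 1)
    return path, handle, reader


def read_cells(path) -> list[CellRecord]:
    """Read a labelled-cell table; errors carry the offending line number."""
    path, handle, reader = _open_table(path, CELL_COLUMNS)
    records: list[CellRecord] = []
    with handle:
        for line, row in enumerate(reader, start=2):
            records.append(
                CellRecord(
                    animal_id=row["animal_id"],
                    group=_parse_enum(row["group"], Group, "group", path, line),
                    tracer=_parse_enum(row["tracer"], Tracer, "tracer", path, line),
                    x_um=_parse_float(row["x_um"], "x_um", path, line),
                    y_um=_parse_float(row["y_um"], "y_um", path, line),
                    z_um=_parse_float(row["z_um"], "z_um", path, line),
                )
            )
    return records


def write_cells(records: list[CellRecord], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CELL_COLUMNS)
        for r in records:
            writer.writerow(
                [r.animal_id, r.group.value, r.tracer.value, repr(r.x_um), repr(r.y_um), repr(r.z_um)]
            )


def read_injections(path) -> list[InjectionRecord]:
    """Read a V1 injection table (volume_nl may be blank)."""
    path, handle, reader = _open_table(path, INJECTION_COLUMNS[:3])
    records: list[InjectionRecord] = []
    seen: set[str] = set()
    with handle:
        for line, row in enumerate(reader, start=2):
            animal_id = row["animal_id"]
            if animal_id in seen:
                raise TableParseError(f"duplicate animal_id {animal_id!r}", path, line)
            seen.add(animal_id)
            vol_text = (row.get("volume_nl") or "").strip()
            records.append(
                InjectionRecord(
                    animal_id=animal_id,
                    ap_mm=_parse_float(row["ap_mm"], "ap_mm", path, line),
                    ml_mm=_parse_float(row["ml_mm"], "ml_mm", path, line),
                    volume_nl=_parse_float(vol_text, "volume_nl", path, line)
                    if vol_text
                    else None,
                )
            )
    return records


def write_injections(records: list[InjectionRecord], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(INJECTION_COLUMNS)
        for r in records:
            vol = "" if r.volume_nl is None else repr(r.volume_nl)
            writer.writerow([r.animal_id, repr(r.ap_mm), repr(r.ml_mm), vol])


# ---------------------------------------------------------------------------
# meshes


def read_mesh(path, pial_path) -> NucleusMesh:
    """Load an OFF/PLY triangle mesh plus a pial-face sidecar.

    The sidecar lists 0-based face indices, one per line; blank lines and
    ``#`` comments are ignored.  Validation (closedness, manifoldness,
    outward orientation, pial subset) happens in :class:`NucleusMesh`.
    """
    path = Path(path)
    loaded = trimesh.load(path, process=False, force="mesh")
    if not isinstance(loaded, trimesh.Trimesh):
        raise MeshValidationError(f"{path}: not a triangle mesh")
    pial: list[int] = []
    for line_no, raw in enumerate(Path(pial_path).read_text().splitlines(), start=1):
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue
        try:
            pial.append(int(text))
        except ValueError:
            raise TableParseError(f"bad pial face index {text!r}", pial_path, line_no) from None
    return NucleusMesh(loaded.vertices, loaded.faces, pial)


def write_mesh(mesh: NucleusMesh, path, pial_path) -> None:
    path = Path(path)
    mesh.trimesh.export(path)
    Path(pial_path).write_text("".join(f"{i}\n" for i in mesh.pial_faces))


# ---------------------------------------------------------------------------
# results


def write_summary_json(summary: dict, path) -> None:
    """Write the versioned pipeline summary deterministically."""
    Path(path).write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")


def read_summary_json(path) -> dict:
    return json.loads(Path(path).read_text())
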