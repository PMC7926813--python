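"""Phantom-file plumbing: STL cavity files and the build manifest.

A phantom is a set of 3D-printed cavities, each filled with a mixture
mimicking one tissue.  This module parses/validates the STL geometry
files (both the ASCII dialect and the little-endian binary dialect with
50-byte facet records), binds cavities to tissues, runs the recipe
optimizer once per distinct tissue, and writes a JSON manifest that
downstream tools can consume.

The STL reader is deliberately small and strict: it reports a summary
(triangle count, bounding box, dialect, a watertightness heuristic) and
refuses files whose declared binary triangle count does not match the
payload, reporting the byte offset at which the file ends prematurely.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .mixing_laws import MixingLaw
from .recipe_builder import Recipe, build_recipe
from .recipe_optimizer import FitProblem, FitResult, fit
from .tissue_dielectrics import FrequencyGrid, ValidationError, list_tissues, load_tissue

logger = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = 1

_BINARY_HEADER_BYTES = 80
_BINARY_FACET_BYTES = 50


class StlFormatError(ValueError):
    """Raised for malformed STL files."""


@dataclass(frozen=True)
class StlSummary:
    triangle_count: int
    bbox_min_mm: tuple
    bbox_max_mm: tuple
    file_format: str  # "ascii" | "binary"
    watertight_hint: bool

    def to_dict(self) -> dict:
        return {
            "triangle_count": self.triangle_count,
            "bbox_min_mm": list(self.bbox_min_mm),
            "bbox_max_mm": list(self.bbox_max_mm),
            "file_format": self.file_format,
            "watertight_hint": self.watertight_hint,
        }


def _summarize(triangles: np.ndarray, fmt: str) -> StlSummary:
    if len(triangles) < 1:
        raise StlFormatError("STL contains no facets")
    pts = triangles.reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise StlFormatError("STL contains non-finite vertex coordinates")
    # watertight heuristic: every undirected edge shared by exactly 2 facets
    edges: Dict[tuple, int] = {}
    for tri in np.round(triangles, 9):
        v = [tuple(p) for p in tri]
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = tuple(sorted((v[a], v[b])))
            edges[key] = edges.get(key, 0) + 1
    watertight = all(c == 2 for c in edges.values())
    return StlSummary(
        triangle_count=int(len(triangles)),
        bbox_min_mm=tuple(float(x) for x in pts.min(axis=0)),
        bbox_max_mm=tuple(float(x) for x in pts.max(axis=0)),
        file_format=fmt,
        watertight_hint=watertight,
    )


def _parse_binary(data: bytes) -> np.ndarray:
    if len(data) < _BINARY_HEADER_BYTES + 4:
        raise StlFormatError(
            f"binary STL truncated in header: file ends at byte {len(data)}, "
            f"need at least {_BINARY_HEADER_BYTES + 4}"
        )
    (count,) = struct.unpack_from("<I", data, _BINARY_HEADER_BYTES)
    expected = _BINARY_HEADER_BYTES + 4 + count * _BINARY_FACET_BYTES
    if len(data) < expected:
        raise StlFormatError(
            f"binary STL declares {count} facets ({expected} bytes) but file "
            f"ends at byte {len(data)}"
        )
    tris = np.empty((count, 3, 3), dtype=float)
    off = _BINARY_HEADER_BYTES + 4
    for i in range(count):
        vals = struct.unpack_from("<12f", data, off)  # normal + 3 vertices
        tris[i] = np.array(vals[3:], dtype=float).reshape(3, 3)
        off += _BINARY_FACET_BYTES
    return tris


def _parse_ascii(text: str) -> np.ndarray:
    verts: List[List[float]] = []
    for ln, line in enumerate(text.splitlines(), 1):
        parts = line.split()
        if parts[:1] == ["vertex"]:
            if len(parts) != 4:
                raise StlFormatError(f"malformed vertex on line {ln}: {line.strip()!r}")
            try:
                verts.append([float(x) for x in parts[1:]])
            except ValueError:
                raise StlFormatError(
                    f"non-numeric vertex on line {ln}: {line.strip()!r}"
                ) from None
    if not verts or len(verts) % 3 != 0:
        raise StlFormatError(
            f"ASCII STL has {len(verts)} vertex lines (need a positive multiple of 3)"
        )
    return np.array(verts, dtype=float).reshape(-1, 3, 3)


def read_stl(path: Union[str, Path]) -> StlSummary:
    """Parse an STL file (either dialect) and return its summary."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) == 0:
        raise StlFormatError(f"{path}: empty file")
    # ASCII dialect starts with 'solid' AND contains facet keywords; some
    # binary exporters also start with 'solid', hence the second check.
    head = data[:512]
    if head.lstrip().startswith(b"solid") and b"facet" in data:
        tris = _parse_ascii(data.decode("utf-8", errors="replace"))
        fmt = "ascii"
    else:
        tris = _parse_binary(data)
        fmt = "binary"
    return _summarize(tris, fmt)


def write_ascii_stl(path: Union[str, Path], triangles: np.ndarray, name: str = "mesh") -> None:
    """Write triangles (n, 3, 3) as an ASCII STL (unit normals recomputed)."""
    tris = np.asarray(triangles, dtype=float).reshape(-1, 3, 3)
    lines = [f"solid {name}"]
    for tri in tris:
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        norm = np.linalg.norm(n)
        n = n / norm if norm > 0 else n
        lines.append(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}")
        lines.append("    outer loop")
        for v in tri:
            lines.append(f"      vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append(f"endsolid {name}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_binary_stl(path: Union[str, Path], triangles: np.ndarray) -> None:
    """Write triangles (n, 3, 3) as a little-endian binary STL."""
    tris = np.asarray(triangles, dtype=float).reshape(-1, 3, 3)
    out = bytearray(b"tmmkit binary stl".ljust(_BINARY_HEADER_BYTES, b"\0"))
    out += struct.pack("<I", len(tris))
    for tri in tris:
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        norm = np.linalg.norm(n)
        n = n / norm if norm > 0 else n
        out += struct.pack("<12fH", *n, *tri.reshape(-1), 0)
    Path(path).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CavityEntry:
    name: str
    stl_path: str
    tissue: str
    stl_summary: StlSummary
    fit: FitResult
    recipe: Recipe


@dataclass(frozen=True)
class CavityManifest:
    phantom_name: str
    law: MixingLaw
    temperature: float
    grid: FrequencyGrid
    entries: tuple

    def to_dict(self) -> dict:
        return {
            "schema_version": MANIFEST_SCHEMA_VERSION,
            "phantom_name": self.phantom_name,
            "law": MixingLaw(self.law).value,
            "temperature_C": self.temperature,
            "frequency_band_Hz": [self.grid.f_min, self.grid.f_max],
            "n_frequency_points": self.grid.n_points,
            "cavities": [
                {
                    "name": e.name,
                    "stl_file": e.stl_path,
                    "stl_summary": e.stl_summary.to_dict(),
                    "tissue": e.tissue,
                    "composition": {
                        "v2_saline": e.fit.composition.v2_saline,
                        "nacl_g_per_L": e.fit.composition.nacl,
                        "tx100_vol_percent": e.fit.tx_vol_percent,
                    },
                    "fit": {
                        "converged": e.fit.converged,
                        "iterations": e.fit.iterations,
                        "final_cost": e.fit.final_cost,
                    },
                    "recipe": e.recipe.to_dict(),
                }
                for e in self.entries
            ],
        }

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")


def build_manifest(config: Union[dict, str, Path]) -> CavityManifest:
    """Build a phantom manifest from a config mapping (or JSON config file).

    Config keys: ``phantom_name``; ``law``; ``temperature_C``;
    ``frequency_band_Hz`` ([f_min, f_max]); ``n_frequency_points``;
    ``batch_volume_L``; ``cavities``: list of
    ``{"name", "stl_file", "tissue"}``.

    All cavities are validated (tissue resolved, STL parsed) before any
    optimization runs, so a bad entry never produces a partial result.
    One fit is run per distinct tissue and shared between cavities.
    """
    base_dir = Path(".")
    if not isinstance(config, dict):
        path = Path(config)
        base_dir = path.parent
        config = json.loads(path.read_text())

    cavities = config.get("cavities", [])
    if not cavities:
        raise ValidationError("config lists no cavities")
    names = [c["name"] for c in cavities]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate cavity names in config: {names}")

    law = MixingLaw(config.get("law", "kraszewski"))
    temperature = float(config.get("temperature_C", 25.0))
    band = config.get("frequency_band_Hz", [0.5e9, 3.0e9])
    grid = FrequencyGrid(
        f_min=float(band[0]),
        f_max=float(band[1]),
        n_points=int(config.get("n_frequency_points", 26)),
    )
    batch_volume = float(config.get("batch_volume_L", 1.0))

    # validate everything up front (atomicity: no partial manifest)
    available = list_tissues()
    summaries = {}
    for cav in cavities:
        if cav["tissue"] not in available:
            raise ValidationError(
                f"cavity {cav['name']!r}: unknown tissue {cav['tissue']!r}; "
                f"available: {', '.join(available)}"
            )
        stl_path = Path(cav["stl_file"])
        if not stl_path.is_absolute():
            stl_path = base_dir / stl_path
        if not stl_path.exists():
            raise ValidationError(
                f"cavity {cav['name']!r}: STL file not found: {stl_path}"
            )
        summaries[cav["name"]] = (str(cav["stl_file"]), read_stl(stl_path))

    fits: Dict[str, FitResult] = {}
    entries = []
    for cav in cavities:
        tissue = cav["tissue"]
        if tissue not in fits:
            problem = FitProblem.for_tissue(
                tissue, law=law, grid=grid, temperature=temperature
            )
            fits[tissue] = fit(problem)
            logger.info("manifest: fitted %s", tissue)
        result = fits[tissue]
        stl_path, summary = summaries[cav["name"]]
        entries.append(
            CavityEntry(
                name=cav["name"],
                stl_path=stl_path,
                tissue=tissue,
                stl_summary=summary,
                fit=result,
                recipe=build_recipe(result.composition, batch_volume),
            )
        )
    return CavityManifest(
        phantom_name=config.get("phantom_name", "phantom"),
        law=law,
        temperature=temperature,
        grid=grid,
        entries=tuple(entries),
    )
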