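"""Pocket proximity of cysteine thiols from structures and Fpocket output.

Fpocket describes candidate pockets as clusters of alpha spheres (probe
spheres touching three protein atoms; radii 3.0-5.0 A in the screening
configuration).  A cysteine is classed as pocket-proximal when its thiol
(SG) atom lies within a cutoff (default 1.5 A) of the closest alpha sphere.
Because "distance to a sphere" is ambiguous, both conventions are supported:
``center`` (Euclidean distance to the sphere center, default) and
``surface`` (center distance minus the sphere radius); the convention used
is recorded in the output.

Structures are read with gemmi (PDB or mmCIF); the Fpocket ``*_pockets.pqr``
alpha-sphere dialect is parsed directly.  Fpocket itself is never executed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .aggregate import SiteKey

__all__ = [
    "AlphaSphere",
    "ThiolAtom",
    "PocketCall",
    "extract_thiol_coords",
    "parse_alpha_spheres",
    "classify_pocket_proximity",
    "pocket_calls_frame",
]


@dataclass(frozen=True)
class AlphaSphere:
    center: tuple[float, float, float]
    radius: float
    pocket_id: int


@dataclass(frozen=True)
class ThiolAtom:
    site: SiteKey
    coords: tuple[float, float, float]
    chain: str
    source_model: str


@dataclass(frozen=True)
class PocketCall:
    site: SiteKey
    in_pocket: bool
    min_distance: float
    convention: str


def extract_thiol_coords(
    structure_file: str | Path, accession: str | None = None
) -> list[ThiolAtom]:
    """Gamma-sulfur coordinates of every cysteine in the first model.

    Residue numbering is taken from the file; ``accession`` defaults to the
    structure's own name.  CYS residues lacking an SG atom are skipped.
    """
    st = gemmi.read_structure(str(structure_file))
    if len(st) == 0:
        raise ValueError(f"{structure_file}: no models found")
    model = st[0]
    model_id = str(getattr(model, "num", getattr(model, "name", 1)))
    acc = accession or st.name or Path(structure_file).stem
    thiols: list[ThiolAtom] = []
    for chain in model:
        for residue in chain:
            if residue.name not in ("CYS", "CYX", "CYM"):
                continue
            sg = residue.find_atom("SG", "*")
            if sg is None:
                continue
            thiols.append(
                ThiolAtom(
                    site=SiteKey(acc, residue.seqid.num),
                    coords=(sg.pos.x, sg.pos.y, sg.pos.z),
                    chain=chain.name,
                    source_model=model_id,
                )
            )
    return thiols


def parse_alpha_spheres(pqr_path: str | Path) -> list[AlphaSphere]:
    """Parse an Fpocket ``*_pockets.pqr`` alpha-sphere file.

    Each ATOM/HETATM line carries the sphere center (x, y, z), a charge
    column and the sphere radius in the final column; the residue sequence
    number groups spheres into pockets.  Header, remark and terminator lines
    are ignored; malformed ATOM lines raise with their line number.  An empty
    file (a protein with no pockets) yields an empty list.
    """
    spheres: list[AlphaSphere] = []
    with open(pqr_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or not stripped.startswith(("ATOM", "HETATM")):
                continue
            tokens = stripped.split()
            if len(tokens) < 10:
                raise ValueError(
                    f"{pqr_path}, line {lineno}: truncated alpha-sphere record"
                )
            try:
                pocket_id = int(tokens[-6])
                x, y, z = (float(t) for t in tokens[-5:-2])
                radius = float(tokens[-1])
            except ValueError as exc:
                raise ValueError(
                    f"{pqr_path}, line {lineno}: unparseable field ({exc})"
                ) from exc
            spheres.append(AlphaSphere(center=(x, y, z), radius=radius,
                                       pocket_id=pocket_id))
    return spheres


def classify_pocket_proximity(
    thiols: Sequence[ThiolAtom],
    spheres: Sequence[AlphaSphere],
    cutoff: float = 1.5,
    convention: str = "center",
) -> list[PocketCall]:
    """Flag each thiol as in-pocket by its distance to the nearest sphere.

    ``center``: min Euclidean distance to sphere centers <= cutoff.
    ``surface``: min (center distance - radius) <= cutoff.
    The minimal distance under the chosen convention is always reported;
    with no spheres every call is negative with infinite distance.
    """
    if convention not in ("center", "surface"):
        raise ValueError(f"unknown distance convention {convention!r}")
    if not thiols:
        return []
    if not spheres:
        return [
            PocketCall(t.site, False, math.inf, convention) for t in thiols
        ]
    tcoords = np.array([t.coords for t in thiols], dtype=float)
    centers = np.array([s.center for s in spheres], dtype=float)
    dist = cdist(tcoords, centers)
    if convention == "surface":
        dist = dist - np.array([s.radius for s in spheres], dtype=float)
    dmin = dist.min(axis=1)
    return [
        PocketCall(t.site, bool(d <= cutoff), float(d), convention)
        for t, d in zip(thiols, dmin)
    ]


def pocket_calls_frame(calls: Sequence[PocketCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_accession": c.site.protein_accession,
                "residue_index": c.site.residue_index,
                "in_pocket": c.in_pocket,
                "min_distance": c.min_distance,
                "convention": c.convention,
            }
            for c in calls
        ],
        columns=[
            "protein_accession",
            "residue_index",
            "in_pocket",
            "min_distance",
            "convention",
        ],
    )
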