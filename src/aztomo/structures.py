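"""Atomic-model helpers for the tether-size screen.

The geometric screen asks whether a detected tether can accommodate the
membrane-to-membrane span of a candidate bridging protein, e.g. the Munc13
C1C2BMUN fragment (PDB 5ue8), whose rod-shaped MUN domain flanked by
lipid-binding domains sets a lower bound on the vesicle-to-plasma-membrane
distance it can bridge. ``fetch_munc13_model`` downloads the deposited
coordinates when network access exists; ``synthetic_munc13_like_model``
builds a labelled synthetic stand-in for exercising the span-measurement
machinery where the deposited file is unavailable.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

import numpy as np

__all__ = [
    "MUNC13_PDB_ID",
    "MUNC13_C2B_RANGE",
    "MUNC13_MUN_CTERM_RANGE",
    "fetch_munc13_model",
    "synthetic_munc13_like_model",
    "SYNTHETIC_C2B_RANGE",
    "SYNTHETIC_CTERM_RANGE",
]

MUNC13_PDB_ID = "5ue8"
# Default residue selections for the deposited Munc13-1 C1C2BMUN model
# (rat Munc13-1 numbering): the C2B domain and the C-terminal end of the MUN
# domain. Domain limits are configurable; these defaults follow the model's
# annotated domain boundaries.
MUNC13_C2B_RANGE = (678, 820)
MUNC13_MUN_CTERM_RANGE = (1725, 1735)

SYNTHETIC_C2B_RANGE = (1, 144)
SYNTHETIC_CTERM_RANGE = (795, 800)


def fetch_munc13_model(dest: Path | str, pdb_id: str = MUNC13_PDB_ID,
                       timeout: float = 60.0) -> Path:
    """Download the deposited mmCIF coordinates from the RCSB (needs network)."""
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - y ** 2)
    theta = phi * i
    return radius * np.column_stack([r * np.cos(theta), y, r * np.sin(theta)])


def synthetic_munc13_like_model():
    """SYNTHETIC stand-in for an elongated two-membrane-binding protein model.

    Not deposited coordinates: a CA-only AtomArray built programmatically,
    with a compact globular 'C2B-like' domain (residues 1-144, points on a
    1.2 nm sphere at the origin) joined by a straight 'MUN-like' rod along x
    (residues 200-800) whose final residues sit 14.6 nm from the origin. The
    exact minimal inter-region distance follows from the construction and is
    used to validate the span-measurement code, never as a stand-in for the
    deposited model's printed span.
    """
    import biotite.structure as struc

    dom = _fibonacci_sphere(144, 12.0)  # Angstrom
    rod_res = np.arange(200, 801)
    rod_x = np.linspace(20.0, 146.0, len(rod_res))
    rod = np.column_stack([rod_x, np.zeros_like(rod_x), np.zeros_like(rod_x)])
    coords = np.vstack([dom, rod]).astype(np.float32)
    res_ids = np.concatenate([np.arange(1, 145), rod_res])
    n = len(coords)
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = res_ids.astype(int)
    atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms
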