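"""Per-atom attention heatmaps on 2D molecule depictions.

Attention coefficients (deviations of each atom's attention score from the
molecular mean, summing to zero) are mapped onto a symmetric diverging
color scale centered at zero: the color midpoint is exactly coefficient 0
and the scale endpoints sit at ±max|c|.  The red/blue orientation is
property-specific — for lipophilicity, blue marks lipophilic-increasing
atoms and red anti-lipophilic ones; for solubility the convention flips
(red = soluble-increasing) — and is configurable.

A sidecar CSV of (atom index, element, coefficient) is written next to
every image so the raw numbers stay inspectable.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

#: property name -> True if positive coefficients are drawn red
RED_POSITIVE_DEFAULTS = {"lipophilicity": False, "solubility": True}


@dataclasses.dataclass
class HeatmapSpec:
    """What to draw: a molecule, its per-atom coefficients and the color convention."""

    smiles: str
    coefficients: np.ndarray
    property_name: str = "property"
    red_positive: bool | None = None      # None: look up property_name, default False
    fmt: str = "svg"                      # 'svg' or 'png'
    size: tuple = (420, 420)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(-1)
        if self.fmt not in ("svg", "png"):
            raise ValueError("fmt must be 'svg' or 'png'")


def atom_colors(coefficients: np.ndarray, red_positive: bool) -> list[tuple]:
    """RGB per atom on a symmetric diverging scale (midpoint = 0)."""
    c = np.asarray(coefficients, dtype=float)
    vmax = float(np.max(np.abs(c))) if np.any(c) else 1.0
    cmap = colormaps["bwr"]  # blue -> white -> red
    colors = []
    for v in c:
        t = 0.5 + v / (2 * vmax)
        if not red_positive:
            t = 1.0 - t
        r, g, b, _ = cmap(float(np.clip(t, 0.0, 1.0)))
        colors.append((r, g, b))
    return colors


def render_heatmap(spec: HeatmapSpec, path) -> Path:
    """Draw the molecule with attention-colored atoms; returns the image path.

    Also writes ``<path>.atoms.csv`` with (atom index, element, coefficient).
    """
    mol = Chem.MolFromSmiles(spec.smiles)
    if mol is None:
        raise ValueError(f"SMILES not parseable: {spec.smiles!r}")
    if not np.all(np.isfinite(spec.coefficients)):
        raise ValueError("coefficients must be finite")
    if len(spec.coefficients) != mol.GetNumAtoms():
        raise ValueError(
            f"{len(spec.coefficients)} coefficients for {mol.GetNumAtoms()} heavy atoms")
    red_positive = spec.red_positive
    if red_positive is None:
        red_positive = RED_POSITIVE_DEFAULTS.get(spec.property_name.lower(), False)
    colors = atom_colors(spec.coefficients, red_positive)
    highlight = {i: c for i, c in enumerate(colors)}
    if spec.fmt == "png":
        drawer = rdMolDraw2D.MolDraw2DCairo(*spec.size)
    else:
        drawer = rdMolDraw2D.MolDraw2DSVG(*spec.size)
    pos, neg = ("raises", "lowers") if red_positive else ("lowers", "raises")
    legend = f"{spec.property_name}: red {pos}, blue {neg}"
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol, legend=legend,
        highlightAtoms=list(highlight), highlightAtomColors=highlight)
    drawer.FinishDrawing()
    path = Path(path)
    if spec.fmt == "png":
        path.write_bytes(drawer.GetDrawingText())
    else:
        text = drawer.GetDrawingText()
        # legend glyphs are drawn as paths; keep the statement machine-readable
        text = text.replace("</svg>", f"<!-- {legend} -->\n</svg>")
        path.write_text(text)
    _write_sidecar(mol, spec.coefficients, path.with_suffix(path.suffix + ".atoms.csv"))
    return path


def _write_sidecar(mol: Chem.Mol, coefficients: np.ndarray, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["atom_index", "element", "coefficient"])
        for atom in mol.GetAtoms():
            w.writerow([atom.GetIdx(), atom.GetSymbol(),
                        f"{coefficients[atom.GetIdx()]:.6g}"])


def export_coefficients(smiles: str, coefficients: np.ndarray, path) -> None:
    """Standalone coefficient CSV export (atom index, element, coefficient)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES not parseable: {smiles!r}")
    _write_sidecar(mol, np.asarray(coefficients, dtype=float), Path(path))
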