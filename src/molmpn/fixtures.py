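"""Deterministic synthetic molecules and properties for end-to-end testing.

Real lipophilicity/solubility tables must be downloaded; every stage of
this package is instead exercisable on molecules assembled from a small
fragment grammar (alkyl chains with optional branches, aromatic and
saturated rings, and common terminal groups: hydroxyl, amine, halides,
carbonyls, nitrile...).  All generated SMILES parse; duplicates are
allowed on purpose so the cleaning step has something to do; every
molecule stays small (<= ~25 heavy atoms).

Synthetic target properties:

- ``atom_count_linear`` (default): y = sum_e c_e * (#atoms of element e)
  plus Gaussian noise.  Linear in elemental composition, hence learnable
  by a depth>=1 message passing model, and exactly recoverable by linear
  regression on element counts when the noise is zero.
- ``heavy_atom_count``: total heavy atoms plus noise.
- ``ring_fraction``: fraction of heavy atoms in rings plus noise — used as
  the second property of the two-target dataset.

Molecule structure and noise come from independently seeded streams so the
same molecules can be re-labelled under different noise draws.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .chemgraph import DatasetRecord
from .encoder import param_rng

DEFAULT_COEFFICIENTS: dict[str, float] = {
    "C": 0.5, "O": 0.8, "N": -0.4, "F": -0.6, "Cl": 0.9, "S": 0.2,
}

_PREFIXES = ("", "O", "N", "Cl", "F")
_RINGS = ("", "c1ccccc1", "c1ccncc1", "C1CCCCC1", "c1ccoc1", "c1ccsc1")
_SUFFIXES = ("", "O", "N", "Cl", "F", "C(=O)C", "C(=O)O", "C#N", "OC", "NC")


@dataclasses.dataclass
class FixtureConfig:
    """Settings of the synthetic dataset generator."""

    n: int = 100
    seed: int = 0
    property_kind: str = "atom_count_linear"
    noise_sd: float = 0.1
    coefficients: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.property_kind not in ("atom_count_linear", "heavy_atom_count", "ring_fraction"):
            raise ValueError(f"unknown property kind {self.property_kind!r}")


def _one_smiles(rng: np.random.Generator) -> str:
    """Assemble one SMILES from the fragment grammar (always parseable)."""
    prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
    a = int(rng.integers(1, 7))             # main chain length 1..6
    branch = "(C)" if rng.random() < 0.3 else ""
    b = int(rng.integers(0, 4))             # chain continuation 0..3
    ring = _RINGS[rng.integers(len(_RINGS))]
    suffix = _SUFFIXES[rng.integers(len(_SUFFIXES))]
    if rng.random() < 0.5:
        body = "C" * a + branch + "C" * b + ring
    else:
        body = ring + "C" * a + branch + "C" * b
    return prefix + body + suffix


def generate_molecules(config: FixtureConfig) -> list[str]:
    """Deterministic list of ``config.n`` valid SMILES (duplicates allowed)."""
    rng = param_rng(config.seed, "fixtures.molecules")
    return [_one_smiles(rng) for _ in range(config.n)]


def _property_value(mol: Chem.Mol, kind: str, coefficients: Mapping[str, float]) -> float:
    if kind == "atom_count_linear":
        return float(sum(coefficients.get(a.GetSymbol(), 0.0) for a in mol.GetAtoms()))
    if kind == "heavy_atom_count":
        return float(mol.GetNumAtoms())
    if kind == "ring_fraction":
        return float(sum(a.IsInRing() for a in mol.GetAtoms())) / mol.GetNumAtoms()
    raise ValueError(kind)


def synthetic_property(smiles: str, config: FixtureConfig,
                       noise: float | None = None) -> float:
    """Noise-free structural property plus an optional pre-drawn noise term."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES not parseable: {smiles!r}")
    y = _property_value(mol, config.property_kind, config.coefficients)
    return y + (noise if noise is not None else 0.0)


def make_records(config: FixtureConfig, second_property: str | None = None,
                 missing_fraction: float = 0.3) -> list[DatasetRecord]:
    """Generate labelled records; optionally a partially missing second property.

    With *second_property* set, each row's second target is unobserved with
    probability *missing_fraction* (and a random ~10% of rows lose the
    first target instead, so neither column fully covers the data).
    """
    smiles = generate_molecules(config)
    noise_rng = param_rng(config.seed, "fixtures.noise")
    miss_rng = param_rng(config.seed, "fixtures.missing")
    records = []
    for s in smiles:
        eps = float(noise_rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        y1 = synthetic_property(s, config, eps)
        if second_property is None:
            records.append(DatasetRecord(s, [y1], [True]))
            continue
        cfg2 = dataclasses.replace(config, property_kind=second_property)
        eps2 = float(noise_rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        y2 = synthetic_property(s, cfg2, eps2)
        u = miss_rng.random()
        mask = [True, True]
        if u < missing_fraction:
            mask[1] = False
        elif u > 0.9:
            mask[0] = False
        records.append(DatasetRecord(s, [y1, y2], mask))
    return records


def make_dataset(config: FixtureConfig, path, second_property: str | None = None,
                 missing_fraction: float = 0.3) -> list[DatasetRecord]:
    """Write a fixture dataset CSV (byte-identical across runs for one config)."""
    records = make_records(config, second_property, missing_fraction)
    columns = [config.property_kind] + ([second_property] if second_property else [])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(["smiles", *columns]) + "\n")
        for r in records:
            cells = [r.smiles]
            for k in range(len(columns)):
                cells.append(f"{r.targets[k]:.6f}" if r.mask[k] else "")
            fh.write(",".join(cells) + "\n")
    return records
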