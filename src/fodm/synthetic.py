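"""Synthetic effective-atom clouds with known hydrophobic-core behaviour.

The generator produces point clouds shaped roughly like protein
effective-atom sets together with per-residue intrinsic
hydrophobicities arranged to a prescribed regime:

  core_sorted — the most hydrophobic residues sit closest to the centre
                (by descending theoretical-profile rank): an ideal
                micelle, expected RD < 0.5 and a small optimal K;
  inverted    — hydrophobicity exposed at the surface, polar residues
                buried: the membrane-like inversion, expected RD > 0.5;
  shuffled    — hydrophobicities permuted at random: no designed core;
  k_target    — the observed profile is manufactured outright as
                M(K = k_target), optionally blurred with Dirichlet
                noise, so the K scan has a known ground-truth optimum.

Geometry is statistical only (no sterics, no backbone chemistry); the
point of the module is controlled truth for testing the statistics, not
realistic protein models.  The same seed always yields bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import KGrid, FodResult, analyze_profiles, analyze_unit, m_profile
from .hydro_field import (
    GaussianField,
    HydroProfile,
    HydroScale,
    default_scale,
    fit_gaussian,
    theoretical_profile,
)
from .structure_io import EffectiveAtomSet, ResidueId, write_effective_pdb

__all__ = [
    "SyntheticSpec",
    "SyntheticUnit",
    "generate",
    "write_as_pdb",
    "analyze_synthetic",
    "GEOMETRIES",
    "ASSIGNMENTS",
]

GEOMETRIES = ("gaussian_cloud", "helix_like_curve")
ASSIGNMENTS = ("core_sorted", "inverted", "shuffled", "k_target")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic structural unit.

    ``noise`` is a Dirichlet concentration for the k_target regime
    (larger = less noise; 0/None = exact construction) and a coordinate
    jitter sigma in Å for the geometric regimes.
    """

    n: int = 60
    geometry: str = "gaussian_cloud"
    assignment: str = "core_sorted"
    k_target: Optional[float] = None
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("need n >= 4 residues")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.assignment not in ASSIGNMENTS:
            raise ValueError(f"unknown assignment {self.assignment!r}")
        if self.assignment == "k_target" and self.k_target is None:
            raise ValueError("k_target assignment needs a k_target value")


@dataclass
class SyntheticUnit:
    atoms: EffectiveAtomSet
    hydrophobicity: np.ndarray            # exact assigned H^r per residue
    field: GaussianField
    observed: Optional[HydroProfile]      # only for the k_target regime
    truth: dict = field(default_factory=dict)


def _positions(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.geometry == "gaussian_cloud":
        # anisotropic globule; scale tracks the R ~ n^(1/3) packing law
        s0 = 1.8 * spec.n ** (1.0 / 3.0)
        sigmas = s0 * np.array([1.2, 1.0, 0.85])
        pts = rng.normal(size=(spec.n, 3)) * sigmas
    else:  # helix_like_curve: ideal alpha-helix axis geometry
        i = np.arange(spec.n)
        theta = np.deg2rad(100.0) * i
        pts = np.column_stack([
            2.3 * np.cos(theta),
            2.3 * np.sin(theta),
            1.5 * i,
        ])
        pts -= pts.mean(axis=0)
    if spec.assignment != "k_target" and spec.noise > 0:
        pts = pts + rng.normal(scale=spec.noise, size=pts.shape)
    return pts


def _nearest_resnames(h: np.ndarray, scale: HydroScale) -> list[str]:
    names = sorted(scale.values)  # deterministic tie order
    vals = np.array([scale.values[nm] for nm in names])
    return [names[int(np.argmin(np.abs(vals - x)))] for x in h]


def generate(spec: SyntheticSpec,
             scale: Optional[HydroScale] = None) -> SyntheticUnit:
    """Build a synthetic unit with ground-truth regime annotation.

    Hydrophobicity values are drawn from the scale's 20 intrinsic values
    (with replacement) and then arranged according to the regime; the
    exact values are returned alongside the nearest-residue-name
    encoding used when the unit is written to PDB.
    """
    if scale is None:
        scale = default_scale()
    rng = np.random.default_rng(spec.seed)
    pts = _positions(spec, rng)
    rids = [ResidueId("A", i + 1) for i in range(spec.n)]

    h = rng.choice(np.array(sorted(scale.values.values())), size=spec.n)
    atoms = EffectiveAtomSet(rids, pts, _nearest_resnames(h, scale))
    fld = fit_gaussian(atoms)
    T = theoretical_profile(fld, atoms)
    t_rank = np.argsort(-T.values)  # residue indices, most central first

    observed = None
    truth: dict = {
        "regime": spec.assignment,
        "geometry": spec.geometry,
        "n": spec.n,
        "seed": spec.seed,
        "noise": spec.noise,
    }
    if spec.assignment == "core_sorted":
        h_sorted = np.sort(h)[::-1]
        h_out = np.empty(spec.n)
        h_out[t_rank] = h_sorted  # highest H at highest T
    elif spec.assignment == "inverted":
        h_sorted = np.sort(h)
        h_out = np.empty(spec.n)
        h_out[t_rank] = h_sorted  # lowest H at highest T
    elif spec.assignment == "shuffled":
        h_out = rng.permutation(h)
    else:  # k_target: O is manufactured, H is irrelevant to the truth
        h_out = h
        M = m_profile(T, spec.k_target)
        if spec.noise > 0:
            vals = rng.dirichlet(spec.noise * M.values)
            vals = np.maximum(vals, 1e-12)
            observed = HydroProfile("O", vals / vals.sum(), list(rids))
        else:
            observed = HydroProfile("O", M.values.copy(), list(rids))
        truth["k_target"] = spec.k_target

    atoms = EffectiveAtomSet(rids, pts, _nearest_resnames(h_out, scale))
    return SyntheticUnit(atoms=atoms, hydrophobicity=h_out, field=fld,
                         observed=observed, truth=truth)


def analyze_synthetic(unit: SyntheticUnit, grid: KGrid = KGrid()) -> FodResult:
    """Run the full FOD-M readout on a synthetic unit.

    Geometric regimes go through the standard pipeline (T from the
    fitted field, O from Levitt interactions using the exact assigned
    hydrophobicities); the k_target regime uses its manufactured O.
    """
    label = unit.truth.get("regime", "synthetic")
    if unit.observed is not None:
        T = theoretical_profile(unit.field, unit.atoms)
        result, _ = analyze_profiles(unit.observed, T, grid, unit_label=label)
        return result
    result, _, _ = analyze_unit(
        unit.atoms, unit.field, hydrophobicity=unit.hydrophobicity,
        grid=grid, unit_label=label,
    )
    return result


def write_as_pdb(unit: SyntheticUnit, path: str | Path,
                 sidecar: bool = True) -> None:
    """Write the unit as a CA-only PDB plus sidecar truth files.

    The PDB encodes hydrophobicity through residue names (nearest scale
    value), which quantises it; the sidecar CSV carries the exact
    assigned values and the JSON the ground-truth regime record.
    """
    path = Path(path)
    write_effective_pdb(unit.atoms, path)
    if sidecar:
        csv_path = path.with_suffix(".hydro.csv")
        lines = ["residue_id,resname,hydrophobicity"]
        for rid, nm, h in zip(unit.atoms.residue_ids,
                              unit.atoms.residue_names,
                              unit.hydrophobicity):
            lines.append(f"{rid},{nm},{h:.10g}")
        csv_path.write_text("\n".join(lines) + "\n")
        path.with_suffix(".truth.json").write_text(
            json.dumps(unit.truth, indent=2) + "\n"
        )
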