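"""The 3D Gaussian hydrophobicity field and the T / O / R profiles.

The fuzzy-oil-drop picture treats a folded, water-soluble protein as a
spherical micelle: hydrophobicity should peak at the centre of the
molecule and decay towards the surface.  That ideal is encoded as a
3D Gaussian fitted to the structural unit's effective-atom cloud, which
yields the *theoretical* profile T.  What the structure actually does is
summarised by the *observed* profile O, which accumulates pairwise
hydrophobic interactions between residues (Levitt's distance-dependent
contact function with a 9 Å cutoff) weighted by intrinsic residue
hydrophobicities.  The *uniform* profile R (1/N everywhere) is the
no-core reference.  All three are normalised to sum to one, so they are
discrete probability distributions over the residues and can be compared
by Kullback-Leibler divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import EffectiveAtomSet

__all__ = [
    "HydroScale",
    "GaussianField",
    "HydroProfile",
    "KYTE_DOOLITTLE",
    "default_scale",
    "load_scale",
    "fit_gaussian",
    "theoretical_profile",
    "observed_profile",
    "uniform_profile",
    "levitt_weight",
    "DegenerateFieldError",
    "DegenerateProfileError",
]

log = logging.getLogger(__name__)

STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

# Kyte & Doolittle residue hydropathies (raw, before normalisation).
_KD_RAW = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


class DegenerateFieldError(ValueError):
    """Point cloud too degenerate (collinear/coincident) to fit a field."""


class DegenerateProfileError(ValueError):
    """All interaction terms vanished; the observed profile is undefined."""


@dataclass(frozen=True)
class HydroScale:
    """An intrinsic per-residue hydrophobicity scale on [0, 1].

    ``values`` maps three-letter residue names to dimensionless intrinsic
    hydrophobicities H^r.  The scale must cover the 20 standard residues
    and stay within [0, 1]; observed profiles are normalisation-invariant
    under positive rescaling of H^r, so only the relative ordering and
    spacing matter.
    """

    name: str
    values: dict[str, float]

    def __post_init__(self):
        missing = [r for r in STANDARD_RESIDUES if r not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {missing}")
        bad = {r: v for r, v in self.values.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"scale {self.name!r} values outside [0,1]: {bad}")

    def __getitem__(self, resname: str) -> float:
        try:
            return self.values[resname]
        except KeyError:
            raise KeyError(
                f"residue {resname!r} not in hydrophobicity scale "
                f"{self.name!r}"
            ) from None


def _normalized(raw: dict[str, float], name: str) -> HydroScale:
    lo, hi = min(raw.values()), max(raw.values())
    return HydroScale(name, {r: (v - lo) / (hi - lo) for r, v in raw.items()})


KYTE_DOOLITTLE = _normalized(_KD_RAW, "kyte-doolittle")


def default_scale() -> HydroScale:
    """The built-in scale: Kyte-Doolittle, min-max normalised to [0, 1]."""
    return KYTE_DOOLITTLE


def load_scale(path: str | Path, name: Optional[str] = None) -> HydroScale:
    """Load a scale from a two-column text file.

    Format: whitespace-separated ``RESNAME value`` rows, ``#`` comments.
    Values outside [0, 1] are min-max normalised with a warning.
    """
    path = Path(path)
    raw: dict[str, float] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'RESNAME value'")
        raw[parts[0].upper()] = float(parts[1])
    vals = list(raw.values())
    if vals and (min(vals) < 0.0 or max(vals) > 1.0):
        log.warning("scale %s not in [0,1]; applying min-max normalisation",
                    path)
        return _normalized(raw, name or path.stem)
    return HydroScale(name or path.stem, raw)


@dataclass
class GaussianField:
    """Fitted 3D Gaussian: centre, principal-axis rotation and sigmas.

    ``rotation`` columns are the principal axes of the centred cloud
    (descending variance); ``sigmas`` follow the three-sigma convention:
    after rotating into the principal frame, sigma_j = max_i |coord_ij|/3,
    so the whole molecule lies inside the +-3 sigma box.
    """

    center: np.ndarray    # (3,) Å
    rotation: np.ndarray  # (3, 3), columns = principal axes
    sigmas: np.ndarray    # (3,) Å

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates into the centred principal-axis frame."""
        return (np.asarray(points, dtype=float) - self.center) @ self.rotation

    def density(self, points: np.ndarray) -> np.ndarray:
        """Unnormalised Gaussian value at each point."""
        local = self.to_local(points)
        z2 = (local / self.sigmas) ** 2
        return np.exp(-0.5 * z2.sum(axis=1))


def fit_gaussian(atoms: EffectiveAtomSet, margin: float = 0.0) -> GaussianField:
    """Fit the unit's 3D Gaussian field to its effective-atom cloud.

    centre = mean position; axes = principal components (eigenvectors of
    the covariance, descending variance, each axis's sign fixed so its
    largest-magnitude loading is positive); sigma_j = (max |coord_j| +
    ``margin``)/3 in the rotated frame.  ``margin`` (Å) optionally pads
    the Gaussian's support beyond the molecular envelope.

    Raises :class:`DegenerateFieldError` for clouds with fewer than three
    points or with (near-)zero extent along any principal axis.
    """
    pts = np.asarray(atoms.positions, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateFieldError("need at least 3 effective atoms")
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]  # descending variance
    axes = evecs[:, order]
    for j in range(3):  # deterministic axis orientation
        col = axes[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            axes[:, j] = -col
    local = centered @ axes
    extent = np.abs(local).max(axis=0)
    if np.any(extent + margin < 1e-8):
        raise DegenerateFieldError(
            f"degenerate cloud: extent {extent} along principal axes"
        )
    sigmas = (extent + margin) / 3.0
    return GaussianField(center=center, rotation=axes, sigmas=sigmas)


def _as_profile(raw: np.ndarray, role: str, atoms: EffectiveAtomSet
                ) -> "HydroProfile":
    return HydroProfile(role=role, values=raw / raw.sum(),
                        residue_ids=list(atoms.residue_ids))


@dataclass
class HydroProfile:
    """A normalised per-residue hydrophobicity distribution.

    ``role`` records which distribution this is: ``"T"`` (theoretical,
    Gaussian), ``"O"`` (observed, Levitt contacts), ``"R"`` (uniform) or
    ``"M"`` (environment-modified).  Values are nonnegative and sum to 1.
    """

    role: str
    values: np.ndarray
    residue_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError(f"{self.role} profile has negative entries")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.role} profile sums to {self.values.sum()!r}, not 1"
            )
        if len(self.residue_ids) != len(self.values):
            raise ValueError("residue ids and values misaligned")

    @property
    def n(self) -> int:
        return len(self.values)


def theoretical_profile(field: GaussianField,
                        atoms: EffectiveAtomSet) -> HydroProfile:
    """T profile: the Gaussian evaluated at every effective atom, normalised.

    T_i = exp(-(x_i-x̄)²/2σx²) · exp(-(y_i-ȳ)²/2σy²) · exp(-(z_i-z̄)²/2σz²)
    in the principal-axis frame, divided by the sum over residues.
    """
    raw = field.density(atoms.positions)
    return _as_profile(raw, "T", atoms)


def levitt_weight(r: np.ndarray, cutoff: float = 9.0) -> np.ndarray:
    """Levitt's pairwise hydrophobic contact function.

    w(r) = 1 - 1/2 (7(r/c)² - 9(r/c)⁴ + 5(r/c)⁶ - (r/c)⁹) for r <= c,
    0 beyond the cutoff c.  w(0) = 1 and w(c) = 0 exactly.
    """
    r = np.asarray(r, dtype=float)
    t = r / cutoff
    poly = 7 * t**2 - 9 * t**4 + 5 * t**6 - t**9
    return np.where(r <= cutoff, 1.0 - 0.5 * poly, 0.0)


def residue_hydrophobicities(atoms: EffectiveAtomSet,
                             scale: HydroScale) -> np.ndarray:
    """Intrinsic H^r per residue, looked up by residue name."""
    return np.array([scale[name] for name in atoms.residue_names])


def observed_hydrophobicity_raw(
    atoms: EffectiveAtomSet,
    scale: Optional[HydroScale] = None,
    hydrophobicity: Optional[np.ndarray] = None,
    cutoff: float = 9.0,
    floor: float = 1e-12,
) -> np.ndarray:
    """Unnormalised observed hydrophobicity collected per residue.

    O_i^raw = sum over j != i of (H_i^r + H_j^r) · w(r_ij).  Intrinsic
    hydrophobicities come either from ``scale`` (via residue names) or an
    explicit per-residue ``hydrophobicity`` array.  A small ``floor`` is
    applied so no entry is exactly zero (the KL divergence downstream
    needs strictly positive reference entries); triggering it is logged.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if hydrophobicity is not None:
        h = np.asarray(hydrophobicity, dtype=float)
        if h.shape != (atoms.n,):
            raise ValueError("hydrophobicity array misaligned with residues")
    elif scale is not None:
        h = residue_hydrophobicities(atoms, scale)
    else:
        raise ValueError("provide a scale or an explicit hydrophobicity array")

    w = squareform(levitt_weight(pdist(atoms.positions), cutoff))
    pair_h = h[:, None] + h[None, :]
    raw = (pair_h * w).sum(axis=1)  # diagonal of w is 0: j == i excluded
    if raw.sum() <= 0:
        raise DegenerateProfileError(
            "all pairwise hydrophobic interactions are zero"
        )
    n_floored = int(np.sum(raw < floor))
    if n_floored:
        log.warning("observed profile: %d residue(s) below the %g floor",
                    n_floored, floor)
    return np.maximum(raw, floor)


def observed_profile(
    atoms: EffectiveAtomSet,
    scale: Optional[HydroScale] = None,
    hydrophobicity: Optional[np.ndarray] = None,
    cutoff: float = 9.0,
    floor: float = 1e-12,
) -> HydroProfile:
    """O profile: summed Levitt pairwise interactions, normalised to 1."""
    raw = observed_hydrophobicity_raw(atoms, scale, hydrophobicity,
                                      cutoff, floor)
    return _as_profile(raw, "O", atoms)


def uniform_profile(n: int, residue_ids: Optional[list] = None) -> HydroProfile:
    """R profile: 1/n for every residue — the no-core reference."""
    if n < 1:
        raise ValueError("need at least one residue")
    if residue_ids is None:
        residue_ids = list(range(n))
    return HydroProfile("R", np.full(n, 1.0 / n), list(residue_ids))
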