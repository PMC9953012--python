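"""Solvent-accessible surface area and derived packing / solvation metrics.

The SASA engine is a deterministic Shrake-Rupley implementation: each heavy
atom's probe-expanded sphere is sampled on a fixed golden-spiral lattice
(default 960 points) and points occluded by neighbouring expanded spheres are
removed. Downstream metrics:

* relative solvent accessibility RSA_i = s_i / A_i against reference areas
  A_i, with residues exposed iff RSA > 0.2 (strict);
* packing ratio = (sum_i A_i - sum_i s_i) / sum_i s_i, i.e. buried reference
  area per unit of exposed area;
* dynamic solvation index D_i = (max_t s_it - min_t s_it) / A_i over a
  trajectory;
* trajectory packing-ratio means with parametric-bootstrap confidence
  intervals under an AR(1) model of the per-frame ratio series.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .resources import reference_areas, vdw_radii
from .structures import Structure, Trajectory, write_structure

DEFAULT_PROBE = 1.4  # A
DEFAULT_N_POINTS = 960


@dataclass
class SasaSeries:
    """Per-residue, per-frame SASA values (n_residues x n_frames, A^2)."""

    residue_index: np.ndarray
    residue_names: np.ndarray
    values: np.ndarray
    probe_radius: float = DEFAULT_PROBE
    method: str = "shrake-rupley"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("SASA values must be finite and >= 0")


@dataclass
class PackingResult:
    ratio: float
    buried_area: float
    total_sasa: float
    series: Optional[np.ndarray] = None
    mean: Optional[float] = None
    ci: Optional[tuple[float, float]] = None


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def atom_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[np.ndarray, Structure]:
    """Shrake-Rupley per-atom SASA over heavy atoms.

    Returns (areas for each heavy atom, the heavy-atom substructure).
    """
    heavy = structure.heavy()
    radii_table = vdw_radii()
    unknown = sorted({e for e in heavy.element if e not in radii_table})
    if unknown:
        raise ValueError(f"unknown element(s) for SASA: {unknown}")
    radii = np.array([radii_table[e] for e in heavy.element]) + probe
    coords = heavy.coords
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.empty(len(heavy))
    for i in range(len(heavy)):
        sphere = coords[i] + radii[i] * pts
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((sphere - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / n_points
    return areas, heavy


def sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-residue SASA (A^2), ordered by residue index."""
    areas, heavy = atom_sasa(structure, probe, n_points)
    res_ids = np.unique(structure.residue_index)
    out = np.zeros(len(res_ids))
    for k, r in enumerate(res_ids):
        out[k] = areas[heavy.residue_index == r].sum()
    return out


def relative_sasa(
    per_residue_sasa: np.ndarray,
    residue_names: np.ndarray,
    ref: dict[str, float] | None = None,
) -> np.ndarray:
    ref = ref or reference_areas()
    missing = sorted({str(r) for r in residue_names if str(r) not in ref})
    if missing:
        raise KeyError(f"no reference area for residue(s): {missing}")
    A = np.array([ref[str(r)] for r in residue_names])
    return np.asarray(per_residue_sasa, dtype=float) / A


def classify_exposure(rsa: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """'exposed' iff RSA > threshold (strictly greater), else 'buried'."""
    return np.where(np.asarray(rsa) > threshold, "exposed", "buried")


def packing_ratio(
    per_residue_sasa: np.ndarray,
    residue_names: np.ndarray,
    ref: dict[str, float] | None = None,
) -> PackingResult:
    ref = ref or reference_areas()
    missing = sorted({str(r) for r in residue_names if str(r) not in ref})
    if missing:
        raise KeyError(f"no reference area for residue(s): {missing}")
    total_sasa = float(np.sum(per_residue_sasa))
    if total_sasa == 0:
        raise ValueError("total SASA is zero; packing ratio undefined")
    total_ref = float(sum(ref[str(r)] for r in residue_names))
    buried = total_ref - total_sasa
    if buried < 0:
        warnings.warn("negative buried area: SASA exceeds reference total")
    return PackingResult(ratio=buried / total_sasa, buried_area=buried, total_sasa=total_sasa)


def sasa_series(
    traj: Trajectory,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaSeries:
    """Per-residue SASA for every trajectory frame."""
    res_ids = np.unique(traj.topology.residue_index)
    values = np.empty((len(res_ids), traj.n_frames))
    for t in range(traj.n_frames):
        values[:, t] = sasa(traj.frame(t), probe, n_points)
    return SasaSeries(
        residue_index=res_ids,
        residue_names=traj.topology.residue_names,
        values=values,
        probe_radius=probe,
    )


def dynamic_solvation(series: SasaSeries, ref: dict[str, float] | None = None) -> np.ndarray:
    """D_i = (max_t s_it - min_t s_it) / A_i per residue."""
    ref = ref or reference_areas()
    missing = sorted({str(r) for r in series.residue_names if str(r) not in ref})
    if missing:
        raise KeyError(f"no reference area for residue(s): {missing}")
    A = np.array([ref[str(r)] for r in series.residue_names])
    return (series.values.max(axis=1) - series.values.min(axis=1)) / A


def ar1_bootstrap_ci(
    series: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Parametric bootstrap CI for the mean of an autocorrelated series.

    An AR(1) model is fit to the series (lag-1 autocorrelation, innovation
    variance); replicate series are simulated and the percentile interval of
    replicate means is returned.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 observations for a bootstrap CI")
    mu = x.mean()
    xc = x - mu
    denom = np.sum(xc[:-1] ** 2)
    phi = float(np.sum(xc[:-1] * xc[1:]) / denom) if denom > 0 else 0.0
    phi = np.clip(phi, -0.999, 0.999)
    resid = xc[1:] - phi * xc[:-1]
    sd_innov = float(resid.std(ddof=1)) if len(resid) > 1 else 0.0
    rng = np.random.default_rng(seed)
    if sd_innov == 0.0:
        return (mu, mu)
    # stationary AR(1) simulation, vectorized over replicates
    sd_marginal = sd_innov / np.sqrt(1 - phi**2)
    sims = np.empty((n_boot, n))
    sims[:, 0] = rng.normal(0.0, sd_marginal, size=n_boot)
    innov = rng.normal(0.0, sd_innov, size=(n_boot, n - 1))
    for t in range(1, n):
        sims[:, t] = phi * sims[:, t - 1] + innov[:, t - 1]
    means = mu + sims.mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return (float(lo), float(hi))


def trajectory_packing(
    traj: Trajectory,
    ref: dict[str, float] | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    n_boot: int = 1000,
    seed: int = 0,
) -> PackingResult:
    """Per-frame packing ratios with an autocorrelation-aware mean and 95% CI."""
    ref = ref or reference_areas()
    names = traj.topology.residue_names
    ratios = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        ratios[t] = packing_ratio(sasa(traj.frame(t), probe, n_points), names, ref).ratio
    mean = float(ratios.mean())
    if traj.n_frames >= 2:
        ci = ar1_bootstrap_ci(ratios, n_boot=n_boot, seed=seed)
    else:
        warnings.warn("single-frame trajectory: CI undefined")
        ci = None
    last = packing_ratio(sasa(traj.frame(traj.n_frames - 1), probe, n_points), names, ref)
    return PackingResult(
        ratio=mean,
        buried_area=last.buried_area,
        total_sasa=last.total_sasa,
        series=ratios,
        mean=mean,
        ci=ci,
    )


def surface_burial_composition(
    residue_names: np.ndarray, labels: np.ndarray
) -> tuple[Optional[dict[str, float]], Optional[dict[str, float]]]:
    """Amino-acid fractions among exposed and among buried residues.

    Returns (exposed_fractions, buried_fractions); an empty stratum yields
    None for that distribution.
    """
    from .sequences import CANONICAL_AA

    three_to_one = {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
        "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
        "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
        "TYR": "Y", "VAL": "V",
    }

    def stratum(mask: np.ndarray) -> Optional[dict[str, float]]:
        total = int(mask.sum())
        if total == 0:
            return None
        out = {aa: 0.0 for aa in CANONICAL_AA}
        for rname in residue_names[mask]:
            aa = three_to_one.get(str(rname))
            if aa:
                out[aa] += 1
        return {aa: c / total for aa, c in out.items()}

    labels = np.asarray(labels)
    return stratum(labels == "exposed"), stratum(labels == "buried")


def secondary_structure(structure: Structure) -> tuple[np.ndarray, dict[str, float]]:
    """3-state secondary structure (H/E/C) per residue plus proportions.

    Assignment is the Kabsch-Sander (DSSP) classification collapsed to three
    states (H,G,I -> H; E,B -> E; else C). Residues the assignment cannot
    cover (e.g. missing backbone) are labeled C with a warning.
    """
    import mdtraj as md

    n_res = structure.n_residues
    labels = np.full(n_res, "C", dtype="U1")
    backbone_ok = True
    for r in np.unique(structure.residue_index):
        names = set(structure.name[structure.residue_index == r])
        if not {"N", "CA", "C", "O"} <= names:
            backbone_ok = False
    if not backbone_ok:
        warnings.warn("missing backbone atoms; affected residues labeled C")
    try:
        with tempfile.TemporaryDirectory() as tmp:
            path = os.path.join(tmp, "ss.pdb")
            write_structure(structure, path)
            t = md.load(path)
            dssp = md.compute_dssp(t, simplified=True)[0]
        for i, code in enumerate(dssp[:n_res]):
            labels[i] = code if code in ("H", "E") else "C"
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"secondary structure assignment failed ({exc}); labeling C")
    proportions = {s: float(np.mean(labels == s)) for s in ("H", "E", "C")}
    return labels, proportions


def write_dynamic_solvation_pdb(
    structure: Structure, d_values: np.ndarray, path: str
) -> None:
    """Export the structure with per-residue D_i painted into the B-factor column."""
    per_atom = np.array([d_values[r] for r in structure.residue_index], dtype=float)
    write_structure(structure, path, bfactors=per_atom)
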