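"""Census of salt bridges, disulfide bonds, and hydrogen bonds per structure.

Salt bridges: any side-chain carboxylate oxygen (Asp OD1/OD2, Glu OE1/OE2)
within the cutoff (default 3.2 A) of a basic side-chain nitrogen (Lys NZ,
Arg NH1/NH2/NE; His ND1/NE2 only when His is treated as charged). One count
per residue pair regardless of how many atom pairs qualify.

Disulfides: Cys SG-SG pairs within 2.3 A, greedily matched nearest-first so
each cysteine joins at most one bond.

Hydrogen bonds: geometric criterion — donor-acceptor distance <= 3.5 A and
D-H...A angle >= 120 deg; amide hydrogens are placed at ideal geometry when
absent from the structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structures import Structure

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
HIS_BASIC_ATOMS = ("ND1", "NE2")


@dataclass
class InteractionSet:
    salt_bridges: list[tuple[int, int]] = field(default_factory=list)
    disulfides: list[tuple[int, int]] = field(default_factory=list)
    hbond_count: int = 0
    cutoffs: dict[str, float] = field(default_factory=dict)


def _atoms_of(structure: Structure, spec: dict[str, tuple[str, ...]]):
    """(residue_index, coords) for atoms matching residue->atom-name spec."""
    out = []
    for i in range(len(structure)):
        names = spec.get(str(structure.residue_name[i]))
        if names and str(structure.name[i]) in names:
            out.append((int(structure.residue_index[i]), structure.coords[i]))
    return out


def find_salt_bridges(
    structure: Structure,
    cutoff: float = 3.2,
    charged_his: set[int] | None = None,
) -> list[tuple[int, int]]:
    """Unique (acidic residue, basic residue) index pairs within the cutoff.

    ``charged_his`` optionally lists residue indices of histidines to treat
    as protonated (included as basic); by default His is excluded.
    """
    acidic = _atoms_of(structure, ACIDIC_ATOMS)
    basic = _atoms_of(structure, BASIC_ATOMS)
    if charged_his:
        his = _atoms_of(structure, {"HIS": HIS_BASIC_ATOMS})
        basic.extend((r, c) for r, c in his if r in charged_his)
    pairs = set()
    for ra, ca in acidic:
        for rb, cb in basic:
            if ra != rb and np.linalg.norm(ca - cb) <= cutoff:
                pairs.add((ra, rb))
    return sorted(pairs)


def find_disulfides(structure: Structure, cutoff: float = 2.3) -> list[tuple[int, int]]:
    """Cys SG-SG pairs within the cutoff; greedy nearest-first unique matching."""
    sg = [
        (int(structure.residue_index[i]), structure.coords[i])
        for i in range(len(structure))
        if str(structure.residue_name[i]) == "CYS" and str(structure.name[i]) == "SG"
    ]
    candidates = []
    for a in range(len(sg)):
        for b in range(a + 1, len(sg)):
            d = float(np.linalg.norm(sg[a][1] - sg[b][1]))
            if d <= cutoff and sg[a][0] != sg[b][0]:
                candidates.append((d, sg[a][0], sg[b][0]))
    candidates.sort()
    used: set[int] = set()
    pairs = []
    skipped = 0
    for d, ra, rb in candidates:
        if ra in used or rb in used:
            skipped += 1
            continue
        pairs.append((min(ra, rb), max(ra, rb)))
        used.update((ra, rb))
    if skipped:
        warnings.warn(f"{skipped} candidate disulfide pair(s) dropped by greedy matching")
    return sorted(pairs)


def _donor_hydrogens(structure: Structure) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(donor atom index, donor coords, H coords) for N/O donors.

    Explicit hydrogens are matched by covalent distance (<= 1.25 A); backbone
    amide H is placed at ideal in-plane geometry when absent.
    """
    coords = structure.coords
    is_h = structure.element == "H"
    h_idx = np.where(is_h)[0]
    donors = []
    matched: dict[int, list[np.ndarray]] = {}
    for hi in h_idx:
        d2 = np.sum((coords - coords[hi]) ** 2, axis=1)
        d2[is_h] = np.inf
        j = int(np.argmin(d2))
        if structure.element[j] in ("N", "O") and d2[j] <= 1.25**2:
            matched.setdefault(j, []).append(coords[hi])
    for j, hs in matched.items():
        for h in hs:
            donors.append((j, coords[j], h))
    # infer missing backbone amide hydrogens
    res_atoms: dict[int, dict[str, int]] = {}
    for i in range(len(structure)):
        res_atoms.setdefault(int(structure.residue_index[i]), {})[str(structure.name[i])] = i
    for r, atoms in res_atoms.items():
        ni = atoms.get("N")
        if ni is None or ni in matched:
            continue
        prev = res_atoms.get(r - 1, {})
        ci, cai = prev.get("C"), atoms.get("CA")
        if ci is None or cai is None or str(structure.residue_name[ni]) == "PRO":
            continue
        n = coords[ni]
        u = (n - coords[ci]) / np.linalg.norm(n - coords[ci]) + (
            n - coords[cai]
        ) / np.linalg.norm(n - coords[cai])
        h = n + 1.01 * u / np.linalg.norm(u)
        donors.append((ni, n, h))
    return donors


def count_hbonds(
    structure: Structure,
    d_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> int:
    """Count (donor, acceptor) pairs meeting the geometric criterion.

    Acceptors are all N/O atoms; pairs within the same residue are excluded,
    and each (donor atom, acceptor atom) pair counts once (the best hydrogen
    is used when a donor carries several).
    """
    donors = _donor_hydrogens(structure)
    acc_idx = np.where(np.isin(structure.element, ("N", "O")))[0]
    coords = structure.coords
    count = 0
    counted: set[tuple[int, int]] = set()
    for di, d_xyz, h_xyz in donors:
        for ai in acc_idx:
            if ai == di or (di, int(ai)) in counted:
                continue
            if structure.residue_index[ai] == structure.residue_index[di]:
                continue
            a_xyz = coords[ai]
            if np.linalg.norm(d_xyz - a_xyz) > d_cutoff:
                continue
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle >= angle_cutoff:
                counted.add((di, int(ai)))
                count += 1
    return count


def interaction_census(
    structure: Structure,
    salt_bridge_cutoff: float = 3.2,
    disulfide_cutoff: float = 2.3,
    hbond_d_cutoff: float = 3.5,
    hbond_angle_cutoff: float = 120.0,
) -> InteractionSet:
    return InteractionSet(
        salt_bridges=find_salt_bridges(structure, salt_bridge_cutoff),
        disulfides=find_disulfides(structure, disulfide_cutoff),
        hbond_count=count_hbonds(structure, hbond_d_cutoff, hbond_angle_cutoff),
        cutoffs={
            "salt_bridge": salt_bridge_cutoff,
            "disulfide": disulfide_cutoff,
            "hbond_distance": hbond_d_cutoff,
            "hbond_angle": hbond_angle_cutoff,
        },
    )
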