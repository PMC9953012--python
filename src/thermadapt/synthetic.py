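"""Synthetic fixtures with known ground truth for every analysis stage.

All generators are deterministic given a seed. The conformational-trajectory
generator emulates the data model behind the active-site state analysis: a
hidden discrete Markov chain over a small number of well-separated catalytic
site conformations, observed through isotropic Gaussian coordinate noise.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .sequences import CANONICAL_AA, EnvironmentRecord, SequenceRecord
from .structures import Structure, Trajectory
from .tables import AnnotationRecord

# ---------------------------------------------------------------------------
# Ideal-geometry peptide builder
# ---------------------------------------------------------------------------

# bond lengths (A) and angles (deg) for an ideal polypeptide backbone
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.521, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.5

PHI_PSI = {"helix": (-57.0, -47.0), "extended": (-135.0, 135.0)}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float,
          torsion: float) -> np.ndarray:
    """Place atom d given chain a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d)."""
    angle = np.deg2rad(angle)
    torsion = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O (+ placement anchors) for each residue."""
    res: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": N, "CA": CA, "C": C})
    for _ in range(1, n_res):
        prev = res[-1]
        Nn = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        CAn = _nerf(prev["CA"], prev["C"], Nn, _B_N_CA, _A_C_N_CA, 180.0)
        Cn = _nerf(prev["C"], Nn, CAn, _B_CA_C, _A_N_CA_C, phi)
        res.append({"N": Nn, "CA": CAn, "C": Cn})
    # carbonyl oxygens: anti to the next N (torsion N-CA-C-O = psi - 180)
    for i, r in enumerate(res):
        r["O"] = _nerf(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi - 180.0)
    return res


def gen_peptide_structure(
    n_res: int,
    conformation: str = "helix",
    seed: int = 0,
    residue_name: str = "ALA",
    hydrogens: bool = False,
) -> Structure:
    """Build an ideal-geometry poly-amino-acid peptide.

    ``helix`` uses phi=-57, psi=-47; ``extended`` phi=-135, psi=135;
    ``separated`` places single residues >= 20 A apart (no inter-residue
    contacts at any van der Waals based cutoff).
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    if conformation not in ("helix", "extended", "separated"):
        raise ValueError(f"unknown conformation {conformation!r}")

    def residue_atoms(bb: dict[str, np.ndarray], idx: int, with_h: bool):
        atoms = [
            ("N", "N", bb["N"]),
            ("CA", "C", bb["CA"]),
            ("C", "C", bb["C"]),
            ("O", "O", bb["O"]),
        ]
        if residue_name != "GLY":
            cb = _nerf(bb["C"], bb["N"], bb["CA"], _B_CA_CB, _A_N_CA_CB, 122.5)
            atoms.append(("CB", "C", cb))
        if with_h and "H" in bb:
            atoms.append(("H", "H", bb["H"]))
        return [(name, elem, tuple(xyz), idx, residue_name) for name, elem, xyz in atoms]

    if conformation == "separated":
        records = []
        bb0 = _build_backbone(1, *PHI_PSI["extended"])[0]
        for i in range(n_res):
            offset = np.array([25.0 * i, 0.0, 0.0])
            bb = {k: v + offset for k, v in bb0.items()}
            records.extend(residue_atoms(bb, i, hydrogens))
        return Structure.from_atom_records(records, source_id=f"separated{n_res}")

    phi, psi = PHI_PSI[conformation]
    bbs = _build_backbone(n_res, phi, psi)
    if hydrogens:
        for i in range(1, n_res):
            n, ca, cprev = bbs[i]["N"], bbs[i]["CA"], bbs[i - 1]["C"]
            u = (n - cprev) / np.linalg.norm(n - cprev) + (n - ca) / np.linalg.norm(n - ca)
            bbs[i]["H"] = n + _B_N_H * u / np.linalg.norm(u)
    records = []
    for i, bb in enumerate(bbs):
        records.extend(residue_atoms(bb, i, hydrogens))
    return Structure.from_atom_records(records, source_id=f"{conformation}{n_res}")


# ---------------------------------------------------------------------------
# Catalytic-site conformational-state trajectories
# ---------------------------------------------------------------------------

# heavy atoms of the three catalytic residues: Ser (6), Lys (9), Ser (6)
SITE_ATOMS = (
    [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O")],
    [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"),
     ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O")],
)
SITE_RESIDUES = ("SER", "LYS", "SER")
SITE_ROLES = ("S1", "K", "S2")
N_SITE_ATOMS = 21


def site_topology(source_id: str = "site") -> Structure:
    """A 21-heavy-atom Ser-Lys-Ser catalytic-site topology (coords filled later)."""
    records = []
    for ridx, (atoms, rname) in enumerate(zip(SITE_ATOMS, SITE_RESIDUES)):
        for name, elem in atoms:
            records.append((name, elem, (0.0, 0.0, 0.0), ridx, rname))
    return Structure.from_atom_records(records, source_id=source_id)


def _base_site_coords(rng: np.random.Generator) -> np.ndarray:
    """A rough catalytic-site geometry: three residue blobs ~6-8 A apart."""
    centers = np.array([[0.0, 0.0, 0.0], [6.0, 1.0, 0.5], [3.5, 5.5, 1.0]])
    coords = []
    for block, center in zip(SITE_ATOMS, centers):
        coords.append(center + rng.uniform(-1.8, 1.8, size=(len(block), 3)))
    return np.vstack(coords)


def make_site_centroids(
    n_states: int, seed: int = 0, separation: float = 2.0
) -> np.ndarray:
    """``n_states`` site conformations with pairwise RMSD > ``separation``.

    States differ by internal deformation (not rigid motion), so their
    interatomic-distance vectors are genuinely distinct.
    """
    rng = np.random.default_rng(seed)
    base = _base_site_coords(rng)
    centroids = [base]
    while len(centroids) < n_states:
        cand = base + rng.normal(scale=separation, size=base.shape)
        rmsds = [np.sqrt(np.mean(np.sum((cand - c) ** 2, axis=1))) for c in centroids]
        if min(rmsds) > separation:
            centroids.append(cand)
    return np.array(centroids)


@dataclass
class StateTrajectorySpec:
    """Ground-truth specification of a Markov-switching conformational trajectory."""

    n_states: int
    n_frames: int
    transition_matrix: np.ndarray
    centroids: np.ndarray | None = None  # (k, 21, 3); generated from seed if None
    noise_sd: float = 0.25  # A
    seed: int = 0
    frame_interval: float = 20.0  # ps

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        P = self.transition_matrix
        if P.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape mismatch")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must be stochastic")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.centroids is None:
            self.centroids = make_site_centroids(
                self.n_states, seed=self.seed, separation=max(4.0 * self.noise_sd, 2.0)
            )
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (self.n_states, N_SITE_ATOMS, 3):
            raise ValueError("centroids must have shape (k, 21, 3)")


def gen_state_trajectory(spec: StateTrajectorySpec) -> tuple[Trajectory, np.ndarray]:
    """Simulate the hidden chain from a uniform start and return frames + labels."""
    rng = np.random.default_rng(spec.seed)
    k, T = spec.n_states, spec.n_frames
    labels = np.empty(T, dtype=int)
    labels[0] = rng.integers(k)
    cum = np.cumsum(spec.transition_matrix, axis=1)
    u = rng.random(T)
    for t in range(1, T):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t])
    coords = spec.centroids[labels] + rng.normal(
        scale=spec.noise_sd, size=(T, N_SITE_ATOMS, 3)
    ) if spec.noise_sd > 0 else spec.centroids[labels].copy()
    traj = Trajectory(
        topology=site_topology(f"site-seed{spec.seed}"),
        coords=coords,
        frame_interval=spec.frame_interval,
    )
    return traj, labels


# ---------------------------------------------------------------------------
# Annotation tables with known curation ground truth
# ---------------------------------------------------------------------------

_SERINE_GO = "serine-type endopeptidase activity"
_INHIBITOR_GO = "serine-type endopeptidase inhibitor activity"


def _random_sequence(rng: np.random.Generator, length: int = 120) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


def gen_annotation_table(
    n_true_proteases: int,
    n_decoys: int,
    n_membrane_flagged: int,
    n_signal_rescued: int,
    seed: int = 0,
) -> tuple[list[AnnotationRecord], set[str]]:
    """An annotation table plus the ground-truth retained accession set.

    Each decoy violates exactly one curation rule (cycling through inhibitor
    GO, absent serine evidence, and the ClpA name blocklist); membrane-flagged
    records alternate between deep membrane regions and unrescued N-terminal
    ones; rescued records have an N-terminal membrane region plus a signal
    peptide.
    """
    for n in (n_true_proteases, n_decoys, n_membrane_flagged, n_signal_rescued):
        if n < 0:
            raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[AnnotationRecord] = []
    truth: set[str] = set()
    counter = 0

    def acc() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:04d}"

    for i in range(n_true_proteases):
        a = acc()
        records.append(
            AnnotationRecord(
                accession=a,
                go_terms={_SERINE_GO},
                protein_name=f"putative serine protease {i + 1}",
                sequence=_random_sequence(rng),
            )
        )
        truth.add(a)
    for i in range(n_decoys):
        kind = i % 3
        if kind == 0:
            rec = AnnotationRecord(
                accession=acc(),
                go_terms={_SERINE_GO, _INHIBITOR_GO},
                protein_name="protease inhibitor",
                sequence=_random_sequence(rng),
            )
        elif kind == 1:
            rec = AnnotationRecord(
                accession=acc(),
                go_terms={"hydrolase activity"},
                protein_name="hypothetical protein",
                sequence=_random_sequence(rng),
            )
        else:
            rec = AnnotationRecord(
                accession=acc(),
                go_terms={_SERINE_GO},
                protein_name="ATP-dependent Clp protease ATP-binding subunit ClpA",
                sequence=_random_sequence(rng),
            )
        records.append(rec)
    for i in range(n_membrane_flagged):
        if i % 2 == 0:  # membrane region beyond position 70: never rescuable
            regions, signal = [(80, 100)], None
        else:  # N-terminal membrane region but no signal peptide
            regions, signal = [(5, 25)], None
        records.append(
            AnnotationRecord(
                accession=acc(),
                go_terms={_SERINE_GO},
                protein_name="membrane-associated serine protease",
                membrane_regions=regions,
                signal_peptide=signal,
                sequence=_random_sequence(rng),
            )
        )
    for _ in range(n_signal_rescued):
        a = acc()
        records.append(
            AnnotationRecord(
                accession=a,
                go_terms={_SERINE_GO},
                protein_name="secreted serine protease",
                membrane_regions=[(5, 25)],
                signal_peptide=(1, 29),
                sequence=_random_sequence(rng),
            )
        )
        truth.add(a)
    order = rng.permutation(len(records))
    return [records[i] for i in order], truth


# ---------------------------------------------------------------------------
# Group-biased sequence sets
# ---------------------------------------------------------------------------


def gen_group_sequences(
    groups: dict[str, np.ndarray | dict[str, float]],
    n_per_group: int,
    length: int,
    seed: int = 0,
) -> list[SequenceRecord]:
    """IID sequences drawn from group-specific letter distributions.

    ``groups`` maps a group name to a probability vector over the 20
    canonical letters (array in CANONICAL_AA order, or a letter->prob dict).
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(CANONICAL_AA))
    records = []
    for group, bias in groups.items():
        if isinstance(bias, dict):
            p = np.array([bias.get(a, 0.0) for a in CANONICAL_AA], dtype=float)
        else:
            p = np.asarray(bias, dtype=float)
        if p.shape != (20,):
            raise ValueError(f"{group}: bias must cover the 20 canonical letters")
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError(f"{group}: bias is not a probability vector")
        thermal = group if group in ("psychrophile", "mesophile", "thermophile") else "unknown"
        for i in range(n_per_group):
            seq = "".join(rng.choice(letters, size=length, p=p))
            records.append(
                SequenceRecord(
                    id=f"{group}_{i + 1}",
                    sequence=seq,
                    organism_id=group,
                    thermal_group=thermal,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Synthetic study cohort
# ---------------------------------------------------------------------------


@dataclass
class SyntheticProtein:
    protein_id: str
    structure: Structure
    trajectory: Trajectory
    state_labels: np.ndarray
    environment: EnvironmentRecord
    catalytic_residues: tuple[int, int, int] = (0, 1, 2)


def gen_cohort(
    n_proteins: int = 3,
    n_frames: int = 500,
    n_states: int = 3,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> list[SyntheticProtein]:
    """A small synthetic protein cohort for end-to-end runs.

    Every protein gets an ideal-helix peptide "structure" (for surface, PSN
    and interaction stages), a catalytic-site trajectory drawn over a shared
    set of conformational states (so that all trajectories embed into the
    same space, as in a joint multi-protein analysis), and an environmental
    temperature spanning the psychrophile-thermophile range.
    """
    rng = np.random.default_rng(seed)
    centroids = make_site_centroids(n_states, seed=seed, separation=max(4 * noise_sd, 2.0))
    temperatures = np.linspace(275.0, 350.0, n_proteins)
    proteins = []
    for i in range(n_proteins):
        alpha = np.full(n_states, 0.6)
        P = rng.dirichlet(alpha, size=n_states)
        P = 0.5 * P + 0.5 * np.eye(n_states)  # sticky states
        P /= P.sum(axis=1, keepdims=True)
        spec = StateTrajectorySpec(
            n_states=n_states,
            n_frames=n_frames,
            transition_matrix=P,
            centroids=centroids,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        traj, labels = gen_state_trajectory(spec)
        structure = gen_peptide_structure(12 + 2 * i, "helix", seed=seed)
        structure.source_id = f"synprot{i + 1}"
        proteins.append(
            SyntheticProtein(
                protein_id=f"synprot{i + 1}",
                structure=structure,
                trajectory=traj,
                state_labels=labels,
                environment=EnvironmentRecord(
                    organism_id=f"org{i + 1}", temperature=float(temperatures[i])
                ),
            )
        )
    return proteins
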