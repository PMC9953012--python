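"""Moiety-level protein structure networks and cohesion statistics.

Nodes are chemical moieties (a backbone group per residue plus chemically
contiguous side-chain groups); two moieties are adjacent when at least one
heavy-atom pair lies within ``factor`` (default 1.1) times the sum of the
atoms' van der Waals radii. Degree and degree k-core number are the local
cohesion measures; cohesion is regressed on observed environmental
temperature by OLS with Pearson correlation and pointwise confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy import stats

from .resources import moiety_table, vdw_radii
from .structures import Structure

DEFAULT_CONTACT_FACTOR = 1.1


def build_psn(
    structure: Structure,
    moieties: dict[tuple[str, str], str] | None = None,
    vdw: dict[str, float] | None = None,
    factor: float = DEFAULT_CONTACT_FACTOR,
    include_intra_residue: bool = True,
) -> nx.Graph:
    """Build the moiety contact network from heavy atoms.

    Contact comparison is "<=" at exactly ``factor * (r_a + r_b)``. Node ids
    are (residue_index, moiety_label); node attributes carry residue name and
    index. Hydrogens are excluded from contact detection.
    """
    moieties = moieties or moiety_table()
    vdw = vdw or vdw_radii()
    heavy = structure.heavy()
    labels = []
    for rname, aname in zip(heavy.residue_name, heavy.name):
        key = (str(rname), str(aname))
        if key not in moieties:
            raise KeyError(f"atom {aname!r} of residue {rname!r} has no moiety mapping")
        labels.append(moieties[key])
    node_ids = [
        (int(r), lab) for r, lab in zip(heavy.residue_index, labels)
    ]
    radii = np.array([vdw[e] for e in heavy.element])

    g = nx.Graph()
    for (nid, rname) in sorted(set(zip(node_ids, heavy.residue_name))):
        g.add_node(nid, residue_index=nid[0], moiety=nid[1], residue_name=str(rname))

    coords = heavy.coords
    tree = cKDTree(coords)
    cutoff_max = factor * 2 * radii.max()
    for i, j in tree.query_pairs(cutoff_max):
        u, v = node_ids[i], node_ids[j]
        if u == v:
            continue
        if not include_intra_residue and u[0] == v[0]:
            continue
        d = np.linalg.norm(coords[i] - coords[j])
        if d <= factor * (radii[i] + radii[j]):
            g.add_edge(u, v)
    return g


def core_numbers(psn: nx.Graph) -> dict:
    """Per-node degree k-core numbers (standard peeling)."""
    if psn.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return nx.core_number(psn)


@dataclass
class CohesionSummary:
    protein_id: str
    mean_degree: float
    mean_core: float
    temperature: float
    by_exposure: dict[str, dict[str, float]] = field(default_factory=dict)
    by_ss: dict[str, dict[str, float]] = field(default_factory=dict)
    n_nodes: int = 0


def cohesion_summary(
    psn: nx.Graph,
    temperature: float,
    protein_id: str = "",
    exposure: Optional[np.ndarray] = None,
    ss: Optional[np.ndarray] = None,
) -> CohesionSummary:
    """Mean degree / core number, optionally stratified by residue exposure and
    secondary-structure class (a moiety inherits its residue's labels)."""
    if psn.number_of_nodes() == 0:
        raise ValueError("empty graph")
    cores = core_numbers(psn)
    nodes = list(psn.nodes)
    deg = np.array([psn.degree(n) for n in nodes], dtype=float)
    core = np.array([cores[n] for n in nodes], dtype=float)
    ridx = np.array([psn.nodes[n]["residue_index"] for n in nodes])

    def stratify(residue_labels: np.ndarray) -> dict[str, dict[str, float]]:
        node_labels = np.array([str(residue_labels[r]) for r in ridx])
        out = {}
        for lab in sorted(set(node_labels)):
            m = node_labels == lab
            out[lab] = {
                "mean_degree": float(deg[m].mean()),
                "mean_core": float(core[m].mean()),
                "n_nodes": int(m.sum()),
            }
        return out

    return CohesionSummary(
        protein_id=protein_id,
        mean_degree=float(deg.mean()),
        mean_core=float(core.mean()),
        temperature=float(temperature),
        by_exposure=stratify(exposure) if exposure is not None else {},
        by_ss=stratify(ss) if ss is not None else {},
        n_nodes=len(nodes),
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    band: np.ndarray  # (n, 2) pointwise 95% CI of the mean at each x
    x: np.ndarray
    fitted: np.ndarray


def cohesion_temperature_regression(
    summaries: list[CohesionSummary],
    measure: str = "mean_core",
) -> RegressionResult:
    """OLS of mean cohesion on temperature with Pearson rho and 95% bands."""
    import statsmodels.api as sm

    if len(summaries) < 3:
        raise ValueError("need >= 3 proteins for the regression")
    x = np.array([s.temperature for s in summaries], dtype=float)
    y = np.array([getattr(s, measure) for s in summaries], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero temperature variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    r, p = stats.pearsonr(x, y)
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    band = np.column_stack([pred["mean_ci_lower"], pred["mean_ci_upper"]])
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pearson_r=float(r),
        p_value=float(p),
        band=band,
        x=x,
        fitted=np.asarray(fit.fittedvalues),
    )


def export_edge_list(psn: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("u_residue\tu_moiety\tv_residue\tv_moiety\n")
        for (ur, um), (vr, vm) in sorted(psn.edges):
            fh.write(f"{ur}\t{um}\t{vr}\t{vm}\n")


def export_graphml(psn: nx.Graph, path: str) -> None:
    g = nx.relabel_nodes(psn, {n: f"{n[0]}:{n[1]}" for n in psn.nodes})
    nx.write_graphml(g, path)
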