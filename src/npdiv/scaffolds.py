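"""Molecular networking: consolidate LC-MS features into chemical scaffolds.

Natural product biosynthesis emits assemblages of structurally related
metabolites rather than single products, so counting raw LC-MS features
overstates the number of distinct chemistries. Feature-based molecular
networking groups features whose MS/MS spectra are similar under the
modified cosine score — a cosine similarity that also counts fragment
peaks offset by the precursor mass difference, so analogs differing by a
single modification still align. Connected components of the resulting
network ("molecular families") serve as a proxy for shared chemical
scaffolds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import IncidenceMatrix
from .errors import MalformedMGFError

__all__ = [
    "Spectrum",
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "assignment_from_network",
    "scaffold_incidence",
]


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor m/z plus fragment peaks.

    Peaks are stored sorted by fragment m/z; intensities must be
    nonnegative and the peak list nonempty.
    """

    feature_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise MalformedMGFError(f"spectrum {self.feature_id}: empty peak list")
        if self.mz.shape != self.intensity.shape:
            raise MalformedMGFError(f"spectrum {self.feature_id}: mz/intensity mismatch")
        if (self.intensity < 0).any():
            raise MalformedMGFError(f"spectrum {self.feature_id}: negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return self.mz.size


def _weights(spectrum: Spectrum, weighting: str) -> np.ndarray:
    if weighting == "sqrt":
        w = np.sqrt(spectrum.intensity)
    elif weighting == "raw":
        w = spectrum.intensity.astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    norm = np.linalg.norm(w)
    if norm == 0:
        raise MalformedMGFError(f"spectrum {spectrum.feature_id}: all-zero intensities")
    return w / norm


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = 0.02,
    weighting: str = "sqrt",
) -> tuple[float, int]:
    """Modified cosine similarity between two spectra.

    Candidate peak pairs are those matching directly
    (``|mz_a - mz_b| <= frag_tol``) or after shifting by the precursor
    mass difference (``|mz_a - mz_b - delta| <= frag_tol`` with
    ``delta = precursor_a - precursor_b``). A greedy one-to-one
    assignment is taken in descending order of intensity product, and
    the score is the sum of matched products after normalizing each
    spectrum's (optionally square-root) intensity vector to unit length,
    giving a score in [0, 1].

    Returns
    -------
    (score, n_matched)
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    wa = _weights(a, weighting)
    wb = _weights(b, weighting)
    delta = a.precursor_mz - b.precursor_mz
    diff = a.mz[:, None] - b.mz[None, :]
    candidate = np.abs(diff) <= frag_tol
    if delta != 0.0:
        candidate |= np.abs(diff - delta) <= frag_tol
    ii, jj = np.nonzero(candidate)
    if ii.size == 0:
        return 0.0, 0
    products = wa[ii] * wb[jj]
    # stable order: descending product, ties broken by (i, j) for determinism
    order = np.lexsort((jj, ii, -products))
    used_a = np.zeros(a.n_peaks, dtype=bool)
    used_b = np.zeros(b.n_peaks, dtype=bool)
    score = 0.0
    n_matched = 0
    for idx in order:
        i, j = ii[idx], jj[idx]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = True
        used_b[j] = True
        score += products[idx]
        n_matched += 1
    return float(min(score, 1.0)), n_matched


def _candidate_upper_bound(a: Spectrum, b: Spectrum, frag_tol: float) -> int:
    """Cheap upper bound on the number of matchable peak pairs.

    Counts a-peaks that have any direct or shifted partner in b (each
    matched pair consumes a distinct a-peak, so this bounds n_matched
    from above). Used to skip full scoring for the vast majority of
    unrelated spectrum pairs during network construction.
    """
    delta = a.precursor_mz - b.precursor_mz
    hits = _has_partner(a.mz, b.mz, frag_tol)
    if delta != 0.0:
        hits |= _has_partner(a.mz - delta, b.mz, frag_tol)
    return int(hits.sum())


def _has_partner(query: np.ndarray, sorted_ref: np.ndarray, tol: float) -> np.ndarray:
    lo = np.searchsorted(sorted_ref, query - tol, side="left")
    hi = np.searchsorted(sorted_ref, query + tol, side="right")
    return hi > lo


@dataclass
class MolecularNetwork:
    """Spectra as nodes, modified-cosine edges, components as scaffolds."""

    graph: nx.Graph
    components: pd.Series  # feature_id -> scaffold label
    params: dict = field(default_factory=dict)

    @property
    def n_scaffolds(self) -> int:
        return int(self.components.nunique())

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["cosine"], d["n_matched"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "cosine", "n_matched"])


def build_network(
    spectra,
    min_cosine: float = 0.7,
    min_matched: int = 6,
    top_k: int = 10,
    frag_tol: float = 0.02,
    weighting: str = "sqrt",
) -> MolecularNetwork:
    """Build a molecular network and its scaffold partition.

    An edge is kept iff the modified cosine score is at least
    ``min_cosine``, the number of matched peaks at least ``min_matched``,
    and each endpoint ranks the other within its ``top_k`` best-scoring
    partners (the mutual-rank rule used by feature-based molecular
    networking). Connected components define scaffolds; isolated nodes
    are singleton scaffolds.
    """
    if min_cosine <= 0 or min_matched <= 0 or top_k <= 0:
        raise ValueError("network parameters must be positive")
    spectra = list(spectra)
    ids = [s.feature_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise MalformedMGFError("duplicate feature IDs among spectra")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    candidates: list[tuple[str, str, float, int]] = []
    for a, b in itertools.combinations(spectra, 2):
        if _candidate_upper_bound(a, b, frag_tol) < min_matched:
            continue
        score, n_matched = modified_cosine(a, b, frag_tol=frag_tol, weighting=weighting)
        if score >= min_cosine and n_matched >= min_matched:
            candidates.append((a.feature_id, b.feature_id, score, n_matched))

    # mutual top-K filter: each endpoint must rank the other in its top_k
    partners: dict[str, list[tuple[float, str]]] = {i: [] for i in ids}
    for u, v, score, _ in candidates:
        partners[u].append((score, v))
        partners[v].append((score, u))
    allowed: dict[str, set[str]] = {}
    for node, lst in partners.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
        allowed[node] = {other for _, other in lst[:top_k]}
    for u, v, score, n_matched in candidates:
        if v in allowed[u] and u in allowed[v]:
            graph.add_edge(u, v, cosine=score, n_matched=n_matched)

    labels = {}
    for comp_idx, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]), start=1
    ):
        for node in comp:
            labels[node] = f"SC{comp_idx:05d}"
    components = pd.Series(labels, name="scaffold_id").loc[ids]
    return MolecularNetwork(
        graph,
        components,
        params={
            "min_cosine": min_cosine,
            "min_matched": min_matched,
            "top_k": top_k,
            "frag_tol": frag_tol,
            "weighting": weighting,
        },
    )


def assignment_from_network(network: MolecularNetwork) -> pd.DataFrame:
    """Tabulate the scaffold membership: feature_id, scaffold_id, singleton flag."""
    sizes = network.components.value_counts()
    out = pd.DataFrame(
        {
            "feature_id": network.components.index,
            "scaffold_id": network.components.to_numpy(),
        }
    )
    out["singleton"] = out["scaffold_id"].map(sizes).eq(1).to_numpy()
    return out.set_index("feature_id")


def scaffold_incidence(
    assignment: pd.DataFrame,
    feature_incidence: IncidenceMatrix,
    drop_singletons: bool = False,
) -> tuple[IncidenceMatrix, int]:
    """Project feature presence onto scaffolds.

    A scaffold is present in an isolate iff at least one member feature
    is present there. Features without a scaffold assignment become
    their own singleton scaffolds. When ``drop_singletons`` is set,
    single-feature scaffolds are removed and their count returned.

    Returns
    -------
    (scaffold_incidence, n_singletons_removed)
    """
    presence = feature_incidence.presence
    scaffold_of = assignment["scaffold_id"].to_dict()
    labels = []
    n_orphans = 0
    for fid in presence.index:
        sid = scaffold_of.get(str(fid), scaffold_of.get(fid))
        if sid is None:
            n_orphans += 1
            sid = f"ORPHAN{n_orphans:05d}"
        labels.append(sid)
    grouped = presence.groupby(pd.Index(labels, name="scaffold_id")).max()
    # singleton status comes from the network partition (component of size
    # one); orphan features are singletons by construction
    network_sizes = assignment["scaffold_id"].value_counts()
    member_counts = pd.Index(labels).value_counts()
    sizes = network_sizes.reindex(member_counts.index).fillna(1)
    singletons = sizes[sizes == 1].index
    n_removed = 0
    if drop_singletons:
        n_removed = int(grouped.index.isin(singletons).sum())
        grouped = grouped.loc[~grouped.index.isin(singletons)]
    return IncidenceMatrix(grouped, feature_incidence.groups), n_removed
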