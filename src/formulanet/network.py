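"""Molecular-network construction from MS/MS spectra.

Pairwise modified-cosine similarity (square-root intensity weighting, greedy
one-to-one peak assignment over direct and precursor-shifted matches),
thresholding on score and matched-peak count, mutual top-K neighbor pruning,
and connected-component cluster indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import SpectrumRecord


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkParams:
    """Edge-filtering parameters of the molecular network.

    Defaults follow common GNPS practice for plant-extract profiling:
    0.02 Da fragment tolerance, cosine >= 0.7, >= 6 matched peaks, and the
    mutual top-50 neighbor rule.  ``strict_matched`` switches the matched-peak
    rule to a strict "more than" reading.
    """

    fragment_tol: float = 0.02
    cosine_min: float = 0.7
    min_matched: int = 6
    top_k: int = 50
    strict_matched: bool = False

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0:
            raise ValueError("fragment_tol must be > 0")
        if not 0.0 <= self.cosine_min <= 1.0:
            raise ValueError("cosine_min must be in [0, 1]")
        if self.top_k < 0:
            raise ValueError("top_k must be >= 0")

    def matched_ok(self, matched: int) -> bool:
        return matched > self.min_matched if self.strict_matched else matched >= self.min_matched


@dataclass(frozen=True)
class SpectralEdge:
    node_a: int
    node_b: int
    cosine: float
    matched_peaks: int

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValueError("edges are canonically ordered: node_a < node_b")


@dataclass
class MolecularNetwork:
    """Nodes are features with spectra; clusters are components of size >= 2.

    Cluster ids are 1-based, numbered by descending component size with ties
    broken by smallest member feature id; singletons map to -1.
    """

    mode: str
    nodes: list[int]
    edges: list[SpectralEdge]
    cluster_index: dict[int, int] = field(default_factory=dict)

    def cluster_members(self, cluster_id: int) -> list[int]:
        members = sorted(n for n, c in self.cluster_index.items() if c == cluster_id)
        if not members:
            raise KeyError(f"no such cluster: {cluster_id}")
        return members

    def cluster_ids(self) -> list[int]:
        ids = sorted({c for c in self.cluster_index.values() if c != -1})
        return ids


@dataclass
class NetworkSummary:
    n_nodes: int
    n_clusters: int
    n_clustered_nodes: int
    n_singletons: int


def normalize_spectrum(spec: SpectrumRecord) -> np.ndarray:
    """Square-root intensities scaled to unit Euclidean norm.

    Returns the per-peak weights aligned with ``spec.peaks``.
    """
    if spec.n_peaks == 0:
        raise DegenerateInputError(f"feature {spec.feature_id}: empty spectrum")
    w = np.sqrt(spec.peaks[:, 1])
    return w / np.linalg.norm(w)


def _spec_key(spec: SpectrumRecord) -> tuple:
    return (spec.precursor_mz, spec.n_peaks, spec.peaks.tobytes())


def modified_cosine(a: SpectrumRecord, b: SpectrumRecord, fragment_tol: float = 0.02
                    ) -> tuple[float, int]:
    """Modified-cosine score and matched-peak count between two spectra.

    Candidate peak pairs are those matching directly (|mz_a - mz_b| <= tol)
    or after shifting by the precursor-mass difference
    (|mz_a - mz_b - (prec_a - prec_b)| <= tol).  A one-to-one assignment is
    chosen greedily by descending weight product; the score is the sum of
    products of the unit-normalized square-root intensity weights.
    """
    # canonical operand order makes the greedy tie-breaks symmetric
    if _spec_key(b) < _spec_key(a):
        a, b = b, a
    wa = normalize_spectrum(a)
    wb = normalize_spectrum(b)
    mza = a.peaks[:, 0]
    mzb = b.peaks[:, 0]
    shift = a.precursor_mz - b.precursor_mz

    diff = mza[:, None] - mzb[None, :]
    cand = np.abs(diff) <= fragment_tol
    if abs(shift) > 1e-12:
        cand |= np.abs(diff - shift) <= fragment_tol
    ii, jj = np.nonzero(cand)
    if len(ii) == 0:
        return 0.0, 0
    products = wa[ii] * wb[jj]
    order = np.lexsort((jj, ii, -products))
    used_a = np.zeros(len(mza), dtype=bool)
    used_b = np.zeros(len(mzb), dtype=bool)
    score = 0.0
    matched = 0
    for k in order:
        i, j = ii[k], jj[k]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = True
        used_b[j] = True
        score += products[k]
        matched += 1
    return min(float(score), 1.0), matched


def build_network(spectra: list[SpectrumRecord], params: NetworkParams | None = None,
                  mode: str = "PI") -> MolecularNetwork:
    """Build the molecular network from a collection of spectra.

    Stage 1 keeps pairs passing the cosine and matched-peak thresholds;
    stage 2 keeps an edge iff each endpoint ranks within the other's top-K
    surviving neighbors by cosine (ties by lower feature id); stage 3 assigns
    cluster indices by connected components.
    """
    if params is None:
        params = NetworkParams()
    if not spectra:
        raise DegenerateInputError("no spectra supplied")
    spectra = sorted(spectra, key=lambda s: s.feature_id)
    nodes = [s.feature_id for s in spectra]
    if len(set(nodes)) != len(nodes):
        raise ValueError("duplicate feature ids among spectra")

    # stage 1: thresholded pair list
    surviving: dict[int, list[tuple[float, int]]] = {n: [] for n in nodes}
    pair_score: dict[tuple[int, int], tuple[float, int]] = {}
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            cos, matched = modified_cosine(spectra[i], spectra[j], params.fragment_tol)
            if cos >= params.cosine_min and params.matched_ok(matched):
                na, nb = nodes[i], nodes[j]
                pair_score[(na, nb)] = (cos, matched)
                surviving[na].append((cos, nb))
                surviving[nb].append((cos, na))

    # stage 2: mutual top-K pruning
    topk: dict[int, set[int]] = {}
    for n, neigh in surviving.items():
        neigh.sort(key=lambda t: (-t[0], t[1]))
        topk[n] = {other for _, other in neigh[: params.top_k]}
    edges = [
        SpectralEdge(na, nb, cos, matched)
        for (na, nb), (cos, matched) in sorted(pair_score.items())
        if nb in topk[na] and na in topk[nb]
    ]

    # stage 3: connected components -> cluster index
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((e.node_a, e.node_b) for e in edges)
    components = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    components.sort(key=lambda c: (-len(c), c[0]))
    cluster_index = {n: -1 for n in nodes}
    for cid, members in enumerate(components, start=1):
        for n in members:
            cluster_index[n] = cid
    return MolecularNetwork(mode=mode, nodes=nodes, edges=edges, cluster_index=cluster_index)


def network_summary(network: MolecularNetwork) -> NetworkSummary:
    """Node/cluster counts of a built network."""
    clustered = [n for n, c in network.cluster_index.items() if c != -1]
    n_clusters = len({network.cluster_index[n] for n in clustered})
    return NetworkSummary(
        n_nodes=len(network.nodes),
        n_clusters=n_clusters,
        n_clustered_nodes=len(clustered),
        n_singletons=len(network.nodes) - len(clustered),
    )
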