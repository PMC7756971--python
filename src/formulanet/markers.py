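"""Marker selection and multi-component-signature classification.

A marker candidate is an ELSD-backed abundant component judged on its
specificity in both ionization modes.  Signature clusters are classified
into three categories: (1) herb-specific clusters containing a formally
identified marker, (2) non-specific clusters containing a marker, whose
herb-specific sub-nodes are extracted, and (3) herb-specific clusters with
no marker but taxonomically consistent annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import PROTON, AnchorPoint, AnnotationCandidate
from .elsd import ElsdAssignment
from .io import FeatureTable
from .manifest import SampleManifest
from .network import MolecularNetwork
from .specificity import (
    ClusterSpecificityTable,
    ConfigurationError,
    SpecificityParams,
    SpecificityTable,
)

STATUS_SPECIFIC = "specific"
STATUS_NON_SPECIFIC = "non_specific"
STATUS_NON_SPECIFIC_RETAINED = "non_specific_retained"
STATUS_NOT_IN_FORMULA = "not_in_formula"

DEFAULT_PAIR_RT_TOL = 0.05   # min
DEFAULT_PAIR_PPM_TOL = 10.0  # ppm on the neutral mass
DEFAULT_INSOURCE_RT_TOL = 0.02  # min; same-RT collapse of in-source features


@dataclass(frozen=True)
class CrossModePair:
    feature_id_pi: int
    feature_id_ni: int
    rt_delta: float
    neutral_mass_delta_ppm: float


@dataclass
class MarkerCandidate:
    elsd_label: str
    herb_code: str
    feature_id_pi: int | None
    feature_id_ni: int | None
    min_share: float | None
    area: float
    status: str
    single_mode: bool = False
    annotation: str = ""


@dataclass
class SignatureCluster:
    cluster_id: int
    herb_code: str
    category: int                      # 1, 2 or 3
    member_ids: list[int] = field(default_factory=list)
    anchor_ids: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------

def _neutral(mz: float, mode: str) -> float:
    return mz - PROTON if mode == "PI" else mz + PROTON


def pair_cross_mode(features_pi: FeatureTable, spec_pi: SpecificityTable,
                    features_ni: FeatureTable, spec_ni: SpecificityTable,
                    rt_tol: float = DEFAULT_PAIR_RT_TOL,
                    ppm_tol: float = DEFAULT_PAIR_PPM_TOL) -> list[CrossModePair]:
    """Pair PI and NI features of the same neutral molecule.

    A pair requires RT agreement within ``rt_tol`` and neutral-mass agreement
    ([M+H]+ minus a proton vs [M-H]- plus a proton) within ``ppm_tol``.
    Assignment is 1:1, greedy by smallest combined normalized distance, ties
    by feature ids.  Unpaired features are simply absent from the result.
    """
    pi_feats = [features_pi.get(fid) for fid in spec_pi._by_id if fid in features_pi]
    ni_feats = [features_ni.get(fid) for fid in spec_ni._by_id if fid in features_ni]
    candidates = []
    for fp in pi_feats:
        mp = _neutral(fp.mz, "PI")
        for fn in ni_feats:
            d_rt = fp.rt - fn.rt
            if abs(d_rt) > rt_tol:
                continue
            mn = _neutral(fn.mz, "NI")
            ppm = (mp - mn) / mn * 1e6
            if abs(ppm) > ppm_tol:
                continue
            dist = abs(d_rt) / rt_tol + abs(ppm) / ppm_tol
            candidates.append((dist, fp.feature_id, fn.feature_id, d_rt, ppm))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_pi: set[int] = set()
    used_ni: set[int] = set()
    pairs = []
    for _, fid_pi, fid_ni, d_rt, ppm in candidates:
        if fid_pi in used_pi or fid_ni in used_ni:
            continue
        used_pi.add(fid_pi)
        used_ni.add(fid_ni)
        pairs.append(CrossModePair(fid_pi, fid_ni, d_rt, ppm))
    pairs.sort(key=lambda p: p.feature_id_pi)
    return pairs


def _herb_share(spec: SpecificityTable | None, fid: int | None, herb: str) -> float | None:
    if spec is None or fid is None or fid not in spec:
        return None
    row = spec.get(fid)
    if row.shares is None:
        return None
    return row.shares.get(herb)


def select_markers(assignments: list[ElsdAssignment],
                   spec_pi: SpecificityTable | None,
                   spec_ni: SpecificityTable | None,
                   params: SpecificityParams | None = None,
                   abundance_override_top_n: int = 0,
                   annotations: dict[str, str] | None = None
                   ) -> list[MarkerCandidate]:
    """Judge each ELSD-backed feature as a marker candidate.

    Status is ``specific`` iff the specificity share for the source herb is
    >= the node threshold in every ionization mode where the feature was
    detected (single-mode features are judged on that mode and flagged);
    ``not_in_formula`` when the ELSD peak matched no formula feature.  With
    ``abundance_override_top_n`` > 0, the top-n peaks per herb by area that
    fail the threshold are relabeled ``non_specific_retained`` instead of
    being silently passed (abundance can justify keeping a sub-threshold
    marker).  Output is sorted by herb then area descending.
    """
    params = params or SpecificityParams()
    out = []
    for a in assignments:
        if not a.matched:
            out.append(MarkerCandidate(a.elsd_label, a.herb_code, None, None,
                                       None, a.area, STATUS_NOT_IN_FORMULA))
            continue
        shares = [
            s for s in (
                _herb_share(spec_pi, a.feature_id_pi, a.herb_code),
                _herb_share(spec_ni, a.feature_id_ni, a.herb_code),
            ) if s is not None
        ]
        min_share = min(shares) if shares else None
        single = len(shares) == 1
        if min_share is not None and min_share >= params.node_threshold:
            status = STATUS_SPECIFIC
        else:
            status = STATUS_NON_SPECIFIC
        out.append(MarkerCandidate(
            a.elsd_label, a.herb_code, a.feature_id_pi, a.feature_id_ni,
            min_share, a.area, status, single_mode=single,
            annotation=(annotations or {}).get(a.elsd_label, ""),
        ))
    if abundance_override_top_n > 0:
        by_herb: dict[str, list[MarkerCandidate]] = {}
        for m in out:
            by_herb.setdefault(m.herb_code, []).append(m)
        for group in by_herb.values():
            group.sort(key=lambda m: -m.area)
            for m in group[:abundance_override_top_n]:
                if m.status == STATUS_NON_SPECIFIC:
                    m.status = STATUS_NON_SPECIFIC_RETAINED
    out.sort(key=lambda m: (m.herb_code, -m.area, m.elsd_label))
    return out


def specificity_bins(markers: list[MarkerCandidate]) -> dict[str, int]:
    """Bin specific markers by their worst-mode share: fully specific
    (100%), 95-99%, and 90-94%.  Returns the three counts and their total."""
    bins = {"100": 0, "95-99": 0, "90-94": 0}
    for m in markers:
        if m.status != STATUS_SPECIFIC or m.min_share is None:
            continue
        if m.min_share >= 100.0:
            bins["100"] += 1
        elif m.min_share >= 95.0:
            bins["95-99"] += 1
        elif m.min_share >= 90.0:
            bins["90-94"] += 1
    bins["total"] = bins["100"] + bins["95-99"] + bins["90-94"]
    return bins


def markers_frame(markers: list[MarkerCandidate]) -> pd.DataFrame:
    recs = [
        {"herb": m.herb_code, "label": m.elsd_label, "annotation": m.annotation,
         "feature_id_pi": "" if m.feature_id_pi is None else m.feature_id_pi,
         "feature_id_ni": "" if m.feature_id_ni is None else m.feature_id_ni,
         "min_share": "" if m.min_share is None else round(m.min_share, 1),
         "area": m.area, "single_mode": m.single_mode, "status": m.status}
        for m in markers
    ]
    return pd.DataFrame(recs, columns=["herb", "label", "annotation", "feature_id_pi",
                                       "feature_id_ni", "min_share", "area",
                                       "single_mode", "status"])


# ---------------------------------------------------------------------------

def classify_signature_clusters(ct: ClusterSpecificityTable,
                                network: MolecularNetwork,
                                anchors: list[AnchorPoint],
                                spec: SpecificityTable,
                                candidates: dict[int, list[AnnotationCandidate]] | None = None,
                                params: SpecificityParams | None = None
                                ) -> list[SignatureCluster]:
    """Classify clusters into the three multi-component-signature categories.

    Category 1: dominant herb set and >= 1 anchor (members = all scored
    nodes).  Category 2: anchor present but no dominant herb; members are
    restricted to nodes specific (>= node threshold) to the anchor's herb.
    Category 3: dominant herb, no anchor, and >= 1 member annotation at
    species/genus/family level.  Clusters qualifying for none are omitted.
    """
    params = params or SpecificityParams()
    node_set = set(network.nodes)
    for a in anchors:
        if a.feature_id not in node_set:
            raise ConfigurationError(
                f"anchor {a.name or a.feature_id} is not a node of the network")
    candidates = candidates or {}
    out = []
    for row in ct.rows:
        members = [m for m in network.cluster_members(row.cluster_id) if m in spec]
        cluster_anchors = [a for a in anchors if a.feature_id in
                           set(network.cluster_members(row.cluster_id))]
        if row.dominant_herb is not None and cluster_anchors:
            out.append(SignatureCluster(
                row.cluster_id, row.dominant_herb, 1, members,
                [a.feature_id for a in cluster_anchors]))
        elif cluster_anchors:
            herb = cluster_anchors[0].herb_code
            sub = [
                m for m in members
                if spec.get(m).shares is not None
                and spec.get(m).shares.get(herb, 0.0) >= params.node_threshold
            ]
            out.append(SignatureCluster(
                row.cluster_id, herb, 2, sub,
                [a.feature_id for a in cluster_anchors]))
        elif row.dominant_herb is not None:
            taxo_ok = any(
                c.taxon_level in ("species", "genus", "family")
                for m in members for c in candidates.get(m, [])
            )
            if taxo_ok:
                out.append(SignatureCluster(row.cluster_id, row.dominant_herb, 3,
                                            members, []))
    out.sort(key=lambda s: s.cluster_id)
    return out


def extract_signature(cluster: SignatureCluster, spec: SpecificityTable,
                      features: FeatureTable, manifest: SampleManifest,
                      insource_rt_tol: float = DEFAULT_INSOURCE_RT_TOL
                      ) -> pd.DataFrame:
    """Bar-chromatogram records of a signature cluster.

    Members co-eluting within ``insource_rt_tol`` (in-source adducts or
    fragments of one compound) collapse to the highest formula-height one.
    Rows are sorted by RT ascending.
    """
    formula_sample = manifest.formula_sample
    recs = []
    for fid in cluster.member_ids:
        if fid not in features:
            continue
        feat = features.get(fid)
        recs.append({"feature_id": fid, "rt": feat.rt, "mz": feat.mz,
                     "height": feat.height(formula_sample)})
    recs.sort(key=lambda r: (r["rt"], r["feature_id"]))
    collapsed: list[dict] = []
    for rec in recs:
        if collapsed and rec["rt"] - collapsed[-1]["rt"] <= insource_rt_tol:
            if rec["height"] > collapsed[-1]["height"]:
                collapsed[-1] = rec
        else:
            collapsed.append(rec)
    df = pd.DataFrame(collapsed, columns=["feature_id", "rt", "mz", "height"])
    df.insert(0, "cluster_id", cluster.cluster_id)
    df.insert(1, "herb", cluster.herb_code)
    df.insert(2, "category", cluster.category)
    return df
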