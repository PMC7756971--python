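"""Herb-specificity statistics at the node (feature) and cluster level.

The specificity percentage of a feature for one herb is its peak height in
that herb divided by the sum of its heights across all herbs, x100.  The
cluster specificity percentage is the per-herb arithmetic mean of member
features' specificity percentages.  Thresholds (node 90%, cluster 75% by
default, both inclusive) pick out features and clusters attributable to a
single herb.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .io import FeatureRecord, FeatureTable
from .manifest import SampleManifest
from .network import MolecularNetwork

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (report convention; 28.75 -> 28.8)."""
    scale = 10 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage of a count over a total, half-up rounded.

    One decimal place by default (feature-share convention); use ndigits=0
    for cluster-level summary percentages.
    """
    if total == 0:
        return 0.0
    value = round_half_up(100.0 * count / total, ndigits)
    return value if ndigits > 0 else int(value)


BLANK_RELATIVE = "relative"
BLANK_ANY = "any"


@dataclass(frozen=True)
class SpecificityParams:
    """Thresholds (inclusive, in percent) and the blank-subtraction rule.

    ``blank_rule``: "relative" flags a feature as blank-derived when its
    maximum blank height >= blank_factor x its maximum herb height; "any"
    flags any feature detected in a blank at all.
    """

    node_threshold: float = 90.0
    cluster_threshold: float = 75.0
    blank_rule: str = BLANK_RELATIVE
    blank_factor: float = 0.5

    def __post_init__(self) -> None:
        for name, t in (("node_threshold", self.node_threshold),
                        ("cluster_threshold", self.cluster_threshold)):
            if not 0.0 < t <= 100.0:
                raise ConfigurationError(f"{name} must be in (0, 100], got {t}")
        if self.blank_rule not in (BLANK_RELATIVE, BLANK_ANY):
            raise ConfigurationError(f"unknown blank_rule {self.blank_rule!r}")


@dataclass
class NodeSpecificity:
    feature_id: int
    in_formula: bool
    shares: dict[str, float] | None   # herb_code -> percent; None if no herb signal
    specific_herb: str | None


@dataclass
class SpecificityTable:
    mode: str
    rows: list[NodeSpecificity] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {r.feature_id: r for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, feature_id: int) -> bool:
        return feature_id in self._by_id

    def get(self, feature_id: int) -> NodeSpecificity:
        return self._by_id[feature_id]

    def herb_codes(self) -> list[str]:
        for r in self.rows:
            if r.shares is not None:
                return list(r.shares)
        return []

    def to_frame(self) -> pd.DataFrame:
        herbs = self.herb_codes()
        recs = []
        for r in sorted(self.rows, key=lambda r: r.feature_id):
            rec = {"feature_id": r.feature_id, "in_formula": r.in_formula,
                   "specific_herb": r.specific_herb or ""}
            for h in herbs:
                rec[f"share_{h}"] = float("nan") if r.shares is None else r.shares[h]
            recs.append(rec)
        return pd.DataFrame(recs, columns=["feature_id", "in_formula", "specific_herb",
                                           *[f"share_{h}" for h in herbs]])


@dataclass
class ClusterSpecificityRow:
    cluster_id: int
    mean_shares: dict[str, float]
    dominant_herb: str | None
    n_nodes: int


@dataclass
class ClusterSpecificityTable:
    mode: str
    rows: list[ClusterSpecificityRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {r.cluster_id: r for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, cluster_id: int) -> ClusterSpecificityRow:
        return self._by_id[cluster_id]

    def to_frame(self) -> pd.DataFrame:
        herbs = list(self.rows[0].mean_shares) if self.rows else []
        recs = [
            {"cluster_id": r.cluster_id, "n_nodes": r.n_nodes,
             "dominant_herb": r.dominant_herb or "",
             **{f"share_{h}": r.mean_shares[h] for h in herbs}}
            for r in sorted(self.rows, key=lambda r: r.cluster_id)
        ]
        return pd.DataFrame(recs, columns=["cluster_id", "n_nodes", "dominant_herb",
                                           *[f"share_{h}" for h in herbs]])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def is_blank_derived(record: FeatureRecord, manifest: SampleManifest,
                     params: SpecificityParams) -> bool:
    blanks = manifest.blank_samples
    if not blanks:
        return False
    max_blank = max(record.height(s) for s in blanks)
    if params.blank_rule == BLANK_ANY:
        return max_blank > 0
    max_herb = max((record.height(s) for s in manifest.herb_samples.values()), default=0.0)
    return max_blank >= params.blank_factor * max_herb and max_blank > 0


def filter_features(table: FeatureTable, manifest: SampleManifest,
                    params: SpecificityParams | None = None) -> FeatureTable:
    """Keep features detected in the formula and not attributable to blanks."""
    params = params or SpecificityParams()
    try:
        formula_sample = manifest.formula_sample
    except StopIteration:  # pragma: no cover - manifest invariant forbids it
        raise ConfigurationError("manifest has no formula sample")
    kept = [
        r for r in table.records
        if r.height(formula_sample) > 0 and not is_blank_derived(r, manifest, params)
    ]
    return FeatureTable(table.mode, kept)


def node_specificity(record: FeatureRecord, manifest: SampleManifest) -> dict[str, float] | None:
    """Per-herb specificity percentages of one feature; None if no herb signal.

    The denominator is the sum of heights over herb samples only; formula and
    blank heights do not enter the shares.
    """
    heights = {code: record.height(sample) for code, sample in manifest.herb_samples.items()}
    total = sum(heights.values())
    if total == 0:
        return None
    # divide before scaling so a single-source feature is exactly 100%
    return {code: 100.0 * (h / total) for code, h in heights.items()}


def compute_specificity(table: FeatureTable, manifest: SampleManifest,
                        params: SpecificityParams | None = None,
                        prefiltered: bool = False) -> SpecificityTable:
    """Specificity table of a feature table (formula-filtered unless told not to)."""
    params = params or SpecificityParams()
    work = table if prefiltered else filter_features(table, manifest, params)
    formula_sample = manifest.formula_sample
    rows = []
    for r in work.records:
        shares = node_specificity(r, manifest)
        specific = None
        if shares is not None:
            top_herb = max(shares, key=lambda h: (shares[h], h))
            if shares[top_herb] >= params.node_threshold:
                specific = top_herb
        rows.append(NodeSpecificity(r.feature_id, r.height(formula_sample) > 0, shares, specific))
    return SpecificityTable(table.mode, rows)


def count_specific(spec: SpecificityTable, threshold: float | None = None
                   ) -> tuple[dict[str, int], int, dict[str, float]]:
    """Per-herb counts of specific formula features, total, and herb shares (%).

    When ``threshold`` is given, specific status is re-derived from the raw
    shares at that threshold rather than taken from the stored labels.
    """
    herbs = spec.herb_codes()
    counts = dict.fromkeys(herbs, 0)
    for r in spec.rows:
        if not r.in_formula or r.shares is None:
            continue
        if threshold is None:
            herb = r.specific_herb
        else:
            top = max(r.shares, key=lambda h: (r.shares[h], h))
            herb = top if r.shares[top] >= threshold else None
        if herb is not None:
            counts[herb] += 1
    total = sum(counts.values())
    pct = {h: percent(c, total, 1) for h, c in counts.items()}
    return counts, total, pct


def cluster_specificity(spec: SpecificityTable, network: MolecularNetwork,
                        params: SpecificityParams | None = None,
                        all_nodes: bool = False) -> ClusterSpecificityTable:
    """Per-cluster mean specificity shares and dominant-herb assignment.

    By default only nodes present in the specificity table (formula-detected,
    blank-filtered) enter the averages; ``all_nodes`` has no effect on which
    shares exist but is kept for symmetry with exports of unfiltered tables.
    Clusters without any scored member are excluded with a warning.
    """
    params = params or SpecificityParams()
    herbs = spec.herb_codes()
    rows = []
    for cid in network.cluster_ids():
        members = network.cluster_members(cid)
        scored = [
            spec.get(m) for m in members
            if m in spec and spec.get(m).shares is not None
            and (all_nodes or spec.get(m).in_formula)
        ]
        if not scored:
            logger.warning("cluster %d has no scored members; excluded", cid)
            continue
        mean_shares = {
            h: sum(r.shares[h] for r in scored) / len(scored) for h in herbs
        }
        dominant = None
        top = max(mean_shares, key=lambda h: (mean_shares[h], h))
        if mean_shares[top] >= params.cluster_threshold:
            dominant = top
        rows.append(ClusterSpecificityRow(cid, mean_shares, dominant, len(scored)))
    return ClusterSpecificityTable(spec.mode, rows)


def count_specific_clusters(ct: ClusterSpecificityTable, network: MolecularNetwork
                            ) -> tuple[int, int, int, int]:
    """(n specific clusters, % of clusters, n nodes in them, % of nodes).

    Percentages are against the total cluster and node counts of the network,
    half-up rounded to the nearest integer.
    """
    from .network import network_summary

    summary = network_summary(network)
    specific = [r for r in ct.rows if r.dominant_herb is not None]
    n_nodes = sum(len(network.cluster_members(r.cluster_id)) for r in specific)
    return (
        len(specific),
        percent(len(specific), summary.n_clusters, 0),
        n_nodes,
        percent(n_nodes, summary.n_nodes, 0),
    )


def export_cluster_features(spec: SpecificityTable, network: MolecularNetwork,
                            features: FeatureTable, manifest: SampleManifest,
                            cluster_id: int) -> pd.DataFrame:
    """HRMS data (m/z, RT, formula height, shares) of one cluster, RT-sorted."""
    if cluster_id == -1 or cluster_id not in network.cluster_ids():
        raise KeyError(f"no such cluster: {cluster_id}")
    formula_sample = manifest.formula_sample
    herbs = spec.herb_codes()
    recs = []
    for fid in network.cluster_members(cluster_id):
        if fid not in features or fid not in spec:
            continue
        feat = features.get(fid)
        row = spec.get(fid)
        rec = {"feature_id": fid, "rt": feat.rt, "mz": feat.mz,
               "formula_height": feat.height(formula_sample)}
        for h in herbs:
            rec[f"share_{h}"] = float("nan") if row.shares is None else row.shares[h]
        recs.append(rec)
    recs.sort(key=lambda r: (r["rt"], r["feature_id"]))
    return pd.DataFrame(recs, columns=["feature_id", "rt", "mz", "formula_height",
                                       *[f"share_{h}" for h in herbs]])
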