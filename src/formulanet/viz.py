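"""The workflow's visual artifacts: 2D feature maps, bar chromatograms, and
ring-annotation attribute tables for graph viewers.

Every plot has a CSV twin carrying exactly the plotted records, and
rendering is deterministic: a fixed style, a fixed SVG hash salt, and no
timestamps in the output.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import FeatureTable
from .manifest import SampleManifest
from .network import MolecularNetwork
from .specificity import SpecificityTable

SIZE_FIXED = "fixed"
SIZE_HEIGHT = "height"
SIZE_ELSD = "elsd"
_SIZE_MODES = (SIZE_FIXED, SIZE_HEIGHT, SIZE_ELSD)

_UNASSIGNED = "#ffffff"
_CLAMP_PERCENTILE = 99.0


class ConfigurationError(ValueError):
    pass


def _set_deterministic_style() -> None:
    plt.rcParams["svg.hashsalt"] = "formulanet"
    plt.rcParams["figure.max_open_warning"] = 0


def make_feature_map(spec: SpecificityTable, features: FeatureTable,
                     manifest: SampleManifest, size_mode: str = SIZE_FIXED,
                     elsd_areas: dict[int, float] | None = None,
                     out_path: str | Path | None = None
                     ) -> tuple[pd.DataFrame, plt.Figure]:
    """2D feature map: RT on x, m/z on y, one point per formula feature.

    Specific features are filled with their herb's color inside a black
    outline; non-specific ones are unfilled outlined points.  Point size is
    fixed, proportional to formula height, or proportional to the assigned
    ELSD area (points above the 99th percentile are clamped and flagged).
    """
    if size_mode not in _SIZE_MODES:
        raise ConfigurationError(f"unknown size_mode {size_mode!r}")
    if size_mode == SIZE_ELSD and elsd_areas is None:
        raise ConfigurationError("size_mode 'elsd' requires elsd_areas")
    _set_deterministic_style()
    formula_sample = manifest.formula_sample
    records = []
    for row in sorted(spec.rows, key=lambda r: r.feature_id):
        if not row.in_formula or row.feature_id not in features:
            continue
        feat = features.get(row.feature_id)
        if size_mode == SIZE_ELSD:
            size_value = (elsd_areas or {}).get(row.feature_id)
            if size_value is None:
                continue   # only ELSD-backed features appear in this view
        elif size_mode == SIZE_HEIGHT:
            size_value = feat.height(formula_sample)
        else:
            size_value = 1.0
        color = manifest.herb_color(row.specific_herb) if row.specific_herb else _UNASSIGNED
        records.append({
            "feature_id": row.feature_id, "rt": feat.rt, "mz": feat.mz,
            "specific_herb": row.specific_herb or "", "color": color,
            "size_value": float(size_value), "clamped": False,
        })
    df = pd.DataFrame(records, columns=["feature_id", "rt", "mz", "specific_herb",
                                        "color", "size_value", "clamped"])
    if len(df) and size_mode != SIZE_FIXED:
        cap = float(np.percentile(df["size_value"], _CLAMP_PERCENTILE))
        if cap > 0:
            df.loc[df["size_value"] > cap, "clamped"] = True

    fig, ax = plt.subplots(figsize=(8, 5))
    if len(df):
        values = df["size_value"].to_numpy(dtype=float)
        if size_mode == SIZE_FIXED:
            sizes = np.full(len(df), 30.0)
        else:
            cap = float(np.percentile(values, _CLAMP_PERCENTILE))
            plotted = np.minimum(values, cap) if cap > 0 else values
            top = plotted.max() if plotted.max() > 0 else 1.0
            sizes = 10.0 + 190.0 * plotted / top
        ax.scatter(df["rt"], df["mz"], s=sizes, c=df["color"],
                   edgecolors="black", linewidths=0.6, zorder=2)
        clamped = df[df["clamped"]]
        if len(clamped):
            ax.scatter(clamped["rt"], clamped["mz"], s=220.0, facecolors="none",
                       edgecolors="black", linestyles="dashed", zorder=3,
                       label="clamped (area above 99th percentile)")
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("m/z (Da)")
    ax.set_title(f"2D feature map ({spec.mode}, size: {size_mode})")
    handles = [
        plt.Line2D([], [], marker="o", linestyle="", markeredgecolor="black",
                   markerfacecolor=manifest.herb_color(h), label=h)
        for h in manifest.herb_codes
    ]
    ax.legend(handles=handles, fontsize=7, ncol=2, title="herb", loc="upper right")
    if out_path is not None:
        fig.savefig(str(out_path), metadata={"Date": None})
    return df, fig


def make_bar_chromatogram(signature: pd.DataFrame,
                          formula_profile: pd.DataFrame | None = None,
                          out_path: str | Path | None = None) -> plt.Figure:
    """Bar chromatogram of a signature: formula heights vs retention time.

    ``signature`` is the output of ``extract_signature`` (columns rt,
    height).  An optional full-profile frame (rt, height) is drawn as a pale
    context panel behind the bars.
    """
    _set_deterministic_style()
    fig, ax = plt.subplots(figsize=(8, 3))
    if formula_profile is not None and len(formula_profile):
        ax.vlines(formula_profile["rt"], 0, formula_profile["height"],
                  colors="#cccccc", linewidths=1.0, zorder=1)
    if len(signature):
        ax.vlines(signature["rt"], 0, signature["height"], colors="#d62728",
                  linewidths=2.5, zorder=2)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("feature height")
    if len(signature) and "herb" in signature.columns:
        herb = signature["herb"].iloc[0]
        cid = signature["cluster_id"].iloc[0]
        ax.set_title(f"multi-component signature: herb {herb}, cluster {cid}")
    if out_path is not None:
        fig.savefig(str(out_path), metadata={"Date": None})
    return fig


def export_ring_attributes(network: MolecularNetwork, spec: SpecificityTable,
                           features: FeatureTable, manifest: SampleManifest,
                           elsd_areas: dict[int, float] | None = None) -> pd.DataFrame:
    """Per-node attribute table for pie/ring rendering in a graph viewer.

    Columns: formula height (node size), per-herb share columns (ring
    segments, summing to 100 for any node with herb signal), specific herb,
    cluster id, and the ELSD area where assigned.
    """
    formula_sample = manifest.formula_sample
    herbs = manifest.herb_codes
    records = []
    for node in sorted(network.nodes):
        if node not in spec or node not in features:
            continue
        row = spec.get(node)
        feat = features.get(node)
        rec = {
            "feature_id": node,
            "mz": feat.mz,
            "rt": feat.rt,
            "formula_height": feat.height(formula_sample),
            "in_formula": row.in_formula,
            "specific_herb": row.specific_herb or "",
            "cluster_id": network.cluster_index.get(node, -1),
            "elsd_area": (elsd_areas or {}).get(node, float("nan")),
        }
        for h in herbs:
            rec[f"share_{h}"] = float("nan") if row.shares is None else row.shares[h]
        records.append(rec)
    return pd.DataFrame(records, columns=["feature_id", "mz", "rt", "formula_height",
                                          "in_formula", "specific_herb", "cluster_id",
                                          "elsd_area", *[f"share_{h}" for h in herbs]])
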