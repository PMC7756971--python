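"""End-to-end workflow orchestration.

``run_workflow`` wires the stages — network building, specificity,
ELSD filtering and assignment, cross-mode pairing, marker selection,
signature classification, annotation propagation, visualization — and
writes a deterministic report bundle (CSV tables, GraphML exports, SVG
figures, a summary).  Stages degrade gracefully: missing optional inputs
(ELSD table, anchors, library) skip the dependent stages with a notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import elsd as elsd_mod
from . import markers as markers_mod
from .annotation import AnchorPoint, read_anchors
from .io import (
    ElsdPeakTable,
    FeatureTable,
    SpectrumRecord,
    read_elsd_table,
    read_feature_table,
    read_mgf,
    write_network_graphml,
)
from .manifest import SampleManifest, read_manifest
from .network import MolecularNetwork, NetworkParams, build_network, network_summary
from .specificity import (
    SpecificityParams,
    SpecificityTable,
    cluster_specificity,
    compute_specificity,
    count_specific,
    count_specific_clusters,
    filter_features,
)
from .viz import export_ring_attributes, make_bar_chromatogram, make_feature_map

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.6g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class WorkflowConfig:
    """All stage parameters with their standard defaults."""

    network: NetworkParams = field(default_factory=NetworkParams)
    specificity: SpecificityParams = field(default_factory=SpecificityParams)
    elsd_min_area: float = elsd_mod.DEFAULT_MIN_AREA
    elsd_rt_tol: float = elsd_mod.DEFAULT_RT_TOL
    elsd_candidate_mode: str = elsd_mod.CANDIDATES_SPECIFIC
    pair_rt_tol: float = markers_mod.DEFAULT_PAIR_RT_TOL
    pair_ppm_tol: float = markers_mod.DEFAULT_PAIR_PPM_TOL
    insource_rt_tol: float = markers_mod.DEFAULT_INSOURCE_RT_TOL
    abundance_override_top_n: int = 0
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"network", "specificity", "elsd", "markers", "viz"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {', '.join(sorted(unknown))}")

        def _build(section: str, cls_, allowed: set[str]):
            block = raw.get(section, {}) or {}
            bad = set(block) - allowed
            if bad:
                raise ValueError(f"unknown {section} option(s): {', '.join(sorted(bad))}")
            return cls_(**block)

        net = _build("network", NetworkParams,
                     {"fragment_tol", "cosine_min", "min_matched", "top_k", "strict_matched"})
        spec = _build("specificity", SpecificityParams,
                      {"node_threshold", "cluster_threshold", "blank_rule", "blank_factor"})
        elsd_block = raw.get("elsd", {}) or {}
        markers_block = raw.get("markers", {}) or {}
        viz_block = raw.get("viz", {}) or {}
        return cls(
            network=net, specificity=spec,
            elsd_min_area=elsd_block.get("min_area", elsd_mod.DEFAULT_MIN_AREA),
            elsd_rt_tol=elsd_block.get("rt_tol", elsd_mod.DEFAULT_RT_TOL),
            elsd_candidate_mode=elsd_block.get("candidate_mode", elsd_mod.CANDIDATES_SPECIFIC),
            pair_rt_tol=markers_block.get("pair_rt_tol", markers_mod.DEFAULT_PAIR_RT_TOL),
            pair_ppm_tol=markers_block.get("pair_ppm_tol", markers_mod.DEFAULT_PAIR_PPM_TOL),
            insource_rt_tol=markers_block.get("insource_rt_tol",
                                              markers_mod.DEFAULT_INSOURCE_RT_TOL),
            abundance_override_top_n=markers_block.get("abundance_override_top_n", 0),
            make_figures=viz_block.get("make_figures", True),
        )


@dataclass
class InputBundle:
    manifest: SampleManifest
    features: dict[str, FeatureTable]
    spectra: dict[str, list[SpectrumRecord]]
    elsd: ElsdPeakTable | None = None
    anchors: dict[str, list[AnchorPoint]] = field(default_factory=dict)

    @classmethod
    def from_directory(cls, in_dir: str | Path) -> "InputBundle":
        """Load a bundle laid out as written by the simulator/CLI."""
        d = Path(in_dir)
        manifest = read_manifest(d / "manifest.csv")
        features = {}
        spectra = {}
        for mode in ("PI", "NI"):
            ft = d / f"features_{mode.lower()}.csv"
            mg = d / f"spectra_{mode.lower()}.mgf"
            if ft.exists():
                features[mode] = read_feature_table(ft, manifest, mode)
            if mg.exists():
                spectra[mode] = read_mgf(mg)
        elsd_path = d / "elsd.csv"
        elsd = read_elsd_table(elsd_path, manifest) if elsd_path.exists() else None
        anchors = {}
        for mode in ("PI", "NI"):
            ap = d / f"anchors_{mode.lower()}.csv"
            if ap.exists():
                anchors[mode] = read_anchors(ap)
        return cls(manifest, features, spectra, elsd, anchors)


@dataclass
class WorkflowResult:
    networks: dict[str, MolecularNetwork]
    spec_tables: dict[str, SpecificityTable]
    cluster_tables: dict
    markers: list
    signatures: dict[str, list]
    summary: pd.DataFrame
    out_dir: Path


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def run_workflow(config: WorkflowConfig, bundle: InputBundle,
                 out_dir: str | Path) -> WorkflowResult:
    """Execute all stages on a loaded bundle and write the report bundle.

    The outputs are a pure function of (config, bundle): rerunning into a
    fresh directory yields byte-identical CSV reports.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    modes = [m for m in ("PI", "NI") if m in bundle.features and m in bundle.spectra]
    if not modes:
        raise StageError("load", ValueError("no mode has both features and spectra"))

    networks: dict[str, MolecularNetwork] = {}
    spec_tables: dict[str, SpecificityTable] = {}
    cluster_tables = {}
    summary_rows = []

    for mode in modes:
        stage = f"network[{mode}]"
        try:
            logger.info("%s: cosine_min=%s min_matched=%s top_k=%s fragment_tol=%s",
                        stage, config.network.cosine_min, config.network.min_matched,
                        config.network.top_k, config.network.fragment_tol)
            networks[mode] = build_network(bundle.spectra[mode], config.network, mode=mode)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        stage = f"specificity[{mode}]"
        try:
            filtered = filter_features(bundle.features[mode], bundle.manifest,
                                       config.specificity)
            spec_tables[mode] = compute_specificity(filtered, bundle.manifest,
                                                    config.specificity, prefiltered=True)
            cluster_tables[mode] = cluster_specificity(spec_tables[mode], networks[mode],
                                                       config.specificity)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        counts, total, pct = count_specific(spec_tables[mode])
        ns = network_summary(networks[mode])
        n_spec_cl, pct_cl, n_nodes_cl, pct_nodes = count_specific_clusters(
            cluster_tables[mode], networks[mode])
        summary_rows.append({
            "mode": mode,
            "n_features": len(bundle.features[mode]),
            "n_formula_features": len(spec_tables[mode]),
            "n_nodes": ns.n_nodes,
            "n_clusters": ns.n_clusters,
            "n_clustered_nodes": ns.n_clustered_nodes,
            "n_singletons": ns.n_singletons,
            "n_specific_features": total,
            "n_specific_clusters": n_spec_cl,
            "pct_specific_clusters": pct_cl,
            "n_nodes_in_specific_clusters": n_nodes_cl,
            "pct_nodes_in_specific_clusters": pct_nodes,
        })

        _write_csv(spec_tables[mode].to_frame(), out / f"specificity_{mode.lower()}.csv")
        _write_csv(cluster_tables[mode].to_frame(),
                   out / f"cluster_specificity_{mode.lower()}.csv")
        per_herb = pd.DataFrame(
            [{"herb": h, "n_specific": counts[h], "pct_of_specific": pct[h]}
             for h in sorted(counts)]
        )
        _write_csv(per_herb, out / f"specific_counts_{mode.lower()}.csv")

        ring = export_ring_attributes(networks[mode], spec_tables[mode],
                                      bundle.features[mode], bundle.manifest)
        _write_csv(ring, out / f"ring_attributes_{mode.lower()}.csv")
        attrs = {
            int(r["feature_id"]): {
                k: r[k] for k in ring.columns
                if k != "feature_id"
                and not (isinstance(r[k], float) and pd.isna(r[k]))
            }
            for _, r in ring.iterrows()
        }
        write_network_graphml(networks[mode], attrs, out / f"network_{mode.lower()}.graphml")

    # ---- ELSD / markers ----------------------------------------------------
    markers_list: list = []
    assignments = []
    if bundle.elsd is not None:
        stage = "elsd"
        try:
            filtered_elsd = elsd_mod.filter_elsd_peaks(bundle.elsd, config.elsd_min_area)
            labeled = elsd_mod.label_peaks(filtered_elsd)
            assignments = elsd_mod.match_elsd_to_features(
                labeled,
                bundle.features.get("PI"), spec_tables.get("PI"),
                bundle.features.get("NI"), spec_tables.get("NI"),
                bundle.manifest, rt_tol=config.elsd_rt_tol,
                candidate_mode=config.elsd_candidate_mode,
            )
            _write_csv(elsd_mod.assignments_frame(assignments), out / "elsd_assignments.csv")
        except Exception as exc:
            raise StageError(stage, exc) from exc

        stage = "markers"
        try:
            if len(modes) == 2:
                pairs = markers_mod.pair_cross_mode(
                    bundle.features["PI"], spec_tables["PI"],
                    bundle.features["NI"], spec_tables["NI"],
                    rt_tol=config.pair_rt_tol, ppm_tol=config.pair_ppm_tol)
                pairs_df = pd.DataFrame(
                    [{"feature_id_pi": p.feature_id_pi, "feature_id_ni": p.feature_id_ni,
                      "rt_delta": p.rt_delta, "mass_delta_ppm": p.neutral_mass_delta_ppm}
                     for p in pairs]
                )
                _write_csv(pairs_df, out / "cross_mode_pairs.csv")
            markers_list = markers_mod.select_markers(
                assignments, spec_tables.get("PI"), spec_tables.get("NI"),
                config.specificity,
                abundance_override_top_n=config.abundance_override_top_n)
            _write_csv(markers_mod.markers_frame(markers_list), out / "markers.csv")
        except Exception as exc:
            raise StageError(stage, exc) from exc
    else:
        logger.info("no ELSD table: marker stage skipped")

    # ---- signatures --------------------------------------------------------
    signatures: dict[str, list] = {}
    signature_frames = []
    for mode in modes:
        anchors = bundle.anchors.get(mode, [])
        if not anchors:
            continue
        stage = f"signatures[{mode}]"
        try:
            sigs = markers_mod.classify_signature_clusters(
                cluster_tables[mode], networks[mode], anchors, spec_tables[mode],
                params=config.specificity)
            signatures[mode] = sigs
            for s in sigs:
                df = markers_mod.extract_signature(
                    s, spec_tables[mode], bundle.features[mode], bundle.manifest,
                    insource_rt_tol=config.insource_rt_tol)
                df.insert(0, "mode", mode)
                signature_frames.append(df)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    if signature_frames:
        _write_csv(pd.concat(signature_frames, ignore_index=True), out / "signatures.csv")

    # ---- figures -----------------------------------------------------------
    if config.make_figures:
        stage = "viz"
        try:
            import matplotlib.pyplot as plt

            areas = elsd_mod.assign_areas(assignments) if assignments else {"PI": {}, "NI": {}}
            for mode in modes:
                df_map, fig = make_feature_map(
                    spec_tables[mode], bundle.features[mode], bundle.manifest,
                    size_mode="height",
                    out_path=out / f"feature_map_{mode.lower()}.svg")
                _write_csv(df_map, out / f"feature_map_{mode.lower()}.csv")
                plt.close(fig)
                if areas.get(mode):
                    df_map, fig = make_feature_map(
                        spec_tables[mode], bundle.features[mode], bundle.manifest,
                        size_mode="elsd", elsd_areas=areas[mode],
                        out_path=out / f"feature_map_elsd_{mode.lower()}.svg")
                    _write_csv(df_map, out / f"feature_map_elsd_{mode.lower()}.csv")
                    plt.close(fig)
            for mode, sigs in signatures.items():
                for s in sigs[:3]:   # a few exemplar bar chromatograms
                    df = markers_mod.extract_signature(
                        s, spec_tables[mode], bundle.features[mode], bundle.manifest,
                        insource_rt_tol=config.insource_rt_tol)
                    fig = make_bar_chromatogram(
                        df, out_path=out / f"signature_{mode.lower()}_c{s.cluster_id}.svg")
                    plt.close(fig)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    summary = pd.DataFrame(summary_rows)
    _write_csv(summary, out / "summary.csv")
    manifest_lines = sorted(p.name for p in out.iterdir() if p.is_file())
    (out / "outputs.txt").write_text("\n".join(manifest_lines) + "\n")
    return WorkflowResult(networks, spec_tables, cluster_tables, markers_list,
                          signatures, summary, out)
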