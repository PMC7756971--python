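"""Readers and writers for the workflow's external formats.

Aligned feature quantification tables (CSV, GNPS/MZmine dialect), MS/MS
spectra (MGF via pyteomics), ELSD peak tables (CSV) and molecular-network
export (GraphML via networkx).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .manifest import SampleManifest

logger = logging.getLogger(__name__)

PI = "PI"
NI = "NI"
MODES = (PI, NI)


class FormatError(ValueError):
    """Malformed input file (missing columns, unparsable block)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureRecord:
    """One aligned LC-MS feature: m/z (Da), RT (min), per-sample peak heights."""

    feature_id: int
    mz: float
    rt: float
    heights: dict[str, float] = field(default_factory=dict)

    def height(self, sample_id: str) -> float:
        return self.heights.get(sample_id, 0.0)


@dataclass
class FeatureTable:
    """All aligned features of one ionization mode."""

    mode: str
    records: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        ids = [r.feature_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate feature ids in table")
        for r in self.records:
            if r.mz <= 0:
                raise ValidationError(f"feature {r.feature_id}: m/z must be > 0")
            if r.rt < 0:
                raise ValidationError(f"feature {r.feature_id}: RT must be >= 0")
            if any(h < 0 for h in r.heights.values()):
                raise ValidationError(f"feature {r.feature_id}: negative height")
        self._by_id = {r.feature_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, feature_id: int) -> bool:
        return feature_id in self._by_id

    def get(self, feature_id: int) -> FeatureRecord:
        return self._by_id[feature_id]

    def feature_ids(self) -> list[int]:
        return [r.feature_id for r in self.records]

    def subset(self, feature_ids) -> "FeatureTable":
        keep = set(feature_ids)
        return FeatureTable(self.mode, [r for r in self.records if r.feature_id in keep])

    def to_frame(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        if sample_ids is None:
            seen: dict[str, None] = {}
            for r in self.records:
                for s in r.heights:
                    seen.setdefault(s)
            sample_ids = list(seen)
        rows = [
            {"feature_id": r.feature_id, "mz": r.mz, "rt": r.rt,
             **{s: r.height(s) for s in sample_ids}}
            for r in sorted(self.records, key=lambda r: r.feature_id)
        ]
        return pd.DataFrame(rows, columns=["feature_id", "mz", "rt", *sample_ids])


# GNPS dialect: "row ID", "row m/z", "row retention time", "<sample> Peak height"
_GNPS_ID = re.compile(r"^row id$", re.I)
_GNPS_MZ = re.compile(r"^row m/z$", re.I)
_GNPS_RT = re.compile(r"^row retention time$", re.I)
_GNPS_HEIGHT = re.compile(r"^(?P<sample>.+?)(?:\.mzx?ml)?\s+peak\s+height$", re.I)


def _sniff_columns(cols: list[str]) -> tuple[str, str, str, dict[str, str]]:
    """Return (id_col, mz_col, rt_col, {column -> sample_id})."""
    stripped = {c: c.strip() for c in cols}
    id_col = mz_col = rt_col = None
    heights: dict[str, str] = {}
    gnps = any(_GNPS_ID.match(s) for s in stripped.values())
    for col, s in stripped.items():
        if gnps:
            if _GNPS_ID.match(s):
                id_col = col
            elif _GNPS_MZ.match(s):
                mz_col = col
            elif _GNPS_RT.match(s):
                rt_col = col
            else:
                m = _GNPS_HEIGHT.match(s)
                if m:
                    heights[col] = m.group("sample").strip()
        else:
            low = s.lower()
            if low in {"id", "feature_id", "feature id"}:
                id_col = col
            elif low in {"mz", "m/z"}:
                mz_col = col
            elif low in {"rt", "retention time", "retention_time"}:
                rt_col = col
            else:
                heights[col] = s
    missing = [n for n, c in (("feature id", id_col), ("m/z", mz_col), ("RT", rt_col)) if c is None]
    if missing:
        raise FormatError(f"quantification table is missing column(s): {', '.join(missing)}")
    return id_col, mz_col, rt_col, heights


def read_feature_table(path: str | Path, manifest: SampleManifest, mode: str) -> FeatureTable:
    """Read an aligned quantification table (GNPS or plain dialect).

    Height columns for samples absent from the manifest are ignored with a
    warning; manifest samples without a column read as all-zero heights.
    Empty cells read as 0 (feature not detected in that run).
    """
    df = pd.read_csv(path)
    id_col, mz_col, rt_col, height_cols = _sniff_columns(list(df.columns))
    known = set(manifest.sample_ids)
    unknown = [s for s in height_cols.values() if s not in known]
    if unknown:
        logger.warning(
            "ignoring %d height column(s) for samples not in manifest: %s",
            len(unknown), ", ".join(sorted(unknown)),
        )
    records = []
    for _, row in df.iterrows():
        heights = {
            sample: float(row[col]) if pd.notna(row[col]) else 0.0
            for col, sample in height_cols.items()
            if sample in known
        }
        for sample in known:
            heights.setdefault(sample, 0.0)
        records.append(
            FeatureRecord(
                feature_id=int(row[id_col]),
                mz=float(row[mz_col]),
                rt=float(row[rt_col]),
                heights=heights,
            )
        )
    return FeatureTable(mode, records)


def write_feature_table(table: FeatureTable, manifest: SampleManifest, path: str | Path) -> None:
    """Write a table in the plain ``id,mz,rt,<sample>...`` dialect."""
    df = table.to_frame(manifest.sample_ids)
    df = df.rename(columns={"feature_id": "id"})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumRecord:
    """An MS/MS spectrum keyed to a feature id.

    ``peaks`` is an (n, 2) float array of (fragment m/z, intensity), sorted by
    m/z ascending with strictly positive intensities.
    """

    feature_id: int
    precursor_mz: float
    charge: int
    peaks: np.ndarray

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        keep = peaks[:, 1] > 0
        peaks = peaks[keep]
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]
        if self.precursor_mz <= 0:
            raise ValidationError(f"feature {self.feature_id}: precursor_mz must be > 0")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read MGF spectra; blocks are keyed by FEATURE_ID or SCANS."""
    records = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, block in enumerate(reader):
            params = block["params"]
            fid = params.get("feature_id", params.get("scans"))
            if fid is None:
                raise FormatError(f"MGF block {i}: no FEATURE_ID or SCANS field")
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise FormatError(f"MGF block {i}: no PEPMASS")
            prec = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            if charge:
                ch = int(charge[0])
            else:
                ch = 1
            peaks = np.column_stack([block["m/z array"], block["intensity array"]])
            records.append(SpectrumRecord(int(fid), prec, ch, peaks))
    return records


def write_mgf(spectra: list[SpectrumRecord], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
                "params": {
                    "feature_id": s.feature_id,
                    "pepmass": s.precursor_mz,
                    "charge": s.charge,
                    "scans": s.feature_id,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# ELSD peak tables
# ---------------------------------------------------------------------------

@dataclass
class ElsdPeakTable:
    """ELSD peaks of the single-herb traces: (herb_code, rt, area, label)."""

    rows: pd.DataFrame

    COLUMNS = ("herb_code", "rt", "area", "label")

    def __post_init__(self) -> None:
        df = self.rows.copy()
        for col in ("herb_code", "rt", "area"):
            if col not in df.columns:
                raise FormatError(f"ELSD table missing column {col!r}")
        if "label" not in df.columns:
            df["label"] = ""
        df["label"] = df["label"].fillna("")
        if (df["area"] < 0).any():
            raise ValidationError("ELSD areas must be >= 0")
        self.rows = df[list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)


def read_elsd_table(path: str | Path, manifest: SampleManifest) -> ElsdPeakTable:
    """Read an ELSD peak CSV with columns herb, rt, area (label optional)."""
    df = pd.read_csv(path)
    if df.empty and not set(df.columns) & {"herb", "herb_code"}:
        df = pd.DataFrame(columns=["herb_code", "rt", "area", "label"])
    df = df.rename(columns={"herb": "herb_code"})
    table = ElsdPeakTable(df)
    known = set(manifest.herb_codes)
    bad = sorted(set(table.rows["herb_code"]) - known)
    if bad:
        raise ValidationError(f"ELSD table references unknown herb code(s): {', '.join(map(str, bad))}")
    return table


def write_elsd_table(table: ElsdPeakTable, path: str | Path) -> None:
    table.rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GraphML export
# ---------------------------------------------------------------------------

def write_network_graphml(network, attrs: dict[int, dict] | None, path: str | Path) -> None:
    """Export a molecular network with per-node attributes to GraphML.

    ``attrs`` maps feature_id to extra attribute dicts (m/z, rt, heights,
    specificity shares, annotations ...).  Non-finite values serialize as an
    empty string with a warning, since GraphML has no NaN representation.
    """
    g = nx.Graph()
    g.graph["mode"] = network.mode
    for node in network.nodes:
        node_attrs = {"cluster_id": int(network.cluster_index.get(node, -1))}
        for key, value in (attrs or {}).get(node, {}).items():
            if isinstance(value, float) and not math.isfinite(value):
                logger.warning("node %s attribute %s is non-finite; exporting empty", node, key)
                value = ""
            if isinstance(value, (np.integer,)):
                value = int(value)
            elif isinstance(value, (np.floating,)):
                value = float(value)
            node_attrs[key] = value
        g.add_node(int(node), **node_attrs)
    for edge in network.edges:
        g.add_edge(int(edge.node_a), int(edge.node_b),
                   cosine=float(edge.cosine), matched_peaks=int(edge.matched_peaks))
    nx.write_graphml(g, str(path))


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path), node_type=int)
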