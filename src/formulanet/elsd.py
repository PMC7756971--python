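"""ELSD semi-quantitative filtering and attachment of areas to HRMS features.

ELSD response tracks analyte mass rather than ionization efficiency, so the
per-herb peak areas rank component abundance independently of the MS signal.
Peaks passing the area floor are labeled herb-code + rank (largest area =
rank 1) and matched to aligned HRMS features by retention time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ElsdPeakTable, FeatureTable
from .manifest import SampleManifest
from .specificity import SpecificityTable

DEFAULT_MIN_AREA = 0.004   # uV/s, inclusive floor
DEFAULT_RT_TOL = 0.1       # min, ELSD-to-HRMS retention-time tolerance

CANDIDATES_SPECIFIC = "specific"
CANDIDATES_ALL = "all"


class ConflictError(ValueError):
    """Two ELSD peaks resolved to the same HRMS feature."""


@dataclass
class ElsdAssignment:
    """One labeled ELSD peak and the HRMS feature(s) it was assigned to."""

    elsd_label: str
    herb_code: str
    rt_elsd: float
    area: float
    feature_id_pi: int | None = None
    feature_id_ni: int | None = None
    match_quality_pi: float | None = None   # signed RT offset, min
    match_quality_ni: float | None = None

    @property
    def matched(self) -> bool:
        return self.feature_id_pi is not None or self.feature_id_ni is not None


def filter_elsd_peaks(table: ElsdPeakTable, min_area: float = DEFAULT_MIN_AREA) -> ElsdPeakTable:
    """Keep peaks with area >= min_area (inclusive)."""
    return ElsdPeakTable(table.rows[table.rows["area"] >= min_area].reset_index(drop=True))


def label_peaks(table: ElsdPeakTable) -> ElsdPeakTable:
    """Label peaks herb-code + area rank (1 = largest area; RT breaks ties)."""
    df = table.rows.copy()
    labels = pd.Series([""] * len(df), index=df.index, dtype=object)
    for herb, group in df.groupby("herb_code"):
        order = group.sort_values(["area", "rt"], ascending=[False, True]).index
        for rank, idx in enumerate(order, start=1):
            labels[idx] = f"{herb}{rank}"
    df["label"] = labels
    return ElsdPeakTable(df)


def _assign_mode(row, features: FeatureTable, spec: SpecificityTable,
                 rt_tol: float, candidate_mode: str,
                 herb_sample: str, nominal_mz: float | None):
    """Best candidate feature for one ELSD peak in one mode, or None."""
    candidates = []
    for fid in spec._by_id:
        srow = spec.get(fid)
        if not srow.in_formula or fid not in features:
            continue
        if candidate_mode == CANDIDATES_SPECIFIC and srow.specific_herb != row["herb_code"]:
            continue
        feat = features.get(fid)
        if abs(feat.rt - row["rt"]) > rt_tol:
            continue
        if nominal_mz is not None and abs(round(feat.mz) - nominal_mz) > 0.5:
            continue
        candidates.append(feat)
    if not candidates:
        return None, None
    best = max(candidates, key=lambda f: (f.height(herb_sample), -f.feature_id))
    return best.feature_id, best.rt - row["rt"]


def match_elsd_to_features(elsd: ElsdPeakTable,
                           features_pi: FeatureTable | None,
                           spec_pi: SpecificityTable | None,
                           features_ni: FeatureTable | None,
                           spec_ni: SpecificityTable | None,
                           manifest: SampleManifest,
                           rt_tol: float = DEFAULT_RT_TOL,
                           candidate_mode: str = CANDIDATES_SPECIFIC,
                           nominal_mz: dict[str, float] | None = None,
                           overrides: dict[str, dict[str, int]] | None = None
                           ) -> list[ElsdAssignment]:
    """Assign each labeled ELSD peak to HRMS features per ionization mode.

    Candidates are the herb's specific features (or all formula features with
    ``candidate_mode="all"``) within ``rt_tol``; the candidate with the
    highest height in the source herb wins, ties by lower feature id.  An
    optional ``nominal_mz`` map (label -> QMS m/z) restricts candidates to
    features whose m/z rounds to it within 0.5 Da.  ``overrides`` maps label
    to {"PI": fid, "NI": fid} and always wins (manual curation).
    Unmatched peaks carry empty assignments; they are an outcome, not an
    error ("not detected in the formula").
    """
    if candidate_mode not in (CANDIDATES_SPECIFIC, CANDIDATES_ALL):
        raise ValueError(f"unknown candidate_mode {candidate_mode!r}")
    assignments = []
    herb_samples = manifest.herb_samples
    for _, row in elsd.rows.iterrows():
        label = row["label"] or f"{row['herb_code']}?"
        qms = (nominal_mz or {}).get(label)
        assignment = ElsdAssignment(label, row["herb_code"], float(row["rt"]), float(row["area"]))
        forced = (overrides or {}).get(label, {})
        for mode, features, spec in (("PI", features_pi, spec_pi), ("NI", features_ni, spec_ni)):
            if features is None or spec is None:
                continue
            if mode in forced:
                fid = forced[mode]
                offset = features.get(fid).rt - row["rt"] if fid in features else None
            else:
                fid, offset = _assign_mode(row, features, spec, rt_tol, candidate_mode,
                                           herb_samples[row["herb_code"]], qms)
            if mode == "PI":
                assignment.feature_id_pi, assignment.match_quality_pi = fid, offset
            else:
                assignment.feature_id_ni, assignment.match_quality_ni = fid, offset
        assignments.append(assignment)
    return assignments


def assign_areas(assignments: list[ElsdAssignment]) -> dict[str, dict[int, float]]:
    """Per-mode mapping feature_id -> ELSD area for plotting and ranking.

    Two ELSD peaks resolving to one feature is a conflict (the feature's area
    would be ambiguous) and raises, listing both labels.
    """
    out: dict[str, dict[int, float]] = {"PI": {}, "NI": {}}
    owner: dict[tuple[str, int], str] = {}
    for a in assignments:
        for mode, fid in (("PI", a.feature_id_pi), ("NI", a.feature_id_ni)):
            if fid is None:
                continue
            key = (mode, fid)
            if key in owner:
                raise ConflictError(
                    f"feature {fid} ({mode}) claimed by ELSD peaks "
                    f"{owner[key]} and {a.elsd_label}"
                )
            owner[key] = a.elsd_label
            out[mode][fid] = a.area
    return out


def assignments_frame(assignments: list[ElsdAssignment]) -> pd.DataFrame:
    recs = [
        {
            "elsd_label": a.elsd_label, "herb_code": a.herb_code,
            "rt_elsd": a.rt_elsd, "area": a.area,
            "feature_id_pi": "" if a.feature_id_pi is None else a.feature_id_pi,
            "feature_id_ni": "" if a.feature_id_ni is None else a.feature_id_ni,
            "rt_offset_pi": "" if a.match_quality_pi is None else round(a.match_quality_pi, 6),
            "rt_offset_ni": "" if a.match_quality_ni is None else round(a.match_quality_ni, 6),
            "matched": a.matched,
        }
        for a in assignments
    ]
    return pd.DataFrame(recs, columns=["elsd_label", "herb_code", "rt_elsd", "area",
                                       "feature_id_pi", "feature_id_ni",
                                       "rt_offset_pi", "rt_offset_ni", "matched"])
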