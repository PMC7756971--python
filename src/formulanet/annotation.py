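"""Feature annotation: molecular formulae, spectral-library matching,
chemotaxonomic re-ranking, and anchor-based propagation within clusters.

Formula assignment enumerates CHNO compositions within element bounds whose
monoisotopic mass falls inside a ppm window of the neutral mass, subject to
ring-and-double-bond-equivalent (RDBE) constraints.  Library matching scores
the query against candidate entries with the same modified cosine used for
networking; candidates are then re-sorted by chemotaxonomic plausibility
(structures reported for the species beat genus beat family) and, inside a
cluster holding a formally identified anchor compound, candidates of the
anchor's compound class are promoted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

from pyteomics import mass as _pmass

from .io import SpectrumRecord, read_mgf
from .network import MolecularNetwork, modified_cosine

PROTON = 1.007276

# monoisotopic atomic masses (NIST via pyteomics)
M_C = _pmass.nist_mass["C"][0][0]
M_H = _pmass.nist_mass["H"][0][0]
M_N = _pmass.nist_mass["N"][0][0]
M_O = _pmass.nist_mass["O"][0][0]


@dataclass(frozen=True)
class ElementBounds:
    """Search-space limits for formula assignment (counts inclusive)."""

    c_max: int = 60
    h_max: int = 120
    n_max: int = 10
    o_max: int = 30
    rdbe_min: float = 0.0
    rdbe_max: float = 40.0


@dataclass(frozen=True)
class FormulaCandidate:
    formula: str
    mass: float
    ppm_error: float
    rdbe: float


@dataclass
class LibraryEntry:
    entry_id: str
    name: str
    molecular_formula: str
    monoisotopic_mass: float
    species: str = ""
    genus: str = ""
    family: str = ""
    compound_class: str = ""
    adduct: str = ""
    spectrum: SpectrumRecord | None = None


@dataclass
class AnnotationCandidate:
    feature_id: int
    entry_id: str
    name: str
    cosine: float
    rank: int
    taxon_level: str = "none"     # species | genus | family | none
    class_match: bool = False
    compound_class: str = ""


@dataclass(frozen=True)
class AnchorPoint:
    """A formally identified node (isolation + NMR, or pure-standard match)."""

    feature_id: int
    name: str
    molecular_formula: str
    herb_code: str
    compound_class: str


@dataclass
class HerbTaxonomy:
    species: str = ""
    genus: str = ""
    family: str = ""


# ---------------------------------------------------------------------------
# molecular formula assignment
# ---------------------------------------------------------------------------

def formula_mass(c: int, h: int, n: int, o: int) -> float:
    return c * M_C + h * M_H + n * M_N + o * M_O


def _formula_string(c: int, h: int, n: int, o: int) -> str:
    parts = []
    for sym, count in (("C", c), ("H", h), ("N", n), ("O", o)):
        if count == 1:
            parts.append(sym)
        elif count > 1:
            parts.append(f"{sym}{count}")
    return "".join(parts)


def rdbe(c: int, h: int, n: int) -> float:
    return c - h / 2.0 + n / 2.0 + 1.0


def neutral_mass(precursor_mz: float, mode: str) -> float:
    """Neutral monoisotopic mass from the default adduct of a mode.

    [M+H]+ in PI and [M-H]- in NI.
    """
    if mode == "PI":
        return precursor_mz - PROTON
    if mode == "NI":
        return precursor_mz + PROTON
    raise ValueError(f"unknown mode {mode!r}")


def assign_molecular_formula(target_mass: float, ppm_tol: float = 5.0,
                             bounds: ElementBounds | None = None
                             ) -> list[FormulaCandidate]:
    """All CHNO formulae within a ppm window of a neutral mass, ranked by
    absolute mass error.

    Only integer, non-negative RDBE values in the configured range are kept
    (even-electron neutral molecules).  An empty window returns an empty
    list, not an error.
    """
    bounds = bounds or ElementBounds()
    tol = target_mass * ppm_tol * 1e-6
    out = []
    for c in range(0, bounds.c_max + 1):
        mass_c = c * M_C
        if mass_c - tol > target_mass:
            break
        for n in range(0, bounds.n_max + 1):
            mass_cn = mass_c + n * M_N
            if mass_cn - tol > target_mass:
                break
            for o in range(0, bounds.o_max + 1):
                mass_cno = mass_cn + o * M_O
                if mass_cno - tol > target_mass:
                    break
                rem = target_mass - mass_cno
                h_lo = max(0, int((rem - tol) / M_H))
                h_hi = min(bounds.h_max, int((rem + tol) / M_H) + 1)
                for h in range(h_lo, h_hi + 1):
                    m = mass_cno + h * M_H
                    if abs(m - target_mass) > tol:
                        continue
                    r = rdbe(c, h, n)
                    if not bounds.rdbe_min <= r <= bounds.rdbe_max:
                        continue
                    if abs(r - round(r)) > 1e-9:
                        continue   # half-integer RDBE: odd-electron composition
                    ppm = (m - target_mass) / target_mass * 1e6
                    out.append(FormulaCandidate(_formula_string(c, h, n, o), m, ppm, r))
    out.sort(key=lambda f: (abs(f.ppm_error), f.formula))
    return out


# ---------------------------------------------------------------------------
# library matching and re-ranking
# ---------------------------------------------------------------------------

def read_library(mgf_path: str | Path, sidecar_csv: str | Path) -> list[LibraryEntry]:
    """Load a spectral library: MGF spectra plus a CSV sidecar of metadata.

    Sidecar columns: entry_id, name, molecular_formula, monoisotopic_mass,
    species, genus, family, compound_class, adduct, feature_id (key into the
    MGF's FEATURE_ID/SCANS field).
    """
    spectra = {s.feature_id: s for s in read_mgf(mgf_path)}
    entries = []
    with open(sidecar_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                LibraryEntry(
                    entry_id=row["entry_id"],
                    name=row.get("name", ""),
                    molecular_formula=row.get("molecular_formula", ""),
                    monoisotopic_mass=float(row["monoisotopic_mass"]),
                    species=row.get("species", ""),
                    genus=row.get("genus", ""),
                    family=row.get("family", ""),
                    compound_class=row.get("compound_class", ""),
                    adduct=row.get("adduct", ""),
                    spectrum=spectra.get(int(row["feature_id"])) if row.get("feature_id") else None,
                )
            )
    return entries


def _entry_precursor(entry: LibraryEntry, mode: str) -> float:
    if entry.spectrum is not None:
        return entry.spectrum.precursor_mz
    return entry.monoisotopic_mass + (PROTON if mode == "PI" else -PROTON)


def match_library(spec: SpectrumRecord, library: list[LibraryEntry], mode: str = "PI",
                  mz_tol: float = 0.005, cosine_min: float = 0.2, top_n: int = 6
                  ) -> list[AnnotationCandidate]:
    """Top-N spectral-library candidates for one query spectrum.

    Entries are pre-filtered on precursor (adduct) mass within ``mz_tol`` Da,
    scored by modified cosine at the same tolerance, floored at
    ``cosine_min``, and ranked by descending score (ties by entry id).
    """
    scored = []
    for entry in library:
        if entry.spectrum is None:
            continue
        if abs(_entry_precursor(entry, mode) - spec.precursor_mz) > mz_tol:
            continue
        cos, _ = modified_cosine(spec, entry.spectrum, fragment_tol=mz_tol)
        if cos >= cosine_min:
            scored.append((cos, entry))
    scored.sort(key=lambda t: (-t[0], t[1].entry_id))
    return [
        AnnotationCandidate(
            feature_id=spec.feature_id, entry_id=e.entry_id, name=e.name,
            cosine=cos, rank=r, compound_class=e.compound_class,
        )
        for r, (cos, e) in enumerate(scored[:top_n], start=1)
    ]


_TAXON_PRIORITY = {"species": 0, "genus": 1, "family": 2, "none": 3}


def _taxon_level(entry: LibraryEntry, taxonomy: HerbTaxonomy) -> str:
    if taxonomy.species and entry.species == taxonomy.species:
        return "species"
    if taxonomy.genus and entry.genus == taxonomy.genus:
        return "genus"
    if taxonomy.family and entry.family == taxonomy.family:
        return "family"
    return "none"


def taxonomic_rerank(cands: list[AnnotationCandidate], library: list[LibraryEntry],
                     taxonomy: HerbTaxonomy | None) -> list[AnnotationCandidate]:
    """Stable re-sort: species > genus > family > none, then cosine descending.

    A feature without a specific herb (``taxonomy`` None) is a no-op.  The
    result is a permutation of the input with updated ranks and taxon levels;
    cosine values are untouched.
    """
    by_id = {e.entry_id: e for e in library}
    if taxonomy is None:
        return list(cands)
    tagged = [
        replace(c, taxon_level=_taxon_level(by_id[c.entry_id], taxonomy))
        for c in cands
    ]
    tagged.sort(key=lambda c: (_TAXON_PRIORITY[c.taxon_level], -c.cosine))
    return [replace(c, rank=r) for r, c in enumerate(tagged, start=1)]


@dataclass
class CoMarker:
    feature_id: int
    label: str                 # Co-<anchor>-k, numbered by RT ascending
    anchor: AnchorPoint
    candidates: list[AnnotationCandidate] = field(default_factory=list)


def propagate_from_anchor(network: MolecularNetwork, cluster_id: int,
                          anchors: list[AnchorPoint],
                          candidates: dict[int, list[AnnotationCandidate]],
                          library: list[LibraryEntry],
                          rts: dict[int, float],
                          taxonomy: HerbTaxonomy | None = None
                          ) -> list[CoMarker]:
    """Propagate an anchor's identity to its cluster co-members.

    For each non-anchor member, candidates whose compound class equals an
    anchor's class are promoted ahead of the rest; within each group the
    chemotaxonomic order applies.  Members are labeled ``Co-<anchor>-k`` by
    ascending retention time.  A cluster without an anchor is a no-op.
    """
    members = network.cluster_members(cluster_id)
    cluster_anchors = [a for a in anchors if a.feature_id in members]
    if not cluster_anchors:
        return []
    anchor = cluster_anchors[0]
    anchor_classes = {a.compound_class for a in cluster_anchors if a.compound_class}
    others = [m for m in members if m not in {a.feature_id for a in cluster_anchors}]
    others.sort(key=lambda m: (rts.get(m, float("inf")), m))
    out = []
    for k, member in enumerate(others, start=1):
        cands = taxonomic_rerank(candidates.get(member, []), library, taxonomy)
        promoted = [c for c in cands if c.compound_class in anchor_classes]
        rest = [c for c in cands if c.compound_class not in anchor_classes]
        merged = [
            replace(c, rank=r, class_match=c.compound_class in anchor_classes)
            for r, c in enumerate(promoted + rest, start=1)
        ]
        out.append(CoMarker(member, f"Co-{anchor.name or anchor.herb_code}-{k}",
                            anchor, merged))
    return out


def read_anchors(path: str | Path) -> list[AnchorPoint]:
    """Anchors CSV: feature_id, name, formula, class, herb."""
    anchors = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            anchors.append(
                AnchorPoint(
                    feature_id=int(row["feature_id"]),
                    name=row.get("name", ""),
                    molecular_formula=row.get("formula", row.get("molecular_formula", "")),
                    herb_code=row.get("herb", row.get("herb_code", "")),
                    compound_class=row.get("class", row.get("compound_class", "")),
                )
            )
    return anchors
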