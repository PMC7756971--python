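"""A small built-in spectral library for demonstrations and tests.

Forty entries covering well-known markers of the ten herbs (baicalin,
astilbin, rosmarinic acid, oxymatrine, E-piceid, isovitexin, ...) with
their molecular formulae, compound classes and taxonomic assignments, plus
synthetic analogue entries at genus or family level.  Spectra are synthetic:
deterministic fragment patterns generated per entry (the library carries no
measured data).
"""

from __future__ import annotations

import numpy as np
from pyteomics import mass as _pmass

from .annotation import PROTON, LibraryEntry
from .io import SpectrumRecord

# name, formula, compound class, herb species/genus/family
_MARKERS = [
    ("Ligustilide", "C12H14O2", "isobenzofuran",
     ("Angelica sinensis", "Angelica", "Apiaceae")),
    ("1,3-Dicaffeoyl-epi-quinic acid", "C25H24O12", "caffeoylquinic acid",
     ("Chrysanthemum indicum", "Chrysanthemum", "Asteraceae")),
    ("Cosmosiin", "C21H20O10", "flavone O-glucoside",
     ("Chrysanthemum indicum", "Chrysanthemum", "Asteraceae")),
    ("6''-Malonylcosmosiin", "C24H22O13", "flavone O-glucoside",
     ("Chrysanthemum indicum", "Chrysanthemum", "Asteraceae")),
    ("Uralsaponin A", "C42H62O16", "oleanane triterpenoid",
     ("Glycyrrhiza uralensis", "Glycyrrhiza", "Fabaceae")),
    ("Liquiritin apioside", "C26H30O13", "flavanone",
     ("Glycyrrhiza uralensis", "Glycyrrhiza", "Fabaceae")),
    ("Isovitexin", "C21H20O10", "flavone C-glucoside",
     ("Isatis tinctoria", "Isatis", "Brassicaceae")),
    ("10-O-p-cis-Coumaroyl scandoside methyl ester", "C26H30O13", "scandoside",
     ("Oldenlandia diffusa", "Oldenlandia", "Rubiaceae")),
    ("E-piceid", "C20H22O8", "stilbene",
     ("Polygonum cuspidatum", "Polygonum", "Polygonaceae")),
    ("Emodin-8-O-glucoside", "C21H20O10", "anthraquinone",
     ("Polygonum cuspidatum", "Polygonum", "Polygonaceae")),
    ("Rosmarinic acid", "C18H16O8", "rosmarinic lignan",
     ("Prunella vulgaris", "Prunella", "Lamiaceae")),
    ("Baicalin", "C21H18O11", "flavone O-glucuronide",
     ("Scutellaria baicalensis", "Scutellaria", "Lamiaceae")),
    ("Wogonoside", "C22H20O11", "flavone O-glucuronide",
     ("Scutellaria baicalensis", "Scutellaria", "Lamiaceae")),
    ("Oroxyloside", "C22H20O11", "flavone O-glucuronide",
     ("Scutellaria baicalensis", "Scutellaria", "Lamiaceae")),
    ("Astilbin", "C21H22O11", "flavanone",
     ("Smilax glabra", "Smilax", "Smilacaceae")),
    ("Oxymatrine", "C15H24N2O2", "quinolizidine alkaloid",
     ("Sophora flavescens", "Sophora", "Fabaceae")),
]

# synthetic analogues: formula delta (as a composition shift), taxon depth
_ANALOGUE_SHIFTS = [("CH2", "genus"), ("O", "family"), ("C2H4", "none")]
_SHIFT_MASS = {"CH2": 14.01565, "O": 15.994915, "C2H4": 28.0313}


def _synthetic_spectrum(entry_idx: int, precursor: float, charge: int) -> SpectrumRecord:
    rng = np.random.default_rng(10_000 + entry_idx)
    n = 8
    mzs = np.sort(rng.uniform(60.0, max(80.0, precursor - 20.0), size=n))
    intensities = rng.uniform(20.0, 100.0, size=n)
    return SpectrumRecord(entry_idx, precursor, charge, np.column_stack([mzs, intensities]))


def toy_library(mode: str = "PI") -> list[LibraryEntry]:
    """Build the 40-entry library for one ionization mode.

    Deterministic: spectra are seeded per entry.  Analogue entries reuse the
    parent's class with shifted formula/mass and shallower taxon assignment.
    """
    charge = 1 if mode == "PI" else -1
    entries: list[LibraryEntry] = []
    idx = 0
    for name, formula, cls, (species, genus, family) in _MARKERS:
        m = _pmass.calculate_mass(formula=formula)
        precursor = m + PROTON if mode == "PI" else m - PROTON
        idx += 1
        entries.append(LibraryEntry(
            entry_id=f"TL{idx:03d}", name=name, molecular_formula=formula,
            monoisotopic_mass=m, species=species, genus=genus, family=family,
            compound_class=cls, adduct="[M+H]+" if mode == "PI" else "[M-H]-",
            spectrum=_synthetic_spectrum(idx, precursor, charge),
        ))
    # pad to 40 with analogues of the first markers
    base_i = 0
    while len(entries) < 40:
        name, formula, cls, (species, genus, family) = _MARKERS[base_i % len(_MARKERS)]
        shift, depth = _ANALOGUE_SHIFTS[(len(entries) - len(_MARKERS)) % len(_ANALOGUE_SHIFTS)]
        m = _pmass.calculate_mass(formula=formula) + _SHIFT_MASS[shift]
        precursor = m + PROTON if mode == "PI" else m - PROTON
        idx += 1
        entries.append(LibraryEntry(
            entry_id=f"TL{idx:03d}",
            name=f"{name} analogue (+{shift}) [synthetic]",
            molecular_formula=f"{formula}+{shift}",
            monoisotopic_mass=m,
            species=species if depth == "species" else "",
            genus=genus if depth in ("species", "genus") else "",
            family=family if depth in ("species", "genus", "family") else "",
            compound_class=cls,
            adduct="[M+H]+" if mode == "PI" else "[M-H]-",
            spectrum=_synthetic_spectrum(idx, precursor, charge),
        ))
        base_i += 1
    return entries
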