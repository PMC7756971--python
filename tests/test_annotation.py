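"""Molecular-formula assignment, library matching, and annotation ranking."""

import itertools

import numpy as np
import pytest
from pyteomics import mass as pmass

from formulanet.annotation import (
    AnchorPoint,
    ElementBounds,
    HerbTaxonomy,
    PROTON,
    assign_molecular_formula,
    match_library,
    neutral_mass,
    propagate_from_anchor,
    read_library,
    taxonomic_rerank,
)
from formulanet.network import MolecularNetwork, SpectralEdge
from formulanet.toylib import toy_library

from conftest import make_spectrum


# ---------------------------------------------------------------------------
# formula assignment
# ---------------------------------------------------------------------------

def brute_force_formulas(target, ppm_tol, bounds):
    """Independent exhaustive CHNO enumeration oracle (small bounds only)."""
    tol = target * ppm_tol * 1e-6
    hits = set()
    for c, h, n, o in itertools.product(
            range(bounds.c_max + 1), range(bounds.h_max + 1),
            range(bounds.n_max + 1), range(bounds.o_max + 1)):
        m = pmass.calculate_mass(formula=f"C{c}H{h}N{n}O{o}") if (c or h or n or o) else 0.0
        if abs(m - target) > tol:
            continue
        r = c - h / 2 + n / 2 + 1
        if not (bounds.rdbe_min <= r <= bounds.rdbe_max and abs(r - round(r)) < 1e-9):
            continue
        hits.add((c, h, n, o))
    return hits


def parse_chno(formula):
    import re

    counts = dict.fromkeys("CHNO", 0)
    for sym, num in re.findall(r"([CHNO])(\d*)", formula):
        counts[sym] = int(num) if num else 1
    return tuple(counts[s] for s in "CHNO")


class TestFormulaAssignment:
    def test_exact_glucose_hit(self):
        target = pmass.calculate_mass(formula="C6H12O6")
        cands = assign_molecular_formula(target, ppm_tol=5.0)
        assert cands[0].formula == "C6H12O6"
        assert abs(cands[0].ppm_error) < 1e-6

    def test_baicalin_within_5ppm(self):
        # flavone O-glucuronide marker, C21H18O11
        target = pmass.calculate_mass(formula="C21H18O11")
        cands = assign_molecular_formula(target, ppm_tol=5.0)
        assert "C21H18O11" in [c.formula for c in cands]
        assert all(abs(c.ppm_error) <= 5.0 for c in cands)

    def test_zero_tolerance_perturbed_mass_empty(self):
        target = pmass.calculate_mass(formula="C6H12O6") + 0.01
        assert assign_molecular_formula(target, ppm_tol=0.0) == []

    @pytest.mark.parametrize("formula", ["C10H14N2O4", "C8H10O5", "C15H22O3"])
    def test_matches_brute_force_on_small_bounds(self, formula):
        bounds = ElementBounds(c_max=15, h_max=30, n_max=3, o_max=10)
        target = pmass.calculate_mass(formula=formula)
        got = {parse_chno(c.formula) for c in
               assign_molecular_formula(target, ppm_tol=20.0, bounds=bounds)}
        assert got == brute_force_formulas(target, 20.0, bounds)

    def test_rdbe_parity_excludes_odd_electron(self):
        # CH3 radical-like mass: no even-electron CHNO formula at tight tol
        target = pmass.calculate_mass(formula="C1H3") + 0.0
        cands = assign_molecular_formula(target, ppm_tol=5.0,
                                         bounds=ElementBounds(c_max=2, h_max=6, n_max=1, o_max=1))
        assert all(abs(c.rdbe - round(c.rdbe)) < 1e-9 for c in cands)
        assert "CH3" not in [c.formula for c in cands]

    def test_neutral_mass_adducts(self):
        assert neutral_mass(303.0499, "PI") == pytest.approx(302.0426, abs=1e-3)
        assert neutral_mass(301.0354, "NI") == pytest.approx(302.0427, abs=1e-3)


# ---------------------------------------------------------------------------
# library matching
# ---------------------------------------------------------------------------

class TestMatchLibrary:
    def test_identical_query_is_rank_one(self):
        lib = toy_library("PI")
        entry = lib[0]
        query = make_spectrum(99, entry.spectrum.precursor_mz, entry.spectrum.peaks)
        cands = match_library(query, lib, mode="PI")
        assert cands[0].entry_id == entry.entry_id
        assert cands[0].cosine == pytest.approx(1.0, abs=1e-9)

    def test_empty_library(self):
        q = make_spectrum(1, 500.0, [(100.0, 1.0)])
        assert match_library(q, [], mode="PI") == []

    def test_cosine_floor_excludes_weak_matches(self):
        """Three same-precursor entries engineered to score 1.0, ~0.5 and
        ~0.1 against the query; the floor 0.2 keeps exactly two."""
        rng = np.random.default_rng(0)
        base = np.column_stack([np.sort(rng.uniform(60, 400, 10)),
                                np.full(10, 50.0)])
        prec = 450.0
        query = make_spectrum(1, prec, base)
        from formulanet.annotation import LibraryEntry
        from formulanet.network import modified_cosine

        def entry(eid, peaks):
            s = make_spectrum(1000, prec, peaks)
            return LibraryEntry(entry_id=eid, name=eid, molecular_formula="",
                                monoisotopic_mass=prec - PROTON, spectrum=s)

        # keep k of 10 base peaks, replace the rest far away -> cosine = k/10
        def variant(k):
            far = np.column_stack([np.linspace(405, 440, 10 - k), np.full(10 - k, 50.0)])
            return np.vstack([base[:k], far])

        lib = [entry("full", base), entry("half", variant(5)), entry("weak", variant(1))]
        scores = {e.entry_id: modified_cosine(query, e.spectrum)[0] for e in lib}
        assert scores["full"] == pytest.approx(1.0, abs=1e-9)
        assert scores["half"] == pytest.approx(0.5, abs=1e-9)
        assert scores["weak"] == pytest.approx(0.1, abs=1e-9)
        cands = match_library(query, lib, mode="PI", cosine_min=0.2)
        assert [c.entry_id for c in cands] == ["full", "half"]

    def test_precursor_window_and_floor_respected(self):
        lib = toy_library("NI")
        entry = lib[3]
        query = make_spectrum(7, entry.spectrum.precursor_mz, entry.spectrum.peaks)
        for c in match_library(query, lib, mode="NI", mz_tol=0.005, cosine_min=0.2):
            assert c.cosine >= 0.2
            matched_entry = next(e for e in lib if e.entry_id == c.entry_id)
            assert abs(matched_entry.spectrum.precursor_mz - query.precursor_mz) <= 0.005


# ---------------------------------------------------------------------------
# taxonomic re-ranking
# ---------------------------------------------------------------------------

class TestTaxonomicRerank:
    def _cands_and_lib(self):
        lib = toy_library("PI")
        # Baicalin entry (species Scutellaria baicalensis) and an Apiaceae one
        baicalin = next(e for e in lib if e.name == "Baicalin")
        ligustilide = next(e for e in lib if e.name == "Ligustilide")
        from formulanet.annotation import AnnotationCandidate

        cands = [
            AnnotationCandidate(1, ligustilide.entry_id, ligustilide.name, 0.6, 1),
            AnnotationCandidate(1, baicalin.entry_id, baicalin.name, 0.4, 2),
        ]
        return cands, lib

    def test_species_beats_higher_cosine_family(self):
        cands, lib = self._cands_and_lib()
        taxo = HerbTaxonomy(species="Scutellaria baicalensis",
                            genus="Scutellaria", family="Lamiaceae")
        ranked = taxonomic_rerank(cands, lib, taxo)
        assert ranked[0].name == "Baicalin"
        assert ranked[0].taxon_level == "species"
        assert ranked[0].cosine == 0.4  # cosine untouched

    def test_no_taxon_match_keeps_order(self):
        cands, lib = self._cands_and_lib()
        taxo = HerbTaxonomy(species="Nonexistens plantae", genus="Nonexistens",
                            family="Nullaceae")
        ranked = taxonomic_rerank(cands, lib, taxo)
        assert [c.entry_id for c in ranked] == [c.entry_id for c in cands]

    def test_none_taxonomy_is_noop(self):
        cands, lib = self._cands_and_lib()
        assert taxonomic_rerank(cands, lib, None) == cands

    def test_permutation_no_gain_no_loss(self):
        cands, lib = self._cands_and_lib()
        taxo = HerbTaxonomy(family="Lamiaceae")
        ranked = taxonomic_rerank(cands, lib, taxo)
        assert sorted(c.entry_id for c in ranked) == sorted(c.entry_id for c in cands)


# ---------------------------------------------------------------------------
# anchor propagation
# ---------------------------------------------------------------------------

class TestPropagate:
    def _network(self):
        return MolecularNetwork(
            "PI", [1, 2, 3],
            [SpectralEdge(1, 2, 0.9, 7), SpectralEdge(2, 3, 0.85, 7)],
            {1: 1, 2: 1, 3: 1},
        )

    def test_class_matching_candidate_promoted(self):
        from formulanet.annotation import AnnotationCandidate

        anchor = AnchorPoint(1, "SC1", "C21H18O11", "SC", "flavone O-glucuronide")
        cands = {
            2: [AnnotationCandidate(2, "x", "other thing", 0.8, 1,
                                    compound_class="stilbene"),
                AnnotationCandidate(2, "y", "glucuronide analogue", 0.5, 2,
                                    compound_class="flavone O-glucuronide")],
        }
        out = propagate_from_anchor(self._network(), 1, [anchor], cands, [],
                                    rts={2: 3.0, 3: 2.0})
        co2 = next(c for c in out if c.feature_id == 2)
        assert co2.candidates[0].entry_id == "y"
        assert co2.candidates[0].class_match

    def test_no_class_match_keeps_taxonomy_order(self):
        from formulanet.annotation import AnnotationCandidate

        anchor = AnchorPoint(1, "SC1", "", "SC", "flavone O-glucuronide")
        cands = {2: [AnnotationCandidate(2, "x", "a", 0.8, 1, compound_class="stilbene"),
                     AnnotationCandidate(2, "z", "b", 0.6, 2, compound_class="lignan")]}
        out = propagate_from_anchor(self._network(), 1, [anchor], cands, [],
                                    rts={2: 3.0, 3: 2.0})
        co2 = next(c for c in out if c.feature_id == 2)
        assert [c.entry_id for c in co2.candidates] == ["x", "z"]
        assert not any(c.class_match for c in co2.candidates)

    def test_co_marker_labels_by_rt(self):
        anchor = AnchorPoint(1, "X", "", "SC", "")
        out = propagate_from_anchor(self._network(), 1, [anchor], {}, [],
                                    rts={2: 3.1, 3: 2.8})
        labels = {c.feature_id: c.label for c in out}
        assert labels == {3: "Co-X-1", 2: "Co-X-2"}

    def test_cluster_without_anchor_is_noop(self):
        out = propagate_from_anchor(self._network(), 1, [], {}, [], rts={})
        assert out == []


# ---------------------------------------------------------------------------
# library round trip
# ---------------------------------------------------------------------------

def test_library_round_trip(tmp_path):
    import csv

    from formulanet.io import write_mgf

    lib = toy_library("PI")[:5]
    for i, e in enumerate(lib, start=1):
        e.spectrum.feature_id = i
    write_mgf([e.spectrum for e in lib], tmp_path / "lib.mgf")
    with open(tmp_path / "lib.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["entry_id", "name", "molecular_formula",
                                           "monoisotopic_mass", "species", "genus",
                                           "family", "compound_class", "adduct",
                                           "feature_id"])
        w.writeheader()
        for i, e in enumerate(lib, start=1):
            w.writerow({"entry_id": e.entry_id, "name": e.name,
                        "molecular_formula": e.molecular_formula,
                        "monoisotopic_mass": e.monoisotopic_mass,
                        "species": e.species, "genus": e.genus, "family": e.family,
                        "compound_class": e.compound_class, "adduct": e.adduct,
                        "feature_id": i})
    back = read_library(tmp_path / "lib.mgf", tmp_path / "lib.csv")
    assert len(back) == 5
    for orig, b in zip(lib, back):
        assert b.entry_id == orig.entry_id
        assert b.compound_class == orig.compound_class
        assert b.spectrum is not None
        np.testing.assert_allclose(b.spectrum.peaks, orig.spectrum.peaks, rtol=1e-6)


def test_toy_library_has_forty_consistent_entries():
    lib = toy_library("PI")
    assert len(lib) == 40
    assert len({e.entry_id for e in lib}) == 40
    # the real markers carry formula-consistent masses
    for e in lib[:16]:
        assert e.monoisotopic_mass == pytest.approx(
            pmass.calculate_mass(formula=e.molecular_formula), rel=5e-6)
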