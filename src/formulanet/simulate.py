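"""Synthetic multi-herb LC-MS datasets with known ground truth.

The generator emulates the data the workflow consumes: per-herb metabolite
families sharing fragmentation templates (so that modified-cosine clustering
recovers the families), ubiquitous metabolites spread across herbs, a
formula whose feature heights are the w/w-weighted mixture of the herb
signals under multiplicative lognormal noise, ELSD areas proportional to
concentration but decoupled from MS response through per-metabolite
ionization factors, and blank contaminants.

Each herb's most concentrated family member is a planted marker carrying an
ELSD peak well above the abundance floor; the remaining members sit below
it.  Every generated feature is traceable to exactly one ground-truth
metabolite per ionization mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .annotation import PROTON, AnchorPoint
from .io import (
    ElsdPeakTable,
    FeatureRecord,
    FeatureTable,
    SpectrumRecord,
    write_elsd_table,
    write_feature_table,
    write_mgf,
)
from .manifest import SampleEntry, SampleManifest, write_manifest
from .markers import MarkerCandidate, SignatureCluster, STATUS_SPECIFIC
from .network import MolecularNetwork

import pandas as pd

# Herb codes of a typical 10-herb formula and their w/w proportions of the
# crude mixture, expressed as exact parts of 29 (printed rounded they read
# 3.4%, 6.9%, 3.4%, 6.9%, 20.7%, 10.3%, 13.8%, 6.9%, 20.7%, 6.9%).
DEFAULT_HERBS = ("A", "C", "G", "I", "O", "PO", "PR", "SC", "SM", "SO")
_PARTS = {"A": 1, "C": 2, "G": 1, "I": 2, "O": 6, "PO": 3, "PR": 4, "SC": 2, "SM": 6, "SO": 2}
DEFAULT_WW = {h: _PARTS[h] / 29.0 for h in DEFAULT_HERBS}

_PALETTE = ("#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
            "#a65628", "#f781bf", "#17becf", "#b2df8a", "#999999")

HEIGHT_SCALE = 1e6       # MS counts per unit concentration x ionization factor
ELSD_SCALE = 0.004       # uV/s per unit concentration
ELSD_EMISSION_FLOOR = 0.001  # below this the integrator reports no peak


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic formula.

    Defaults: 10 herbs with the formula's w/w proportions, 4 analogue
    families per herb with 5 members each, 6 ubiquitous metabolites, 10%
    multiplicative lognormal noise, 3 blank contaminants.
    """

    n_herbs: int = 10
    families_per_herb: int = 4
    members_per_family: int = 5
    n_ubiquitous: int = 6
    ww_proportions: dict[str, float] | None = None
    ionization_sigma: float = 0.3    # lognormal sigma of per-metabolite ionization factors
    noise_cv: float = 0.1            # multiplicative lognormal noise on every height/area
    n_blank_contaminants: int = 3
    rt_start: float = 0.5
    rt_step: float = 0.05            # global retention-time grid spacing (min)
    mz_range: tuple[float, float] = (150.0, 900.0)
    marker_conc_range: tuple[float, float] = (5.0, 10.0)
    member_conc_range: tuple[float, float] = (0.1, 0.5)
    ubiquitous_conc: float = 0.3
    single_mode_fraction: float = 0.15   # non-marker members detected in one mode only
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_herbs < 1 or self.families_per_herb < 0 or self.members_per_family < 1:
            raise ConfigError("counts must be positive (families with 0 members are infeasible)")
        if self.n_ubiquitous < 0 or self.n_blank_contaminants < 0:
            raise ConfigError("counts must be >= 0")
        if self.ww_proportions is not None:
            total = sum(self.ww_proportions.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"ww_proportions sum to {total}, expected 1")

    def herbs(self) -> list[str]:
        if self.ww_proportions is not None:
            return list(self.ww_proportions)
        if self.n_herbs <= len(DEFAULT_HERBS):
            return list(DEFAULT_HERBS[: self.n_herbs])
        return [f"H{i}" for i in range(1, self.n_herbs + 1)]

    def ww(self) -> dict[str, float]:
        if self.ww_proportions is not None:
            return dict(self.ww_proportions)
        herbs = self.herbs()
        if set(herbs) == set(DEFAULT_HERBS):
            return dict(DEFAULT_WW)
        return {h: 1.0 / len(herbs) for h in herbs}


@dataclass
class TrueMetabolite:
    met_id: str
    kind: str                       # family | ubiquitous | blank
    source_herbs: list[str]
    family_id: str | None
    concentrations: dict[str, float]
    rt: float
    neutral_mass: float
    modes: tuple[str, ...]
    is_planted_marker: bool = False
    elsd_area_true: float = 0.0
    feature_ids: dict[str, int] = field(default_factory=dict)  # mode -> feature id


@dataclass
class GroundTruth:
    metabolites: list[TrueMetabolite]

    def __post_init__(self) -> None:
        self.by_id = {m.met_id: m for m in self.metabolites}
        self.feature_map = {
            (mode, fid): m.met_id
            for m in self.metabolites for mode, fid in m.feature_ids.items()
        }

    def met_of_feature(self, mode: str, feature_id: int) -> TrueMetabolite:
        return self.by_id[self.feature_map[(mode, feature_id)]]

    def planted_markers(self) -> list[TrueMetabolite]:
        return [m for m in self.metabolites if m.is_planted_marker]

    def family_labels(self, mode: str) -> dict[int, str]:
        """feature_id -> family_id for family members present in a mode."""
        return {
            m.feature_ids[mode]: m.family_id
            for m in self.metabolites
            if m.family_id is not None and mode in m.feature_ids
        }

    def anchors(self, mode: str) -> list[AnchorPoint]:
        """Planted markers expressed as formally identified anchor points."""
        out = []
        for m in self.planted_markers():
            if mode not in m.feature_ids:
                continue
            out.append(AnchorPoint(
                feature_id=m.feature_ids[mode], name=m.met_id,
                molecular_formula="", herb_code=m.source_herbs[0],
                compound_class=f"class_{m.family_id}",
            ))
        return out


@dataclass
class SyntheticBundle:
    manifest: SampleManifest
    features: dict[str, FeatureTable]         # mode -> table
    spectra: dict[str, list[SpectrumRecord]]  # mode -> spectra
    elsd: ElsdPeakTable
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _lognoise(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _draw_masses(rng: np.random.Generator, n: int, lo: float, hi: float,
                 min_sep: float = 2.0) -> list[float]:
    masses: list[float] = []
    while len(masses) < n:
        m = float(rng.uniform(lo, hi))
        if all(abs(m - x) >= min_sep for x in masses):
            masses.append(m)
    return masses


def _family_template(rng: np.random.Generator, max_mz: float, n_peaks: int = 8) -> np.ndarray:
    """Template fragment peaks shared by all members of one family."""
    while True:
        mzs = np.sort(rng.uniform(50.0, max_mz, size=n_peaks))
        if np.all(np.diff(mzs) > 0.1):
            break
    intensities = rng.uniform(50.0, 100.0, size=n_peaks)
    return np.column_stack([mzs, intensities])


def _member_spectrum(rng: np.random.Generator, template: np.ndarray,
                     precursor: float, feature_id: int, charge: int) -> SpectrumRecord:
    extra_mz = rng.uniform(50.0, max(60.0, precursor - 30.0), size=2)
    extra = np.column_stack([extra_mz, np.full(2, 25.0)])
    return SpectrumRecord(feature_id, precursor, charge, np.vstack([template, extra]))


def _random_spectrum(rng: np.random.Generator, precursor: float,
                     feature_id: int, charge: int, n_peaks: int = 10) -> SpectrumRecord:
    mzs = np.sort(rng.uniform(50.0, max(60.0, precursor - 10.0), size=n_peaks))
    intensities = rng.uniform(10.0, 100.0, size=n_peaks)
    return SpectrumRecord(feature_id, precursor, charge, np.column_stack([mzs, intensities]))


def generate_dataset(config: SynthConfig | None = None) -> SyntheticBundle:
    """Generate the full synthetic input bundle, deterministic under the seed.

    Herb heights are concentration x ionization factor x noise; formula
    heights are the w/w-weighted sum of the herb signals times their own
    noise draw; ELSD areas are concentration x noise, independent of the
    ionization factors.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    herbs = config.herbs()
    ww = config.ww()

    manifest = SampleManifest(
        [SampleEntry("Formula", "formula")]
        + [
            SampleEntry(f"H_{h}", "herb", herb_code=h,
                        herb_color=_PALETTE[i % len(_PALETTE)],
                        ww_proportion=ww[h])
            for i, h in enumerate(herbs)
        ]
        + [SampleEntry("Blank", "blank")]
    )

    # ---- metabolite roster -------------------------------------------------
    metabolites: list[TrueMetabolite] = []
    n_family = config.n_herbs * config.families_per_herb * config.members_per_family
    n_total = n_family + config.n_ubiquitous + config.n_blank_contaminants
    lo, hi = config.mz_range
    base_masses = _draw_masses(rng, config.n_herbs * config.families_per_herb + config.n_ubiquitous
                               + config.n_blank_contaminants, lo + 50, hi - 100)
    base_iter = iter(base_masses)

    for herb in herbs:
        for f in range(1, config.families_per_herb + 1):
            family_id = f"{herb}-f{f}"
            base = next(base_iter)
            for j in range(config.members_per_family):
                is_marker = j == 0
                if is_marker:
                    conc = float(rng.uniform(*config.marker_conc_range))
                    modes: tuple[str, ...] = ("PI", "NI")
                else:
                    conc = float(rng.uniform(*config.member_conc_range))
                    if rng.random() < config.single_mode_fraction:
                        modes = ("PI",) if rng.random() < 0.5 else ("NI",)
                    else:
                        modes = ("PI", "NI")
                metabolites.append(TrueMetabolite(
                    met_id=f"{family_id}-m{j + 1}",
                    kind="family",
                    source_herbs=[herb],
                    family_id=family_id,
                    concentrations={herb: conc},
                    rt=0.0,
                    neutral_mass=base + j * 14.01565 + float(rng.normal(0, 0.2)),
                    modes=modes,
                    is_planted_marker=is_marker,
                    elsd_area_true=conc * ELSD_SCALE,
                ))
    for u in range(1, config.n_ubiquitous + 1):
        metabolites.append(TrueMetabolite(
            met_id=f"ubiq-{u}", kind="ubiquitous", source_herbs=list(herbs),
            family_id=None,
            concentrations={h: config.ubiquitous_conc for h in herbs},
            rt=0.0, neutral_mass=next(base_iter), modes=("PI", "NI"),
            elsd_area_true=config.ubiquitous_conc * ELSD_SCALE,
        ))
    for b in range(1, config.n_blank_contaminants + 1):
        metabolites.append(TrueMetabolite(
            met_id=f"blank-{b}", kind="blank", source_herbs=[], family_id=None,
            concentrations={}, rt=0.0, neutral_mass=next(base_iter),
            modes=("PI", "NI"),
        ))

    # ---- retention times: global grid, herbs interleaved so same-herb ------
    # metabolites never co-elute within the ELSD matching window
    groups: dict[str, list[TrueMetabolite]] = {h: [] for h in herbs}
    groups["_other"] = []
    for m in metabolites:
        key = m.source_herbs[0] if m.kind == "family" else "_other"
        groups[key].append(m)
    for g in groups.values():
        rng.shuffle(g)
    order: list[TrueMetabolite] = []
    keys = list(groups)
    idx = {k: 0 for k in keys}
    remaining = n_total
    while remaining:
        for k in keys:
            if idx[k] < len(groups[k]):
                order.append(groups[k][idx[k]])
                idx[k] += 1
                remaining -= 1
    for slot, m in enumerate(order):
        m.rt = config.rt_start + slot * config.rt_step + float(rng.uniform(-0.01, 0.01))

    # ---- heights, spectra, features ---------------------------------------
    herb_sample = manifest.herb_samples
    features: dict[str, list[FeatureRecord]] = {"PI": [], "NI": []}
    spectra: dict[str, list[SpectrumRecord]] = {"PI": [], "NI": []}
    templates: dict[tuple[str, str], np.ndarray] = {}
    counters = {"PI": 0, "NI": 0}

    for m in metabolites:
        ion = {mode: float(rng.lognormal(0.0, config.ionization_sigma)) for mode in ("PI", "NI")}
        for mode in ("PI", "NI"):
            if mode not in m.modes:
                continue
            counters[mode] += 1
            fid = counters[mode]
            m.feature_ids[mode] = fid
            mz = m.neutral_mass + (PROTON if mode == "PI" else -PROTON)
            charge = 1 if mode == "PI" else -1

            heights = {s: 0.0 for s in manifest.sample_ids}
            if m.kind == "blank":
                level = HEIGHT_SCALE * 0.2
                heights["Blank"] = level * float(_lognoise(rng, config.noise_cv))
                heights["Formula"] = level * float(_lognoise(rng, config.noise_cv))
            else:
                herb_signal = {}
                for h, conc in m.concentrations.items():
                    herb_signal[h] = conc * ion[mode] * HEIGHT_SCALE
                    heights[herb_sample[h]] = herb_signal[h] * float(_lognoise(rng, config.noise_cv))
                formula_clean = sum(ww[h] * s for h, s in herb_signal.items())
                heights["Formula"] = formula_clean * float(_lognoise(rng, config.noise_cv))
            features[mode].append(FeatureRecord(fid, mz, m.rt, heights))

            if m.kind == "family":
                key = (mode, m.family_id)
                if key not in templates:
                    templates[key] = _family_template(rng, max_mz=m.neutral_mass - 60.0)
                spectra[mode].append(_member_spectrum(rng, templates[key], mz, fid, charge))
            else:
                spectra[mode].append(_random_spectrum(rng, mz, fid, charge))

    # ---- ELSD table --------------------------------------------------------
    elsd_rows = []
    for m in metabolites:
        for h in m.source_herbs:
            area = m.concentrations[h] * ELSD_SCALE * float(_lognoise(rng, config.noise_cv))
            if area >= ELSD_EMISSION_FLOOR:
                elsd_rows.append({
                    "herb_code": h,
                    "rt": m.rt + float(rng.uniform(-0.02, 0.02)),
                    "area": area,
                    "label": "",
                })
    elsd = ElsdPeakTable(pd.DataFrame(elsd_rows, columns=["herb_code", "rt", "area", "label"]))

    truth = GroundTruth(metabolites)
    return SyntheticBundle(
        manifest=manifest,
        features={mode: FeatureTable(mode, recs) for mode, recs in features.items()},
        spectra=spectra,
        elsd=elsd,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    precision: float
    recall: float
    per_herb: dict[str, tuple[float, float]]
    n_predicted: int
    n_planted: int


def evaluate_recovery(markers: list[MarkerCandidate], truth: GroundTruth) -> RecoveryReport:
    """Precision/recall of planted-marker recovery from selected markers.

    A marker candidate counts as predicted when its status is ``specific``;
    it is mapped back to its ground-truth metabolite through either mode's
    feature id.  Unknown feature ids raise a validation error.
    """
    predicted: set[str] = set()
    pred_by_herb: dict[str, set[str]] = {}
    for m in markers:
        if m.status != STATUS_SPECIFIC:
            continue
        met_id = None
        for mode, fid in (("PI", m.feature_id_pi), ("NI", m.feature_id_ni)):
            if fid is None:
                continue
            if (mode, fid) not in truth.feature_map:
                raise ValueError(f"feature {fid} ({mode}) is unknown to the ground truth")
            met_id = truth.feature_map[(mode, fid)]
        if met_id is not None:
            predicted.add(met_id)
            pred_by_herb.setdefault(m.herb_code, set()).add(met_id)
    planted = {m.met_id for m in truth.planted_markers()}
    planted_by_herb: dict[str, set[str]] = {}
    for m in truth.planted_markers():
        planted_by_herb.setdefault(m.source_herbs[0], set()).add(m.met_id)

    def _pr(pred: set[str], true: set[str]) -> tuple[float, float]:
        tp = len(pred & true)
        precision = tp / len(pred) if pred else (1.0 if not true else 0.0)
        recall = tp / len(true) if true else 1.0
        return precision, recall

    precision, recall = _pr(predicted, planted)
    per_herb = {
        h: _pr(pred_by_herb.get(h, set()), planted_by_herb.get(h, set()))
        for h in sorted(set(pred_by_herb) | set(planted_by_herb))
    }
    return RecoveryReport(precision, recall, per_herb, len(predicted), len(planted))


def cluster_family_ari(network: MolecularNetwork, truth: GroundTruth, mode: str) -> float:
    """Adjusted Rand index between network clusters and planted families.

    Restricted to family-member features present in the network; singleton
    nodes get unique labels so stray singletons count against agreement.
    """
    fam = truth.family_labels(mode)
    nodes = [n for n in network.nodes if n in fam]
    true_labels = [fam[n] for n in nodes]
    pred = []
    next_singleton = -1
    for n in nodes:
        c = network.cluster_index.get(n, -1)
        if c == -1:
            pred.append(next_singleton)
            next_singleton -= 1
        else:
            pred.append(c)
    return float(adjusted_rand_score(true_labels, pred))


def family_recovery(signatures: list[SignatureCluster], truth: GroundTruth,
                    mode: str) -> tuple[int, int]:
    """(n families recovered as category-1 signatures, n eligible families).

    A family is eligible when at least two of its members (including its
    marker) are present in the mode; it is recovered when a category-1
    cluster contains the family's marker feature.
    """
    eligible = {}
    for m in truth.planted_markers():
        if mode not in m.feature_ids:
            continue
        n_members = sum(
            1 for x in truth.metabolites
            if x.family_id == m.family_id and mode in x.feature_ids
        )
        if n_members >= 2:
            eligible[m.family_id] = m.feature_ids[mode]
    recovered = 0
    cat1_members = [set(s.member_ids) | set(s.anchor_ids)
                    for s in signatures if s.category == 1]
    for fid in eligible.values():
        if any(fid in members for members in cat1_members):
            recovered += 1
    return recovered, len(eligible)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write the full input bundle (manifest, tables, MGFs, ELSD, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(bundle.manifest, out / "manifest.csv")
    for mode in ("PI", "NI"):
        write_feature_table(bundle.features[mode], bundle.manifest,
                            out / f"features_{mode.lower()}.csv")
        write_mgf(bundle.spectra[mode], out / f"spectra_{mode.lower()}.mgf")
    write_elsd_table(bundle.elsd, out / "elsd.csv")
    for mode in ("PI", "NI"):
        anchors = bundle.truth.anchors(mode)
        df = pd.DataFrame(
            [{"feature_id": a.feature_id, "name": a.name, "formula": a.molecular_formula,
              "class": a.compound_class, "herb": a.herb_code} for a in anchors]
        )
        df.to_csv(out / f"anchors_{mode.lower()}.csv", index=False)
    truth_json = [
        {
            "met_id": m.met_id, "kind": m.kind, "source_herbs": m.source_herbs,
            "family_id": m.family_id, "concentrations": m.concentrations,
            "rt": m.rt, "neutral_mass": m.neutral_mass, "modes": list(m.modes),
            "is_planted_marker": m.is_planted_marker,
            "elsd_area_true": m.elsd_area_true, "feature_ids": m.feature_ids,
        }
        for m in bundle.truth.metabolites
    ]
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
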