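"""Sample manifest: which LC-MS run is the formula, a single herb, or a blank.

The manifest ties sample columns of the aligned feature tables to their role
in the mixture design.  Herb samples additionally carry the w/w proportion of
the crude herb in the formula before decoction and a plotting color.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import yaml

ROLE_FORMULA = "formula"
ROLE_HERB = "herb"
ROLE_BLANK = "blank"
_ROLES = {ROLE_FORMULA, ROLE_HERB, ROLE_BLANK}


class ManifestError(ValueError):
    """Raised when a sample manifest violates its invariants."""


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    role: str
    herb_code: str = ""
    herb_color: str = ""
    ww_proportion: float | None = None


@dataclass
class SampleManifest:
    """Validated collection of samples for one study.

    Invariants enforced at construction: unique sample ids, exactly one
    formula sample, unique herb codes, and herb w/w proportions summing to
    1 within 1e-6 when all are provided.
    """

    samples: list[SampleEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ManifestError("sample_ids are not unique")
        for s in self.samples:
            if s.role not in _ROLES:
                raise ManifestError(f"unknown role {s.role!r} for {s.sample_id}")
        n_formula = sum(1 for s in self.samples if s.role == ROLE_FORMULA)
        if n_formula != 1:
            raise ManifestError(f"expected exactly one formula sample, got {n_formula}")
        codes = [s.herb_code for s in self.samples if s.role == ROLE_HERB]
        if len(set(codes)) != len(codes):
            raise ManifestError("herb_codes are not unique")
        if any(not c for c in codes):
            raise ManifestError("herb samples must carry a herb_code")
        props = [s.ww_proportion for s in self.samples if s.role == ROLE_HERB]
        if props and all(p is not None for p in props):
            total = sum(props)  # type: ignore[arg-type]
            if abs(total - 1.0) > 1e-6:
                raise ManifestError(
                    f"herb ww_proportions sum to {total:.8f}, expected 1"
                )

    # -- lookups -----------------------------------------------------------
    @property
    def formula_sample(self) -> str:
        return next(s.sample_id for s in self.samples if s.role == ROLE_FORMULA)

    @property
    def herb_samples(self) -> dict[str, str]:
        """Mapping herb_code -> sample_id, in manifest order."""
        return {s.herb_code: s.sample_id for s in self.samples if s.role == ROLE_HERB}

    @property
    def herb_codes(self) -> list[str]:
        return [s.herb_code for s in self.samples if s.role == ROLE_HERB]

    @property
    def blank_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.role == ROLE_BLANK]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def herb_color(self, code: str) -> str:
        for s in self.samples:
            if s.role == ROLE_HERB and s.herb_code == code:
                return s.herb_color
        raise KeyError(code)

    def ww_proportions(self) -> dict[str, float]:
        return {
            s.herb_code: s.ww_proportion
            for s in self.samples
            if s.role == ROLE_HERB and s.ww_proportion is not None
        }


_FIELDS = ("sample_id", "role", "herb_code", "herb_color", "ww_proportion")


def _entry_from_row(row: dict) -> SampleEntry:
    ww = row.get("ww_proportion")
    if ww in (None, ""):
        ww_val = None
    else:
        ww_val = float(ww)
    return SampleEntry(
        sample_id=str(row["sample_id"]),
        role=str(row["role"]).strip().lower(),
        herb_code=str(row.get("herb_code") or ""),
        herb_color=str(row.get("herb_color") or ""),
        ww_proportion=ww_val,
    )


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest from CSV or YAML (by file extension)."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        rows = data["samples"] if isinstance(data, dict) else data
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    if not rows:
        raise ManifestError(f"empty manifest: {path}")
    return SampleManifest([_entry_from_row(r) for r in rows])


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_FIELDS)
        writer.writeheader()
        for s in manifest.samples:
            writer.writerow(
                {
                    "sample_id": s.sample_id,
                    "role": s.role,
                    "herb_code": s.herb_code,
                    "herb_color": s.herb_color,
                    "ww_proportion": "" if s.ww_proportion is None else repr(s.ww_proportion),
                }
            )
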