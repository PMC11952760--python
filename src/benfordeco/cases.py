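"""Packaged case-study fixtures: published digit tallies and raw biomass.

Eight fixtures cover four ecological case studies plus their pooled
combination:

* ``succession_early`` / ``succession_late`` — below-ground functional
  group biomass during early and late stages of ecological succession.
* ``diatoms_small`` / ``diatoms_large`` — diatom community cell counts
  from a colonization experiment on small and large glass-slide islands.
* ``salamanders_pre1990`` / ``salamanders_post1990`` — woodland
  salamander encounter rates before and during a period of widespread
  population decline.
* ``fish_ewh`` — relative weight (kg/km) of 141 fish species encounters
  from five exceptional-warmwater-habitat streams; ships the raw
  biomass values, which re-tally to the published digit counts.
* ``combined_steady_state`` — the pooled tally of the four systems in
  steady-state dynamic equilibrium (n = 604), illustrating Hill-theorem
  aggregation: the pooled sample is closer to Benford than any part.

Each fixture carries the digit tally, the raw values where published,
and the statistics reported alongside the source table (used as
regression expectations). Files are checksummed in a manifest so tests
fail loudly on accidental edits.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .core import DigitTally, tally_digits

__all__ = ["CaseFixture", "load_case", "list_cases", "verify_combination"]

_DATA = resources.files(__package__) / "data"


@dataclass(frozen=True)
class CaseFixture:
    name: str
    tally: DigitTally
    raw_values: tuple[float, ...] | None
    expected: Mapping[str, object]
    source_table: str
    case_label: str

    @property
    def n(self) -> int:
        return self.tally.n


def _sha256(path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest() -> dict:
    return json.loads((_DATA / "manifest.json").read_text(encoding="utf-8"))


def list_cases() -> list[str]:
    """Names of all packaged case fixtures."""
    return sorted(_manifest()["fixtures"])


def load_case(name: str) -> CaseFixture:
    """Load a packaged fixture, verifying its checksum against the manifest."""
    manifest = _manifest()
    try:
        entry = manifest["fixtures"][name]
    except KeyError:
        raise KeyError(
            f"unknown case fixture {name!r}; available: {', '.join(sorted(manifest['fixtures']))}"
        ) from None

    tally_path = _DATA / entry["tally_file"]
    if _sha256(tally_path) != entry["tally_sha256"]:
        raise RuntimeError(f"fixture file {entry['tally_file']} fails its checksum; data edited?")
    with tally_path.open(encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    counts = [0] * 9
    for row in rows:
        counts[int(row["digit"]) - 1] = int(row["count"])
    tally = DigitTally(tuple(counts))

    raw = None
    if entry.get("raw_file"):
        raw_path = _DATA / entry["raw_file"]
        if _sha256(raw_path) != entry["raw_sha256"]:
            raise RuntimeError(f"fixture file {entry['raw_file']} fails its checksum; data edited?")
        with raw_path.open(encoding="utf-8") as fh:
            raw = tuple(float(row["value"]) for row in csv.DictReader(fh))
        retally = tally_digits(raw)
        if retally != tally:
            raise RuntimeError(f"raw values of {name!r} do not re-tally to the stored digit counts")

    if tally.n != entry["expected"]["n"]:
        raise RuntimeError(f"fixture {name!r}: tally n={tally.n} != recorded n={entry['expected']['n']}")

    return CaseFixture(
        name=name,
        tally=tally,
        raw_values=raw,
        expected=entry["expected"],
        source_table=entry["source_table"],
        case_label=entry["case_label"],
    )


def verify_combination(parts: list[str], whole: str) -> bool:
    """True iff the element-wise sum of part tallies equals the whole's tally."""
    combined = None
    for p in parts:
        t = load_case(p).tally
        combined = t if combined is None else combined + t
    return combined == load_case(whole).tally
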