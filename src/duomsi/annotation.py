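"""Sum-composition lipid annotation by accurate mass.

Observed peaks are matched against a local lipid mass list (name,
adduct, theoretical m/z) within a ppm tolerance (default 5 ppm).
Ambiguity is first-class: isobaric species (e.g. [PE 36:1 + H]+ and
[PC 34:1-CH3 + H]+) are both reported for one peak, ordered by absolute
ppm error, mirroring slash-joined assignments like
"[PE 36:1 + H]+/[PC 34:1-CH3 + H]+". The shipped database
(``data/lipid_db.csv``) is a synthetic stand-in computed from molecular
formulas, not a reproduction of any instrument-specific reference list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .datamodel import FormatError


@dataclass(frozen=True)
class LipidRecord:
    """One candidate species: sum-composition name, adduct, exact m/z."""

    name: str
    adduct: str
    theoretical_mz: float

    def __post_init__(self) -> None:
        if self.theoretical_mz <= 0:
            raise ValueError(f"{self.name}: theoretical m/z must be positive")


@dataclass
class Annotation:
    """All database matches for one observed peak, best first."""

    observed_mz: float
    matches: list[tuple[LipidRecord, float]] = field(default_factory=list)

    @property
    def best(self) -> tuple[LipidRecord, float] | None:
        return self.matches[0] if self.matches else None

    @property
    def best_name(self) -> str:
        return self.matches[0][0].name if self.matches else ""

    def joined_names(self) -> str:
        """Slash-joined candidate names, e.g. 'PE 36:1/PC 34:1-CH3'."""
        return "/".join(rec.name for rec, _ in self.matches)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def annotate(
    peaks: list[float],
    db: list[LipidRecord],
    tolerance_ppm: float = 5.0,
) -> list[Annotation]:
    """Match each observed m/z against the database.

    Every record within ``tolerance_ppm`` is kept, sorted by |ppm error|
    (ties broken by database order); a peak with no match gets an empty
    match list.
    """
    if not db:
        raise ValueError("empty lipid database")
    out = []
    for mz in peaks:
        matches = []
        for order, rec in enumerate(db):
            err = ppm_error(mz, rec.theoretical_mz)
            if abs(err) <= tolerance_ppm:
                matches.append((abs(err), order, rec, err))
        matches.sort(key=lambda m: (m[0], m[1]))
        out.append(Annotation(observed_mz=mz, matches=[(rec, err) for _, _, rec, err in matches]))
    return out


def load_database(path: str | Path | None = None) -> list[LipidRecord]:
    """Read a lipid DB CSV (columns: name, adduct, theoretical_mz).

    With no path, the bundled 20-record database is loaded. (name,
    adduct) pairs must be unique.
    """
    if path is None:
        text = (resources.files("duomsi") / "data" / "lipid_db.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with Path(path).open(newline="") as fh:
            rows = list(csv.DictReader(fh))
    if not rows or not {"name", "adduct", "theoretical_mz"}.issubset(rows[0]):
        raise FormatError("lipid DB needs columns name, adduct, theoretical_mz")
    records = [
        LipidRecord(r["name"], r["adduct"], float(r["theoretical_mz"])) for r in rows
    ]
    keys = [(r.name, r.adduct) for r in records]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise FormatError(f"duplicate (name, adduct) records in lipid DB: {dupes}")
    return records


def write_annotation_report(annotations: list[Annotation], path: str | Path) -> None:
    """CSV report: observed_mz, best_name, best_adduct, best_ppm, all_matches."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["observed_mz", "best_name", "best_adduct", "best_ppm", "all_matches"])
        for ann in annotations:
            if ann.best is None:
                w.writerow([f"{ann.observed_mz:.4f}", "", "", "", ""])
            else:
                rec, err = ann.best
                w.writerow(
                    [
                        f"{ann.observed_mz:.4f}",
                        rec.name,
                        rec.adduct,
                        f"{err:.3f}",
                        ann.joined_names(),
                    ]
                )
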