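"""Pre-build step: compute the shipped lipid mass database from formulas.

Monoisotopic masses of neutral molecular formulas plus adduct arithmetic
([M+H]+ and [M+Na]+) give the theoretical m/z values frozen into
``src/duomsi/data/lipid_db.csv``. Run from the repository root:

    python scripts/build_lipid_db.py
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

# CODATA/AME2020 monoisotopic atomic masses, Da
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}
ELECTRON_MASS = 0.00054857990907
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS

# (name, adduct, neutral formula) — sum-composition species typical of
# positive-mode brain lipid imaging (PE/PC/PS/SM/Cer/HexCer classes).
RECORDS = [
    ("PE 34:1", "[M+H]+", "C39H76NO8P"),
    ("PE 36:1", "[M+H]+", "C41H80NO8P"),
    ("PC 34:1-CH3", "[M+H]+", "C41H80NO8P"),  # isobaric with PE 36:1
    ("PE 36:2", "[M+H]+", "C41H78NO8P"),
    ("PE 38:4", "[M+H]+", "C43H78NO8P"),
    ("PE 38:6", "[M+H]+", "C43H74NO8P"),
    ("PE 40:6", "[M+H]+", "C45H78NO8P"),
    ("PE O-36:5", "[M+H]+", "C41H74NO7P"),
    ("PE O-38:5", "[M+H]+", "C43H78NO7P"),
    ("HexCer 42:2;2", "[M+H]+", "C48H91NO8"),
    ("HexCer 40:1;2", "[M+H]+", "C46H89NO8"),
    ("PC 32:0", "[M+H]+", "C40H80NO8P"),
    ("PC 34:1", "[M+H]+", "C42H82NO8P"),
    ("PC 36:4", "[M+H]+", "C44H80NO8P"),
    ("PS 40:6", "[M+H]+", "C46H76NO10P"),
    ("SM d36:1", "[M+H]+", "C41H83N2O6P"),
    ("Cer d36:1", "[M+H]+", "C36H71NO3"),
    ("Cer d42:2", "[M+H]+", "C42H81NO3"),
    ("PC 34:1", "[M+Na]+", "C42H82NO8P"),
    ("PE 40:6", "[M+Na]+", "C45H78NO8P"),
]


def monoisotopic_mass(formula: str) -> float:
    mass = 0.0
    consumed = 0
    for sym, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not sym:
            continue
        mass += ATOMIC_MASS[sym] * (int(count) if count else 1)
        consumed += len(sym) + len(count)
    if consumed != len(formula):
        raise ValueError(f"unparsed formula: {formula!r}")
    return mass


def adduct_mz(neutral: float, adduct: str) -> float:
    if adduct == "[M+H]+":
        return neutral + PROTON_MASS
    if adduct == "[M+Na]+":
        return neutral + ATOMIC_MASS["Na"] - ELECTRON_MASS
    raise ValueError(f"unsupported adduct: {adduct}")


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "src" / "duomsi" / "data" / "lipid_db.csv"
    rows = [
        (name, adduct, f"{adduct_mz(monoisotopic_mass(f), adduct):.4f}")
        for name, adduct, f in RECORDS
    ]
    with out.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "adduct", "theoretical_mz"])
        w.writerows(rows)
    print(f"wrote {len(rows)} records to {out}")


if __name__ == "__main__":
    main()
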