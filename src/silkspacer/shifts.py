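"""¹³C chemical-shift reference table and conformation classification.

Packages the solid-state NMR reference shifts (ppm from TMS) for the
silk-relevant residues — observed dragline-silk values alongside
α-helix, β-sheet, random-coil and 3₁-helix (polyglycine-II-like
(AGG)₁₀ model peptide) references — and classifies an observed shift by
its distance to each reference class. Point references are zero-width
intervals so one distance definition covers everything.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .exceptions import ClassificationError, InputError

CLASSES = ("observed", "alpha", "beta", "coil", "helix31")
ATOMS = ("CA", "CB", "CG", "CD", "CE", "CZ", "CO")

#: Two top-ranked classes closer than this are reported as ambiguous (ppm).
AMBIGUITY_THRESHOLD = 0.2


@dataclass(frozen=True)
class ShiftRecord:
    residue: str          # one-letter code
    atom: str
    conformation: str     # one of CLASSES
    low: float            # ppm; low == high for point references
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise InputError(f"interval lower {self.low} > upper {self.high}")
        if not (0.0 < self.low and self.high < 250.0):
            raise InputError(f"ppm outside (0, 250): {self.low}-{self.high}")
        if self.conformation not in CLASSES:
            raise InputError(f"unknown conformation class {self.conformation!r}")
        if self.atom not in ATOMS:
            raise InputError(f"unknown atom site {self.atom!r}")

    @property
    def is_point(self) -> bool:
        return self.low == self.high

    def distance(self, ppm: float) -> float:
        """0 inside the interval, else the gap to the nearest endpoint."""
        if self.low <= ppm <= self.high:
            return 0.0
        return min(abs(ppm - self.low), abs(ppm - self.high))

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


def load_reference_table(source: str | None = None) -> list[ShiftRecord]:
    """Load shift records from CSV (packaged table when ``source`` is None)."""
    if source is None:
        path = resources.files("silkspacer.data") / "shift_reference.csv"
        text = path.read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(source, newline="") as fh:
            rows = list(csv.DictReader(fh))
    records = []
    for i, row in enumerate(rows):
        try:
            records.append(ShiftRecord(
                residue=row["residue"].strip(),
                atom=row["atom"].strip(),
                conformation=row["class"].strip(),
                low=float(row["low_ppm"]),
                high=float(row["high_ppm"]),
            ))
        except (KeyError, ValueError, InputError) as exc:
            raise InputError(f"malformed shift table row {i + 2}: {row}") from exc
    return records


def write_reference_table(records: list[ShiftRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residue", "atom", "class", "low_ppm", "high_ppm"])
        for r in records:
            writer.writerow([r.residue, r.atom, r.conformation, r.low, r.high])


def lookup(
    records: list[ShiftRecord], residue: str, atom: str, conformation: str
) -> list[ShiftRecord]:
    """All records for one (residue, atom, class) site; empty = missing."""
    return [
        r for r in records
        if r.residue == residue and r.atom == atom and r.conformation == conformation
    ]


@dataclass
class ShiftClassification:
    """Distance ranking of reference classes for one observed shift."""

    residue: str
    atom: str
    observed_ppm: float
    ranking: list[tuple[str, float]]   # (class, distance), ascending
    secondary_shift: float | None      # observed − coil midpoint, ppm
    ambiguous: bool

    @property
    def top(self) -> str:
        return self.ranking[0][0]


def classify_shift(
    residue: str, atom: str, observed_ppm: float,
    table: list[ShiftRecord] | None = None,
) -> ShiftClassification:
    """Rank conformation classes by distance to an observed shift.

    Distance is 0 when the shift falls inside a class interval, else the
    gap to the nearest endpoint (the minimum over multiple records of a
    class). The secondary shift Δδ is observed − random-coil reference.
    Raises :class:`ClassificationError` when no reference class exists
    for the site.
    """
    if table is None:
        table = load_reference_table()
    ranking = []
    coil_ref = None
    for cls in ("alpha", "beta", "coil", "helix31"):
        recs = lookup(table, residue, atom, cls)
        if not recs:
            continue
        dist = min(r.distance(observed_ppm) for r in recs)
        ranking.append((cls, dist))
        if cls == "coil":
            coil_ref = min(recs, key=lambda r: r.distance(observed_ppm))
    if not ranking:
        raise ClassificationError(
            f"no reference classes for {residue} {atom}"
        )
    ranking.sort(key=lambda t: t[1])
    ambiguous = len(ranking) >= 2 and (
        ranking[1][1] - ranking[0][1] < AMBIGUITY_THRESHOLD
    )
    secondary = (
        observed_ppm - coil_ref.midpoint if coil_ref is not None else None
    )
    return ShiftClassification(
        residue=residue,
        atom=atom,
        observed_ppm=observed_ppm,
        ranking=ranking,
        secondary_shift=secondary,
        ambiguous=ambiguous,
    )


def range_membership(
    observed_ppm: float, interval: tuple[float, float]
) -> tuple[str, float]:
    """Three-way verdict vs a closed interval, with the signed gap in ppm.

    Returns ("inside", 0.0), ("below", gap) with gap = lower − observed,
    or ("above", gap) with gap = observed − upper.
    """
    lo, hi = interval
    if lo > hi:
        raise InputError(f"invalid interval ({lo}, {hi})")
    if lo <= observed_ppm <= hi:
        return "inside", 0.0
    if observed_ppm < lo:
        return "below", lo - observed_ppm
    return "above", observed_ppm - hi


def table_as_dataframe(records: list[ShiftRecord] | None = None) -> pd.DataFrame:
    """Reference table as a tidy DataFrame (one row per record)."""
    records = records if records is not None else load_reference_table()
    return pd.DataFrame([
        {"residue": r.residue, "atom": r.atom, "class": r.conformation,
         "low_ppm": r.low, "high_ppm": r.high}
        for r in records
    ])
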