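"""Domain types and tabular I/O for cytoplasmic-incompatibility brood counts.

The experimental unit throughout is a *brood*: the eggs laid by the females
of one replicate cross, scored as adult female offspring, adult male
offspring, and eggs that failed to produce an adult.  In a haplodiploid host
unfertilized eggs develop into males and fertilized eggs into females, so an
incompatible cross (uninfected female x Wolbachia-infected male) shows up
either as missing females (female-mortality CI) or as excess males
(male-development CI).

Three proportions summarise a brood:

    F  = adult_females / eggs
    MD = adult_males   / eggs
    FM = failed eggs   / (eggs - adult_males)

and each is modelled downstream as a binomial numerator over its
denominator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Genotype",
    "CrossClass",
    "CrossType",
    "BroodRecord",
    "ResponseTriple",
    "enumerate_diallel",
    "derive_responses",
    "read_records",
    "write_records",
    "RECORD_COLUMNS",
]


@dataclass(frozen=True, order=True)
class Genotype:
    """A near-isogenic nuclear background, identified by a short label."""

    label: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("genotype label must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class CrossClass:
    """Compatibility class of a cross, fully determined by infection flags."""

    INCOMPATIBLE = "incompatible"
    COMPATIBLE_CONTROL = "compatible_control"
    RESCUE = "rescue"
    RESCUE_CONTROL = "rescue_control"


def _cross_class(male_infected: bool, female_infected: bool) -> str:
    if male_infected and not female_infected:
        return CrossClass.INCOMPATIBLE
    if not male_infected and not female_infected:
        return CrossClass.COMPATIBLE_CONTROL
    if male_infected and female_infected:
        return CrossClass.RESCUE
    return CrossClass.RESCUE_CONTROL


@dataclass(frozen=True)
class CrossType:
    """A mating class: female genotype x male genotype x infection states.

    The compatibility class is derived from the infection flags, never
    stored independently, so the class/flag invariant cannot be violated.
    """

    female_genotype: Genotype
    male_genotype: Genotype
    male_infected: bool
    female_infected: bool = False

    @property
    def cross_class(self) -> str:
        return _cross_class(self.male_infected, self.female_infected)

    @property
    def pair(self) -> tuple[str, str]:
        """(female, male) genotype labels — the pairing key for indexes."""
        return (self.female_genotype.label, self.male_genotype.label)


@dataclass(frozen=True)
class BroodRecord:
    """One replicate's counts plus its day cohort and cross type.

    ``extra`` carries optional pedigree annotations (e.g. maternal_origin,
    modifier_genotype for the inheritance experiment); downstream model
    fitting ignores it.
    """

    cross_type: CrossType
    day: str
    replicate: str
    eggs: int
    adult_females: int
    adult_males: int
    extra: dict = field(default_factory=dict, compare=True, hash=False)

    def __post_init__(self) -> None:
        for name in ("eggs", "adult_females", "adult_males"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.adult_females + self.adult_males > self.eggs:
            raise ValueError(
                "adult_females + adult_males exceeds eggs "
                f"({self.adult_females} + {self.adult_males} > {self.eggs})"
            )


@dataclass(frozen=True)
class ResponseTriple:
    """Numerator/denominator pairs for the F, MD and FM responses."""

    f_num: int
    f_den: int
    md_num: int
    md_den: int
    fm_num: int
    fm_den: int


def enumerate_diallel(genotypes: Sequence[Genotype]) -> list[CrossType]:
    """Enumerate the full diallel with both male infection states.

    Every female genotype is paired with every male genotype, once with an
    infected male (an incompatible cross) and once with an uninfected male
    (its compatible control); females are uninfected throughout.  Order is
    deterministic: female-major, then male, infected male last within a
    pair.  A panel of G genotypes therefore yields 2*G**2 cross types,
    exactly half of them incompatible.
    """
    if not genotypes:
        raise ValueError("need at least one genotype")
    labels = [g.label for g in genotypes]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate genotype labels in {labels}")
    crosses = []
    for f in genotypes:
        for m in genotypes:
            crosses.append(CrossType(f, m, male_infected=False))
            crosses.append(CrossType(f, m, male_infected=True))
    return crosses


def derive_responses(record: BroodRecord) -> ResponseTriple:
    """Derive the three binomial responses from a brood's counts.

    F counts adult females out of all eggs, MD counts adult males out of
    all eggs, and FM counts failed eggs out of the eggs that did not become
    adult males.  The three numerators partition the eggs:
    f_num + md_num + fm_num == eggs.
    """
    eggs = record.eggs
    failed = eggs - record.adult_females - record.adult_males
    return ResponseTriple(
        f_num=record.adult_females,
        f_den=eggs,
        md_num=record.adult_males,
        md_den=eggs,
        fm_num=failed,
        fm_den=eggs - record.adult_males,
    )


# --- delimited-text I/O -----------------------------------------------------

RECORD_COLUMNS = [
    "day",
    "female_genotype",
    "male_genotype",
    "male_infected",
    "female_infected",
    "replicate",
    "eggs",
    "adult_females",
    "adult_males",
]

_INFECTION_WORDS = {"infected": True, "cured": False}


def _format_infection(flag: bool) -> str:
    return "infected" if flag else "cured"


def _parse_infection(value: str, column: str, line_no: int) -> bool:
    try:
        return _INFECTION_WORDS[value.strip().lower()]
    except KeyError:
        raise ValueError(
            f"line {line_no}: {column} must be 'infected' or 'cured', got {value!r}"
        ) from None


def _parse_count(value: str, column: str, line_no: int) -> int:
    s = value.strip()
    try:
        return int(s)
    except ValueError:
        raise ValueError(
            f"line {line_no}: {column} must be a non-negative integer, got {value!r}"
        ) from None


def write_records(records: Iterable[BroodRecord], path: str | Path) -> None:
    """Write brood records as a UTF-8 comma-separated table.

    Column order is fixed; any ``extra`` annotation keys present on the
    records are appended as additional columns (union over records, sorted).
    """
    records = list(records)
    extra_cols = sorted({k for r in records for k in r.extra})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS + extra_cols)
        for r in records:
            ct = r.cross_type
            row = [
                r.day,
                ct.female_genotype.label,
                ct.male_genotype.label,
                _format_infection(ct.male_infected),
                _format_infection(ct.female_infected),
                r.replicate,
                r.eggs,
                r.adult_females,
                r.adult_males,
            ]
            row += [r.extra.get(k, "") for k in extra_cols]
            writer.writerow(row)


def read_records(path: str | Path) -> list[BroodRecord]:
    """Read brood records from a delimited-text table.

    Malformed rows are rejected with their line number; a missing required
    column is a schema error.  Columns beyond the required schema are kept
    as ``extra`` annotations.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        missing = [c for c in RECORD_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        extra_cols = [c for c in reader.fieldnames if c not in RECORD_COLUMNS]
        records = []
        for line_no, row in enumerate(reader, start=2):
            try:
                cross = CrossType(
                    female_genotype=Genotype(row["female_genotype"].strip()),
                    male_genotype=Genotype(row["male_genotype"].strip()),
                    male_infected=_parse_infection(
                        row["male_infected"], "male_infected", line_no
                    ),
                    female_infected=_parse_infection(
                        row["female_infected"], "female_infected", line_no
                    ),
                )
                extra = {
                    c: row[c] for c in extra_cols if row[c] not in (None, "")
                }
                record = BroodRecord(
                    cross_type=cross,
                    day=row["day"].strip(),
                    replicate=row["replicate"].strip(),
                    eggs=_parse_count(row["eggs"], "eggs", line_no),
                    adult_females=_parse_count(
                        row["adult_females"], "adult_females", line_no
                    ),
                    adult_males=_parse_count(
                        row["adult_males"], "adult_males", line_no
                    ),
                    extra=extra,
                )
            except ValueError as err:
                msg = str(err)
                if not msg.startswith("line "):
                    msg = f"line {line_no}: {msg}"
                raise ValueError(f"{path}: {msg}") from None
            records.append(record)
    return records
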