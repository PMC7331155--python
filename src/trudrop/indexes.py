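"""Sample-index sets: edit-distance validation, indexing schemes, and the
unanticipated-combination filter used to remove index-hopped reads.

A sample sheet maps each sample to an i7 index and, for dual-indexed
designs, an i5 index.  Three schemes are distinguished:

``single``
    only i7 indexes (hopped reads are undetectable);
``combinatorial_dual``
    dual indexes with at least one index repeated on one side (hops between
    samples sharing an index remain undetectable);
``unique_dual``
    no index reused on either side — every single-side hop produces an
    (i7, i5) combination that no sample was assigned, so the read can be
    filtered instead of mis-assigned.

Index sets should keep a pairwise edit distance of at least 2 on each side
independently so that one base error (insertion, deletion or substitution)
cannot turn one sample's index into another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import edlib
import pandas as pd

__all__ = [
    "IndexPair",
    "SampleSheet",
    "Violation",
    "Assignment",
    "levenshtein",
    "hamming",
    "classify_scheme",
    "validate_index_set",
    "expected_combinations",
    "assign_read",
    "UNDETERMINED",
    "FILTERED_HOPPED",
]

UNDETERMINED = "undetermined"
FILTERED_HOPPED = "filtered_hopped"


def _check_dna(seq: str, what: str) -> str:
    s = seq.upper()
    if not s:
        raise ValueError(f"{what} must be non-empty")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return s


def levenshtein(a: str, b: str) -> int:
    """Edit distance (insertions, deletions, substitutions) between two
    sequences."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return edlib.align(a.upper(), b.upper(), mode="NW", task="distance")[
        "editDistance"
    ]


def hamming(a: str, b: str) -> int:
    """Substitution-only distance; sequences must have equal length."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(ca != cb for ca, cb in zip(a, b))


@dataclass(frozen=True)
class IndexPair:
    """One sample's index assignment; ``i5`` is None for single indexing."""

    sample_id: str
    i7: str
    i5: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "i7", _check_dna(self.i7, f"{self.sample_id} i7"))
        if self.i5 is not None:
            object.__setattr__(
                self, "i5", _check_dna(self.i5, f"{self.sample_id} i5")
            )


Scheme = Literal["single", "combinatorial_dual", "unique_dual"]


class SampleSheet:
    """An ordered collection of :class:`IndexPair` with a derived scheme."""

    def __init__(self, entries: Iterable[IndexPair]):
        self.entries: list[IndexPair] = list(entries)
        if not self.entries:
            raise ValueError("sample sheet must contain at least one entry")
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        has_i5 = {e.i5 is not None for e in self.entries}
        if len(has_i5) > 1:
            raise ValueError("mixed presence/absence of i5 across entries")
        # mixed index lengths within a side are rejected rather than padded
        for side in ("i7", "i5"):
            lengths = {len(getattr(e, side)) for e in self.entries
                       if getattr(e, side) is not None}
            if len(lengths) > 1:
                raise ValueError(f"{side} indexes have mixed lengths {sorted(lengths)}")
        self.scheme: Scheme = classify_scheme(self)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def is_dual(self) -> bool:
        return self.entries[0].i5 is not None

    def i7_indexes(self) -> list[str]:
        return [e.i7 for e in self.entries]

    def i5_indexes(self) -> list[str]:
        return [e.i5 for e in self.entries if e.i5 is not None]

    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def to_single_index(self) -> "SampleSheet":
        """The same samples demultiplexed by i7 only (drops i5)."""
        return SampleSheet(IndexPair(e.sample_id, e.i7) for e in self.entries)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "SampleSheet":
        """Read ``sample_id,i7[,i5]`` (comma or tab separated by extension)."""
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        required = {"sample_id", "i7"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: header must contain {sorted(required)}")
        entries = []
        for _, row in df.iterrows():
            i5 = row.get("i5")
            if pd.isna(i5):
                i5 = None
            entries.append(IndexPair(str(row["sample_id"]), row["i7"], i5))
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids(),
                "i7": self.i7_indexes(),
                "i5": [e.i5 for e in self.entries],
            }
        )

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def classify_scheme(sheet: SampleSheet) -> Scheme:
    """single / combinatorial_dual / unique_dual, per index reuse."""
    entries = sheet.entries
    if entries[0].i5 is None:
        return "single"
    i7s = [e.i7 for e in entries]
    i5s = [e.i5 for e in entries]
    if len(set(i7s)) == len(i7s) and len(set(i5s)) == len(i5s):
        return "unique_dual"
    return "combinatorial_dual"


@dataclass(frozen=True)
class Violation:
    kind: str  # "distance" or "scheme"
    side: str | None = None
    sample_a: str | None = None
    sample_b: str | None = None
    index_a: str | None = None
    index_b: str | None = None
    distance: int | None = None
    message: str = ""


def validate_index_set(sheet: SampleSheet, min_distance: int = 2) -> list[Violation]:
    """All pairs of same-side indexes closer than ``min_distance`` edits,
    plus a scheme warning when the sheet is not unique-dual.

    An empty list means the set passes.  i7 and i5 sides are checked
    independently, never against each other.
    """
    violations: list[Violation] = []
    sides = [("i7", [(e.sample_id, e.i7) for e in sheet.entries])]
    if sheet.is_dual:
        sides.append(("i5", [(e.sample_id, e.i5) for e in sheet.entries]))
    for side, indexed in sides:
        for i in range(len(indexed)):
            for j in range(i + 1, len(indexed)):
                (sa, xa), (sb, xb) = indexed[i], indexed[j]
                d = levenshtein(xa, xb)
                if d < min_distance:
                    violations.append(
                        Violation(
                            kind="distance",
                            side=side,
                            sample_a=sa,
                            sample_b=sb,
                            index_a=xa,
                            index_b=xb,
                            distance=d,
                            message=(
                                f"{side} indexes {xa}/{xb} of samples {sa}/{sb} "
                                f"are {d} edit(s) apart (< {min_distance})"
                            ),
                        )
                    )
    if sheet.scheme != "unique_dual" and len(sheet) > 1:
        violations.append(
            Violation(
                kind="scheme",
                message=(
                    f"scheme is {sheet.scheme!r}: index-hopped reads cannot all "
                    "be filtered by unanticipated index combinations"
                ),
            )
        )
    return violations


def expected_combinations(sheet: SampleSheet) -> dict[tuple[str, str], str]:
    """The anticipated (i7, i5) combinations of a dual-indexed sheet, mapped
    to their sample ids."""
    if not sheet.is_dual:
        raise ValueError("expected_combinations requires a dual-indexed sheet")
    combos: dict[tuple[str, str], str] = {}
    for e in sheet.entries:
        key = (e.i7, e.i5)  # type: ignore[arg-type]
        if key in combos:
            raise ValueError(
                f"samples {combos[key]!r} and {e.sample_id!r} share the "
                f"index combination {key}"
            )
        combos[key] = e.sample_id
    return combos


@dataclass(frozen=True)
class Assignment:
    """Outcome of matching one read's observed indexes to a sheet."""

    status: str  # sample_id | "undetermined" | "filtered_hopped"
    sample_id: str | None
    i7_mismatches: int | None = None
    i5_mismatches: int | None = None

    @property
    def assigned(self) -> bool:
        return self.sample_id is not None

    @property
    def perfect(self) -> bool:
        """Both observed indexes match the assigned sample with 0 mismatches."""
        return self.assigned and not self.i7_mismatches and not self.i5_mismatches


def _match_side(observed: str, indexes: Sequence[str], max_mismatch: int):
    """Unique sheet index within ``max_mismatch`` Hamming errors, or None.

    Returns (matched_index, mismatches); (None, None) when no index is close
    enough or the best distance is achieved by more than one sheet index.
    """
    best: str | None = None
    best_d: int | None = None
    ambiguous = False
    for idx in set(indexes):
        if len(idx) != len(observed):
            continue
        d = hamming(observed, idx)
        if best_d is None or d < best_d:
            best, best_d, ambiguous = idx, d, False
        elif d == best_d:
            ambiguous = True
    if best_d is None or best_d > max_mismatch or ambiguous:
        return None, None
    return best, best_d


def assign_read(
    observed_i7: str,
    observed_i5: str | None,
    sheet: SampleSheet,
    max_mismatch: int = 1,
) -> Assignment:
    """Assign one read's observed index(es) to a sample.

    Each side is matched to the unique sheet index within ``max_mismatch``
    Hamming errors.  For dual sheets, a matched-but-unanticipated (i7, i5)
    combination is classified ``filtered_hopped``; an unmatched or ambiguous
    side yields ``undetermined``.  Single-index sheets use only i7 and can
    never return ``filtered_hopped``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    observed_i7 = observed_i7.upper()
    i7, d7 = _match_side(observed_i7, sheet.i7_indexes(), max_mismatch)
    if i7 is None:
        return Assignment(UNDETERMINED, None)
    if not sheet.is_dual or observed_i5 is None:
        samples = [e.sample_id for e in sheet.entries if e.i7 == i7]
        if len(samples) != 1:
            return Assignment(UNDETERMINED, None)
        return Assignment(samples[0], samples[0], i7_mismatches=d7)
    observed_i5 = observed_i5.upper()
    i5, d5 = _match_side(observed_i5, sheet.i5_indexes(), max_mismatch)
    if i5 is None:
        return Assignment(UNDETERMINED, None)
    combos = expected_combinations(sheet)
    sample = combos.get((i7, i5))
    if sample is None:
        return Assignment(FILTERED_HOPPED, None, i7_mismatches=d7, i5_mismatches=d5)
    return Assignment(sample, sample, i7_mismatches=d7, i5_mismatches=d5)
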