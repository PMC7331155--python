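"""Sequencing-library structure templates and primer compatibility checks.

Three presets are provided, all written 5'->3' for each strand of the final
double-stranded library:

``TRUSEQ``
    The standard dual-indexed Illumina TruSeq structure: P7/P5 flow-cell
    adapters, i7/i5 sample indexes, and the standard R1/R2 priming sites.
``INDROP_V2``
    The single-indexed inDrop V2 scRNA-seq structure.  Its barcode side
    carries a *truncated* version of the standard R1 (i5) priming site and
    its transcript side an obsolete priming site; both are custom primers
    that are incompatible with standard Illumina primer pools.
``TRUDROP``
    The dual-indexed TruSeq-inDrop hybrid: inDrop cell barcodes and UMI on
    the P5 side behind the *standard* TruSeq priming sites, with unique dual
    (i7, i5) sample indexes.  The cell barcode + UMI read is read 1.

Index-read primers are never part of the library itself; following Illumina
convention they are derived as the reverse complement of the priming site
that flanks the index on the template.  This derivation exposes the central
compatibility hazard of the V2 design: its i7 index primer shares a 13 bp
5' region with the standard TruSeq index primer, enabling mis-priming when
V2 libraries are pooled with standard libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "SequenceSegment",
    "ReadRole",
    "LibraryStructure",
    "PrimerSet",
    "revcomp",
    "get_structure",
    "render_template",
    "derive_sequencing_primers",
    "longest_shared_prefix",
    "mispriming_report",
    "structure_to_config",
    "structure_from_config",
    "save_structure",
    "load_structure",
    "STRUCTURE_NAMES",
    "W1_SPACER",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SEGMENT_ROLES = frozenset(
    {
        "flowcell_adapter",
        "sample_index",
        "priming_site",
        "cell_barcode",
        "spacer",
        "umi",
        "polyT",
        "insert",
    }
)

#: fixed sequences printed for the three structures
P7_ADAPTER = "CAAGCAGAAGACGGCATACGAGAT"
P5_ADAPTER = "AATGATACGGCGACCACCGAGATCTACAC"
TRUSEQ_R1_SITE = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"
TRUSEQ_R2_SITE = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
#: truncated R1 site used on the V2 barcode side (full R1 minus leading ACA)
V2_BARCODE_SITE = "CTCTTTCCCTACACGACGCTCTTCCGATCT"
#: obsolete priming site on the V2 transcript side, added via random hexamer
V2_TRANSCRIPT_SITE = "GGTCTCGGCATTCCTGCTGAACCGCTCTTCCGATCT"
#: the fixed spacer between the two inDrop cell-barcode halves
W1_SPACER = "GAGTGATTGCTTGTGACGCCTT"
POLYT = "T" * 19

STRUCTURE_NAMES = ("TRUSEQ", "INDROP_V2", "TRUDROP")

#: how placeholder tokens are printed in the published templates
_PAPER_TOKENS = {
    "i7": "[i7]",
    "i5": "[i5]",
    "cell_barcode_1": "[cell barcode 1]",
    "cell_barcode_2": "[cell barcode 2]",
    "umi": "[UMI]",
    "insert": "NNNNNN",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence over {A, C, G, T, N}.

    Case-insensitive on input; output is upper case.  Raises ``ValueError``
    naming the first offending position for non-IUPAC characters.
    """
    s = seq.upper()
    for pos, ch in enumerate(s):
        if ch not in "ACGTN":
            raise ValueError(
                f"non-ACGTN character {ch!r} at position {pos} in sequence"
            )
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceSegment:
    """One ordered building block of a library strand.

    Exactly one of ``sequence`` (fixed bases) or ``placeholder`` (a token
    such as ``i7`` or ``cell_barcode_1``) is set.  ``length_range`` is the
    inclusive (min, max) length in bases; ``max`` may be ``None`` for
    unbounded segments (the transcript insert).
    """

    label: str
    role: str
    sequence: str | None = None
    placeholder: str | None = None
    length_range: tuple[int, int | None] | None = None

    def __post_init__(self) -> None:
        if self.role not in SEGMENT_ROLES:
            raise ValueError(f"unknown segment role {self.role!r}")
        if (self.sequence is None) == (self.placeholder is None):
            raise ValueError(
                f"segment {self.label!r}: exactly one of sequence/placeholder required"
            )
        if self.sequence is not None:
            seq = self.sequence.upper()
            for pos, ch in enumerate(seq):
                if ch not in "ACGTN":
                    raise ValueError(
                        f"segment {self.label!r}: non-ACGTN character {ch!r} "
                        f"at position {pos}"
                    )
            object.__setattr__(self, "sequence", seq)
            if self.length_range is None:
                object.__setattr__(self, "length_range", (len(seq), len(seq)))
        elif self.length_range is None:
            raise ValueError(
                f"placeholder segment {self.label!r} requires a length_range"
            )

    @property
    def is_fixed(self) -> bool:
        return self.sequence is not None

    def render(self, placeholder_style: str = "paper") -> str:
        if self.is_fixed:
            return self.sequence  # type: ignore[return-value]
        if placeholder_style == "paper":
            return _PAPER_TOKENS.get(self.placeholder, f"[{self.placeholder}]")
        if placeholder_style == "brackets":
            return f"[{self.placeholder}]"
        raise ValueError(f"unknown placeholder style {placeholder_style!r}")


@dataclass(frozen=True)
class ReadRole:
    """Which side a sequencing read covers and where it primes from.

    ``primes_from`` names a priming-site segment of the structure.  For the
    two insert reads the sequencing primer *is* that site; for index reads
    the primer is its reverse complement (the index is read off the opposite
    strand).  ``covers`` lists the segment labels the read proceeds into and
    may be empty when the covered region is not part of the template (the
    generic TruSeq insert).
    """

    side: str
    primes_from: str
    covers: tuple[str, ...] = ()


@dataclass(frozen=True)
class LibraryStructure:
    name: str
    p5_side: tuple[SequenceSegment, ...]
    p7_side: tuple[SequenceSegment, ...]
    read_roles: Mapping[str, ReadRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = {seg.label for seg in self.p5_side + self.p7_side}
        for read, role in self.read_roles.items():
            if role.side not in ("p5_side", "p7_side"):
                raise ValueError(f"{read}: unknown side {role.side!r}")
            missing = [l for l in (role.primes_from, *role.covers) if l not in labels]
            if missing:
                raise ValueError(
                    f"{self.name} {read}: read_roles reference unknown segments {missing}"
                )

    def side(self, which: str) -> tuple[SequenceSegment, ...]:
        if which not in ("p5_side", "p7_side"):
            raise ValueError(f"side must be 'p5_side' or 'p7_side', got {which!r}")
        return getattr(self, which)

    def segment(self, label: str) -> SequenceSegment:
        for seg in self.p5_side + self.p7_side:
            if seg.label == label:
                return seg
        raise KeyError(label)


@dataclass(frozen=True)
class PrimerSet:
    """Sequencing primers derived from a structure's priming sites."""

    structure: str
    read1_primer: str | None = None
    read2_primer: str | None = None
    index1_primer: str | None = None
    index2_primer: str | None = None

    def as_dict(self) -> dict[str, str]:
        out = {}
        for role in ("read1", "read2", "index1", "index2"):
            primer = getattr(self, f"{role}_primer")
            if primer is not None:
                out[role] = primer
        return out


def _index_placeholder(name: str, token: str) -> SequenceSegment:
    # sample indexes in the presets span 6 (V2) to 10 (extended IDT sets) bases
    return SequenceSegment(name, "sample_index", placeholder=token, length_range=(6, 10))


def _barcode_umi_segments() -> tuple[SequenceSegment, ...]:
    return (
        SequenceSegment(
            "cell_barcode_1", "cell_barcode", placeholder="cell_barcode_1",
            length_range=(8, 11),
        ),
        SequenceSegment("w1", "spacer", sequence=W1_SPACER),
        SequenceSegment(
            "cell_barcode_2", "cell_barcode", placeholder="cell_barcode_2",
            length_range=(8, 8),
        ),
        SequenceSegment("umi", "umi", placeholder="umi", length_range=(6, 6)),
        SequenceSegment("polyt", "polyT", sequence=POLYT),
    )


def _insert_segment() -> SequenceSegment:
    # rendered as the printed NNNNNN random-hexamer prefix; length unbounded
    return SequenceSegment(
        "insert", "insert", placeholder="insert", length_range=(6, None)
    )


def _build_truseq() -> LibraryStructure:
    return LibraryStructure(
        name="TRUSEQ",
        p7_side=(
            SequenceSegment("p7_adapter", "flowcell_adapter", sequence=P7_ADAPTER),
            _index_placeholder("i7", "i7"),
            SequenceSegment("truseq_r2", "priming_site", sequence=TRUSEQ_R2_SITE),
        ),
        p5_side=(
            SequenceSegment("p5_adapter", "flowcell_adapter", sequence=P5_ADAPTER),
            _index_placeholder("i5", "i5"),
            SequenceSegment("truseq_r1", "priming_site", sequence=TRUSEQ_R1_SITE),
        ),
        read_roles={
            "read1": ReadRole("p5_side", "truseq_r1"),
            "read2": ReadRole("p7_side", "truseq_r2"),
            "index1": ReadRole("p7_side", "truseq_r2"),
            "index2": ReadRole("p5_side", "truseq_r1"),
        },
    )


def _build_indrop_v2() -> LibraryStructure:
    # single-indexed; reads are flipped relative to TruSeq: read 1 is the
    # transcript (off the obsolete P5-side site), read 2 the barcode + UMI
    return LibraryStructure(
        name="INDROP_V2",
        p7_side=(
            SequenceSegment("p7_adapter", "flowcell_adapter", sequence=P7_ADAPTER),
            _index_placeholder("i7", "i7"),
            SequenceSegment("v2_r1_trunc", "priming_site", sequence=V2_BARCODE_SITE),
            *_barcode_umi_segments(),
        ),
        p5_side=(
            SequenceSegment("p5_adapter", "flowcell_adapter", sequence=P5_ADAPTER),
            SequenceSegment("v2_obsolete", "priming_site", sequence=V2_TRANSCRIPT_SITE),
            _insert_segment(),
        ),
        read_roles={
            "read1": ReadRole("p5_side", "v2_obsolete", ("insert",)),
            "read2": ReadRole(
                "p7_side",
                "v2_r1_trunc",
                ("cell_barcode_1", "w1", "cell_barcode_2", "umi", "polyt"),
            ),
            "index1": ReadRole("p7_side", "v2_r1_trunc"),
        },
    )


def _build_trudrop() -> LibraryStructure:
    return LibraryStructure(
        name="TRUDROP",
        p7_side=(
            SequenceSegment("p7_adapter", "flowcell_adapter", sequence=P7_ADAPTER),
            _index_placeholder("i7", "i7"),
            SequenceSegment("truseq_r2", "priming_site", sequence=TRUSEQ_R2_SITE),
            _insert_segment(),
        ),
        p5_side=(
            SequenceSegment("p5_adapter", "flowcell_adapter", sequence=P5_ADAPTER),
            _index_placeholder("i5", "i5"),
            SequenceSegment("truseq_r1", "priming_site", sequence=TRUSEQ_R1_SITE),
            *_barcode_umi_segments(),
        ),
        read_roles={
            "read1": ReadRole(
                "p5_side",
                "truseq_r1",
                ("cell_barcode_1", "w1", "cell_barcode_2", "umi", "polyt"),
            ),
            "read2": ReadRole("p7_side", "truseq_r2", ("insert",)),
            "index1": ReadRole("p7_side", "truseq_r2"),
            "index2": ReadRole("p5_side", "truseq_r1"),
        },
    )


_BUILDERS = {
    "TRUSEQ": _build_truseq,
    "INDROP_V2": _build_indrop_v2,
    "TRUDROP": _build_trudrop,
}


def get_structure(name: str) -> LibraryStructure:
    """Return a library-structure preset by name.

    Valid names: ``TRUSEQ``, ``INDROP_V2``, ``TRUDROP`` (case-insensitive).
    """
    key = name.upper()
    if key not in _BUILDERS:
        raise KeyError(
            f"unknown structure {name!r}; valid names: {', '.join(STRUCTURE_NAMES)}"
        )
    return _BUILDERS[key]()


def render_template(
    structure: LibraryStructure, side: str, placeholder_style: str = "paper"
) -> str:
    """Concatenate a side's segments into the 5'->3' template string.

    With the default ``paper`` placeholder dialect the output reproduces the
    published template strings exactly (after whitespace normalisation).
    """
    return "".join(seg.render(placeholder_style) for seg in structure.side(side))


def derive_sequencing_primers(structure: LibraryStructure) -> PrimerSet:
    """Derive the four sequencing primers from a structure's read roles.

    Read primers equal their priming-site sequence; index-read primers are
    the reverse complement of the priming site flanking the index, so an
    index primer's 5' end is the reverse complement of the site's 3' end.
    """
    primers: dict[str, str | None] = {
        "read1_primer": None,
        "read2_primer": None,
        "index1_primer": None,
        "index2_primer": None,
    }
    for read, role in structure.read_roles.items():
        site = structure.segment(role.primes_from)
        if site.role != "priming_site" or site.sequence is None:
            raise ValueError(
                f"{structure.name} {read}: {role.primes_from!r} is not a fixed "
                "priming site"
            )
        if read.startswith("index"):
            primers[f"{read}_primer"] = revcomp(site.sequence)
        else:
            primers[f"{read}_primer"] = site.sequence
    return PrimerSet(structure=structure.name, **primers)


def longest_shared_prefix(a: str, b: str) -> int:
    """Length of the longest exact common prefix of two sequences."""
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    n = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            break
        n += 1
    return n


def mispriming_report(
    a: LibraryStructure, b: LibraryStructure, threshold: int = 13
) -> pd.DataFrame:
    """Score cross-structure primer compatibility by shared 5' prefix.

    For each read role present in both structures the two competing primers
    (the primers that would be pooled for the same read of a shared run) are
    compared by :func:`longest_shared_prefix`.  A pair is ``flagged`` when
    the shared prefix reaches ``threshold`` bases (default 13, the observed
    hazard length between the V2 and TruSeq index primers).  Identical
    primers are reported with ``identical=True`` — informational for shared
    standard primers rather than a hazard.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    pa = derive_sequencing_primers(a).as_dict()
    pb = derive_sequencing_primers(b).as_dict()
    rows = []
    for role in ("read1", "read2", "index1", "index2"):
        if role not in pa or role not in pb:
            continue
        shared = longest_shared_prefix(pa[role], pb[role])
        rows.append(
            {
                "role": role,
                "primer_a": pa[role],
                "primer_b": pb[role],
                "shared_prefix": shared,
                "identical": pa[role] == pb[role],
                "flagged": shared >= threshold,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-config import/export


def structure_to_config(structure: LibraryStructure) -> dict:
    def seg_record(seg: SequenceSegment) -> dict:
        rec: dict = {"label": seg.label, "role": seg.role}
        if seg.is_fixed:
            rec["sequence"] = seg.sequence
        else:
            rec["placeholder"] = seg.placeholder
        rec["length_range"] = list(seg.length_range)  # type: ignore[arg-type]
        return rec

    return {
        "name": structure.name,
        "p5_side": [seg_record(s) for s in structure.p5_side],
        "p7_side": [seg_record(s) for s in structure.p7_side],
        "read_roles": {
            read: {
                "side": role.side,
                "primes_from": role.primes_from,
                "covers": list(role.covers),
            }
            for read, role in structure.read_roles.items()
        },
    }


def structure_from_config(config: Mapping) -> LibraryStructure:
    def seg(rec: Mapping) -> SequenceSegment:
        lr = rec.get("length_range")
        return SequenceSegment(
            label=rec["label"],
            role=rec["role"],
            sequence=rec.get("sequence"),
            placeholder=rec.get("placeholder"),
            length_range=tuple(lr) if lr is not None else None,
        )

    return LibraryStructure(
        name=config["name"],
        p5_side=tuple(seg(r) for r in config["p5_side"]),
        p7_side=tuple(seg(r) for r in config["p7_side"]),
        read_roles={
            read: ReadRole(r["side"], r["primes_from"], tuple(r.get("covers", ())))
            for read, r in config.get("read_roles", {}).items()
        },
    )


def save_structure(structure: LibraryStructure, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(structure_to_config(structure), fh, sort_keys=False)


def load_structure(path) -> LibraryStructure:
    with open(path) as fh:
        return structure_from_config(yaml.safe_load(fh))
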