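"""Parsing of inDrop barcode reads and per-run cycle region maps.

An inDrop barcode read is laid out as::

    [cell barcode 1 (8-11 nt)] [W1 spacer (22 nt)] [cell barcode 2 (8 nt)]
    [UMI (6 nt)] [poly-T ...]

The first barcode half has variable length, so the parser anchors on the
fixed W1 spacer: it scans the admissible offsets (the bc1 length range) and
accepts the best Hamming match within a mismatch tolerance.  A 50-cycle read
uses at least 8+22+8+6 = 44 cycles, leaving up to 6 trailing cycles that run
into the poly-T/poly-A stretch.

Region maps translate the published run layouts into 0-based, half-open
cycle intervals per read, for slicing per-cycle quality summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .structures import W1_SPACER

__all__ = [
    "ParsedBarcode",
    "Region",
    "RegionMap",
    "parse_barcode_read",
    "region_map",
    "REGION_PRESETS",
]


@dataclass(frozen=True)
class ParsedBarcode:
    """Decomposition of one barcode read; ``valid`` is False when the W1
    spacer could not be located (or a whitelist check failed), with the
    reason in ``diagnostic``."""

    bc1: str | None
    bc2: str | None
    umi: str | None
    bc1_length: int | None
    w1_mismatches: int | None
    polyT_fraction: float | None
    valid: bool
    diagnostic: str = ""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def parse_barcode_read(
    seq: str,
    w1: str = W1_SPACER,
    max_w1_mismatch: int = 2,
    bc1_lengths: tuple[int, ...] = (8, 9, 10, 11),
    bc1_whitelist=None,
    bc2_whitelist=None,
    whitelist_mismatch: int = 0,
) -> ParsedBarcode:
    """Split a barcode read into (bc1, bc2, UMI) by anchoring on W1.

    The W1 spacer is searched at each candidate bc1 length; the offset with
    the fewest mismatches wins (ties break to the shortest bc1).  A read
    whose best offset exceeds ``max_w1_mismatch`` is returned as an invalid
    record rather than raising.  Optional whitelists restrict bc1/bc2 to
    known bead barcodes, exactly or within ``whitelist_mismatch`` Hamming
    errors.
    """
    seq = seq.upper()
    min_len = min(bc1_lengths) + len(w1) + 8 + 6
    if len(seq) < min_len:
        return ParsedBarcode(
            None, None, None, None, None, None, False,
            f"read length {len(seq)} < minimum {min_len}",
        )
    best_off, best_mm = None, None
    for off in sorted(bc1_lengths):
        window = seq[off : off + len(w1)]
        if len(window) < len(w1):
            continue
        mm = _hamming(window, w1)
        if best_mm is None or mm < best_mm:
            best_off, best_mm = off, mm
    if best_mm is None or best_mm > max_w1_mismatch:
        return ParsedBarcode(
            None, None, None, None, best_mm, None, False,
            f"W1 not found within {max_w1_mismatch} mismatches "
            f"(best {best_mm} at any offset in {sorted(bc1_lengths)})",
        )
    bc1 = seq[:best_off]
    pos = best_off + len(w1)
    bc2 = seq[pos : pos + 8]
    umi = seq[pos + 8 : pos + 14]
    if len(bc2) < 8 or len(umi) < 6:
        return ParsedBarcode(
            bc1, None, None, best_off, best_mm, None, False,
            "read too short after W1 for barcode 2 + UMI",
        )
    tail = seq[pos + 14 :]
    polyt = tail.count("T") / len(tail) if tail else None
    valid = True
    diagnostic = ""
    for name, bc, wl in (("bc1", bc1, bc1_whitelist), ("bc2", bc2, bc2_whitelist)):
        if wl is None:
            continue
        wl = set(wl)
        if bc in wl:
            continue
        if whitelist_mismatch > 0 and any(
            len(w) == len(bc) and _hamming(bc, w) <= whitelist_mismatch for w in wl
        ):
            continue
        valid = False
        diagnostic = f"{name} {bc} not in whitelist"
        break
    return ParsedBarcode(bc1, bc2, umi, best_off, best_mm, polyt, valid, diagnostic)


@dataclass(frozen=True)
class Region:
    """A named cycle interval within one read (0-based, half-open)."""

    read: str
    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionMap:
    """Per-read cycle regions of a run preset.

    Within each read the regions are non-overlapping, ordered, and cover the
    declared read length exactly.
    """

    preset: str
    read_lengths: dict[str, int]
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        for read, length in self.read_lengths.items():
            regs = self.for_read(read)
            pos = 0
            for r in regs:
                if r.start != pos or r.end <= r.start:
                    raise ValueError(
                        f"{self.preset}/{read}: regions must be ordered, "
                        f"non-overlapping and contiguous (at {r.name})"
                    )
                pos = r.end
            if pos != length:
                raise ValueError(
                    f"{self.preset}/{read}: regions cover {pos} of {length} cycles"
                )

    def for_read(self, read: str) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.read == read)

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def intervals(self, read: str) -> dict[str, tuple[int, int]]:
        """``{region name: (start, end)}`` for one read, ready for
        :func:`trudrop.qc.region_mean_quality`."""
        return {r.name: (r.start, r.end) for r in self.for_read(read)}


def _v2_nextseq() -> RegionMap:
    # 100-cycle transcript read, 6-cycle i7 read, 50-cycle barcode + UMI
    # read; the last 6 barcode-read cycles run into the poly-A tail.
    return RegionMap(
        preset="V2_NEXTSEQ",
        read_lengths={"read1": 100, "index1": 6, "read2": 50},
        regions=(
            Region("read1", "transcript", 0, 100),
            Region("index1", "index1", 0, 6),
            Region("read2", "barcode_umi", 0, 50),
        ),
    )


def _trudrop() -> RegionMap:
    # PE150 with 8+8 index reads.  The barcode read's published QC regions
    # are cycles 1-11 and 31-50 (bc1 and bc2+UMI), treating W1 as cycles
    # 12-30 even though the spacer is 22 nt; cycles beyond 50 are trimmed.
    # The transcript read's QC emphasis is its first 100 cycles, matching
    # the shorter V2 runs.
    return RegionMap(
        preset="TRUDROP",
        read_lengths={"read1": 150, "index1": 8, "index2": 8, "read2": 150},
        regions=(
            Region("read1", "barcode1", 0, 11),
            Region("read1", "w1", 11, 30),
            Region("read1", "barcode2_umi", 30, 50),
            Region("read1", "polyT", 50, 150),
            Region("index1", "index1", 0, 8),
            Region("index2", "index2", 0, 8),
            Region("read2", "transcript", 0, 100),
            Region("read2", "transcript_trimmed", 100, 150),
        ),
    )


REGION_PRESETS = {
    "V2_NEXTSEQ": _v2_nextseq,
    "TRUDROP": _trudrop,
    "TRUDROP_NOVASEQ": _trudrop,
}


def region_map(preset: str) -> RegionMap:
    """Cycle region map for a run preset (``V2_NEXTSEQ`` or ``TRUDROP``)."""
    key = preset.upper()
    if key not in REGION_PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; valid: {sorted(set(REGION_PRESETS))}"
        )
    return REGION_PRESETS[key]()
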