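"""Synthetic pooled-run simulator with index hopping, FASTQ output, and
demultiplexing.

The simulator emulates the demultiplexing-relevant features of a pooled
sequencing run of inDrop-style libraries:

* each read carries a ground-truth sample of origin, cell barcode halves
  (bc1 of 8-11 nt, bc2 of 8 nt), a 6 nt UMI, and observed i7/i5 indexes;
* index hopping swaps one side's index for another pooled sample's index on
  that side.  For dual-indexed sheets each side hops independently at rate
  ``hop_rate/2`` (so the per-read probability of at least one hopped side is
  ~``hop_rate`` for small rates, and single-side hops dominate); for
  single-indexed sheets the lone i7 hops at the full ``hop_rate``;
* the barcode read is laid out ``bc1 + W1 + bc2 + UMI + poly-T`` and the
  transcript read is random sequence, per the structure preset's read roles;
* per-cycle qualities follow a configurable model (constant Q37 by default,
  optionally a per-cycle profile with Gaussian spread).

It does NOT model base-calling errors in the index reads, flow-cell optics,
clustering efficiency, or amplification chemistry: observed indexes differ
from the sample's true indexes only by hopping.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .indexes import (
    FILTERED_HOPPED,
    UNDETERMINED,
    Assignment,
    IndexPair,
    SampleSheet,
    assign_read,
    levenshtein,
)
from .structures import LibraryStructure, W1_SPACER, get_structure

__all__ = [
    "QualityModel",
    "SimulatedRead",
    "ReadAssignment",
    "DemuxReport",
    "DemuxMetrics",
    "CollisionLoss",
    "simulate_pool",
    "write_fastq",
    "read_fastq_indexes",
    "demultiplex",
    "score_demux",
    "single_index_collision_loss",
    "random_index_set",
    "make_sample_sheet",
    "make_barcode_whitelists",
    "DEFAULT_READ_LENGTHS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default (read1, read2) lengths per structure preset: the V2 NextSeq runs
#: used a 100-cycle transcript read and a 50-cycle barcode read; TruDrop
#: runs are PE150.
DEFAULT_READ_LENGTHS = {"TRUDROP": (150, 150), "INDROP_V2": (100, 50)}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


@dataclass(frozen=True)
class QualityModel:
    """Per-cycle Phred quality model.

    ``profile`` is either a scalar mean quality applied to every cycle or a
    per-cycle array (shorter profiles are padded by repeating the last
    value).  ``sd`` adds independent Gaussian spread per base before
    rounding and clipping to [2, 40].
    """

    profile: float | Sequence[float] = 37.0
    sd: float = 0.0

    def sample(self, rng: np.random.Generator, length: int) -> np.ndarray:
        prof = np.asarray(self.profile, dtype=float)
        if prof.ndim == 0:
            means = np.full(length, float(prof))
        else:
            means = np.empty(length)
            n = min(length, prof.size)
            means[:n] = prof[:n]
            means[n:] = prof[-1]
        q = means if self.sd == 0 else means + rng.normal(0.0, self.sd, size=length)
        return np.clip(np.rint(q), 2, 40).astype(int)


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read pair with ground truth."""

    read_id: str
    true_sample: str
    bc1: str
    bc2: str
    umi: str
    observed_i7: str
    observed_i5: str | None
    hopped_i7: bool
    hopped_i5: bool
    read1_seq: str
    read2_seq: str
    read1_quals: tuple[int, ...]
    read2_quals: tuple[int, ...]

    @property
    def hopped(self) -> bool:
        return self.hopped_i7 or self.hopped_i5


def random_index_set(
    n: int, length: int = 8, min_distance: int = 3, seed: int = 0
) -> list[str]:
    """Greedily draw ``n`` random indexes with pairwise edit distance >=
    ``min_distance`` (for synthesising multi-sample sheets)."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError(
                f"could not place {n} indexes of length {length} at distance "
                f">= {min_distance}"
            )
        cand = _random_seq(rng, length)
        if all(levenshtein(cand, x) >= min_distance for x in out):
            out.append(cand)
    return out


def make_sample_sheet(
    n_samples: int,
    dual: bool = True,
    index_length: int = 8,
    min_distance: int = 3,
    seed: int = 0,
) -> SampleSheet:
    """A synthetic unique-dual (or single-indexed) sheet of ``n_samples``."""
    i7s = random_index_set(n_samples, index_length, min_distance, seed)
    if dual:
        i5s = random_index_set(n_samples, index_length, min_distance, seed + 10_000)
        entries = [
            IndexPair(f"sample{i + 1}", i7, i5)
            for i, (i7, i5) in enumerate(zip(i7s, i5s))
        ]
    else:
        entries = [IndexPair(f"sample{i + 1}", i7) for i, i7 in enumerate(i7s)]
    return SampleSheet(entries)


def make_barcode_whitelists(
    n_bc1: int = 384,
    n_bc2: int = 384,
    seed: int = 0,
    bc1_lengths: Sequence[int] = (8, 9, 10, 11),
) -> tuple[list[str], list[str]]:
    """Distinct synthetic bead-barcode whitelists (bc1 cycles through the
    variable length range; bc2 is fixed 8 nt)."""
    rng = np.random.default_rng(seed)
    bc1: list[str] = []
    seen = set()
    while len(bc1) < n_bc1:
        cand = _random_seq(rng, bc1_lengths[len(bc1) % len(bc1_lengths)])
        if cand not in seen:
            seen.add(cand)
            bc1.append(cand)
    bc2: list[str] = []
    seen = set()
    while len(bc2) < n_bc2:
        cand = _random_seq(rng, 8)
        if cand not in seen:
            seen.add(cand)
            bc2.append(cand)
    return bc1, bc2


def _hop_destination(
    rng: np.random.Generator, sheet: SampleSheet, side: str, own_sample: str
) -> str:
    others = [
        getattr(e, side) for e in sheet.entries if e.sample_id != own_sample
    ]
    return others[rng.integers(0, len(others))]


def simulate_pool(
    sheet: SampleSheet,
    structure: LibraryStructure | str = "TRUDROP",
    reads_per_sample: int | Mapping[str, int] = 1000,
    hop_rate: float = 0.0485,
    seed: int = 0,
    cells_per_sample: int | None = None,
    barcode_whitelists: tuple[Sequence[str], Sequence[str]] | None = None,
    quality: QualityModel | None = None,
    read_lengths: tuple[int, int] | None = None,
    cell_sampling: str = "uniform",
) -> list[SimulatedRead]:
    """Simulate a pooled run of the sheet's samples with index hopping.

    By default every read draws fresh random barcodes (bc1 length uniform on
    8-11, bc2 of 8, UMI of 6).  With ``cells_per_sample`` set, each sample
    first draws that many cells uniformly (with replacement) from the
    barcode space defined by ``barcode_whitelists`` (default 384 x 384
    synthetic whitelists), and every read samples one of its cells — this is
    the mode used for cross-sample barcode-collision experiments.
    ``cell_sampling`` is ``"uniform"`` (cells drawn per read with
    replacement) or ``"round_robin"`` (reads cycle through the cells in
    order, giving each cell exactly ``reads_per_sample / cells_per_sample``
    reads when the counts divide evenly).

    Fully reproducible for a fixed seed.  Raises when hopping is requested
    for a 1-sample sheet (there is no foreign index to hop to).
    """
    if not 0.0 <= hop_rate <= 1.0:
        raise ValueError("hop_rate must be in [0, 1]")
    if hop_rate > 0 and len(sheet) < 2:
        raise ValueError("index hopping requires at least 2 samples in the pool")
    if isinstance(structure, str):
        structure = get_structure(structure)
    if sheet.is_dual and "index2" not in structure.read_roles:
        raise ValueError(
            f"dual-indexed sheet requires a dual-indexed structure, "
            f"got {structure.name}"
        )
    if read_lengths is None:
        read_lengths = DEFAULT_READ_LENGTHS.get(structure.name, (150, 150))
    quality = quality or QualityModel()
    rng = np.random.default_rng(seed)

    # which read is the barcode read, per the structure's read roles
    barcode_read = next(
        (
            read
            for read, role in structure.read_roles.items()
            if read in ("read1", "read2") and "cell_barcode_1" in role.covers
        ),
        "read1",
    )

    if isinstance(reads_per_sample, int):
        counts = {e.sample_id: reads_per_sample for e in sheet.entries}
    else:
        counts = dict(reads_per_sample)

    cells: dict[str, list[tuple[str, str]]] = {}
    if cells_per_sample is not None:
        bc1_wl, bc2_wl = barcode_whitelists or make_barcode_whitelists(seed=seed)
        n_space = len(bc1_wl) * len(bc2_wl)
        for e in sheet.entries:
            draws = rng.integers(0, n_space, size=cells_per_sample)
            cells[e.sample_id] = [
                (bc1_wl[d // len(bc2_wl)], bc2_wl[d % len(bc2_wl)]) for d in draws
            ]

    per_side_rate = hop_rate / 2 if sheet.is_dual else hop_rate
    # a noise-free quality model is deterministic per length: draw once
    qual_cache: dict[int, tuple[int, ...]] = {}

    def _quals(length: int) -> tuple[int, ...]:
        if quality.sd == 0:
            cached = qual_cache.get(length)
            if cached is None:
                cached = tuple(quality.sample(rng, length))
                qual_cache[length] = cached
            return cached
        return tuple(quality.sample(rng, length))

    if cell_sampling not in ("uniform", "round_robin"):
        raise ValueError(f"unknown cell_sampling {cell_sampling!r}")
    reads: list[SimulatedRead] = []
    serial = 0
    for entry in sheet.entries:
        for within in range(counts.get(entry.sample_id, 0)):
            serial += 1
            if cells_per_sample is not None:
                pool = cells[entry.sample_id]
                if cell_sampling == "round_robin":
                    bc1, bc2 = pool[within % len(pool)]
                else:
                    bc1, bc2 = pool[rng.integers(0, len(pool))]
            else:
                bc1 = _random_seq(rng, int(rng.integers(8, 12)))
                bc2 = _random_seq(rng, 8)
            umi = _random_seq(rng, 6)

            hopped_i7 = bool(rng.random() < per_side_rate)
            observed_i7 = (
                _hop_destination(rng, sheet, "i7", entry.sample_id)
                if hopped_i7
                else entry.i7
            )
            hopped_i5 = False
            observed_i5 = entry.i5
            if sheet.is_dual:
                hopped_i5 = bool(rng.random() < per_side_rate)
                if hopped_i5:
                    observed_i5 = _hop_destination(
                        rng, sheet, "i5", entry.sample_id
                    )

            bc_seq = bc1 + W1_SPACER + bc2 + umi
            bc_len = read_lengths[0 if barcode_read == "read1" else 1]
            bc_seq = (bc_seq + "T" * bc_len)[:bc_len]
            tx_len = read_lengths[1 if barcode_read == "read1" else 0]
            tx_seq = _random_seq(rng, tx_len)
            if barcode_read == "read1":
                r1, r2 = bc_seq, tx_seq
            else:
                r1, r2 = tx_seq, bc_seq
            reads.append(
                SimulatedRead(
                    read_id=f"sim:{structure.name}:{serial}",
                    true_sample=entry.sample_id,
                    bc1=bc1,
                    bc2=bc2,
                    umi=umi,
                    observed_i7=observed_i7,
                    observed_i5=observed_i5,
                    hopped_i7=hopped_i7,
                    hopped_i5=hopped_i5,
                    read1_seq=r1,
                    read2_seq=r2,
                    read1_quals=_quals(len(r1)),
                    read2_quals=_quals(len(r2)),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# FASTQ I/O


def _open_maybe_gz(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _record(read_id: str, comment: str, seq: str, quals) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=read_id, description=comment)
    rec.letter_annotations["phred_quality"] = list(quals)
    return rec


def write_fastq(
    reads: Iterable[SimulatedRead],
    r1_path: str | Path,
    r2_path: str | Path | None = None,
    i1_path: str | Path | None = None,
    i2_path: str | Path | None = None,
    index_quality: int = 37,
) -> int:
    """Write simulated reads as standard 4-line Phred+33 FASTQ.

    Index reads are emitted as separate I1/I2 files and also encoded in each
    header comment as ``i7+i5`` (bcl2fastq style).  ``.gz`` extensions gzip
    transparently.  Returns the number of read records written.
    """
    paths = {"r1": r1_path, "r2": r2_path, "i1": i1_path, "i2": i2_path}
    handles = {}
    n = 0
    try:
        for key, p in paths.items():
            if p is not None:
                try:
                    handles[key] = _open_maybe_gz(p, "w")
                except OSError as exc:
                    raise OSError(f"cannot open {key} path {p}: {exc}") from exc
        for read in reads:
            n += 1
            index_tag = read.observed_i7 + (
                f"+{read.observed_i5}" if read.observed_i5 else ""
            )
            comment = f"1:N:0:{index_tag}"
            SeqIO.write(
                _record(read.read_id, comment, read.read1_seq, read.read1_quals),
                handles["r1"],
                "fastq",
            )
            if "r2" in handles:
                SeqIO.write(
                    _record(read.read_id, comment.replace("1:N", "2:N", 1),
                            read.read2_seq, read.read2_quals),
                    handles["r2"],
                    "fastq",
                )
            if "i1" in handles:
                SeqIO.write(
                    _record(read.read_id, comment, read.observed_i7,
                            [index_quality] * len(read.observed_i7)),
                    handles["i1"],
                    "fastq",
                )
            if "i2" in handles and read.observed_i5 is not None:
                SeqIO.write(
                    _record(read.read_id, comment, read.observed_i5,
                            [index_quality] * len(read.observed_i5)),
                    handles["i2"],
                    "fastq",
                )
    finally:
        for h in handles.values():
            h.close()
    return n


def read_fastq_indexes(
    r1_path: str | Path,
    i1_path: str | Path | None = None,
    i2_path: str | Path | None = None,
):
    """Yield ``(read_id, i7, i5, read1_seq)`` from FASTQ inputs.

    Indexes come from I1/I2 files when given, otherwise from the ``i7+i5``
    header comment.  Raises on record-count mismatches between files.
    """
    with _open_maybe_gz(r1_path, "r") as fh1:
        r1_iter = SeqIO.parse(fh1, "fastq")
        i1_iter = i2_iter = None
        ctx1 = ctx2 = None
        try:
            if i1_path is not None:
                ctx1 = _open_maybe_gz(i1_path, "r")
                i1_iter = SeqIO.parse(ctx1, "fastq")
            if i2_path is not None:
                ctx2 = _open_maybe_gz(i2_path, "r")
                i2_iter = SeqIO.parse(ctx2, "fastq")
            for rec in r1_iter:
                if i1_iter is not None:
                    try:
                        i7 = str(next(i1_iter).seq)
                    except StopIteration:
                        raise ValueError(
                            f"{i1_path}: fewer records than {r1_path}"
                        ) from None
                    i5 = None
                    if i2_iter is not None:
                        try:
                            i5 = str(next(i2_iter).seq)
                        except StopIteration:
                            raise ValueError(
                                f"{i2_path}: fewer records than {r1_path}"
                            ) from None
                else:
                    # fall back to the bcl2fastq-style header comment
                    parts = rec.description.split()
                    tag = parts[-1].split(":")[-1] if parts else ""
                    if not tag:
                        raise ValueError(
                            f"{r1_path}: no index files and no index header "
                            f"comment on record {rec.id}"
                        )
                    i7, _, i5_tag = tag.partition("+")
                    i5 = i5_tag or None
                yield rec.id, i7, i5, str(rec.seq)
            for it, p in ((i1_iter, i1_path), (i2_iter, i2_path)):
                if it is not None and next(it, None) is not None:
                    raise ValueError(f"{p}: more records than {r1_path}")
        finally:
            for ctx in (ctx1, ctx2):
                if ctx is not None:
                    ctx.close()


# ---------------------------------------------------------------------------
# demultiplexing and scoring


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str  # sample_id | undetermined | filtered_hopped
    sample_id: str | None
    perfect: bool
    true_sample: str | None = None
    hopped: bool | None = None


@dataclass
class DemuxReport:
    """Per-sample tallies of a demultiplexing run.

    ``assigned_correct``/``assigned_wrong`` are populated only when ground
    truth was available (simulated input); counts always satisfy
    ``assigned + filtered_hopped + undetermined == total``.
    """

    per_sample: pd.DataFrame
    filtered_hopped: int
    undetermined: int
    total: int
    has_truth: bool

    @property
    def assigned(self) -> int:
        return int(self.per_sample["assigned"].sum())

    @property
    def percent_perfect_index_reads(self) -> float:
        """Assigned reads whose indexes match their sample exactly, as a
        percentage of assigned reads."""
        if self.assigned == 0:
            return float("nan")
        return 100.0 * self.per_sample["perfect"].sum() / self.assigned

    @property
    def misassignment_rate(self) -> float:
        if not self.has_truth:
            raise ValueError("misassignment_rate requires ground truth")
        if self.assigned == 0:
            return 0.0
        return float(self.per_sample["assigned_wrong"].sum()) / self.assigned

    def percent_of_target(self, target_reads_per_sample: int) -> pd.Series:
        from .qc import percent_of_target

        return self.per_sample["assigned"].map(
            lambda n: percent_of_target(int(n), target_reads_per_sample)
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.per_sample.copy()
        totals = df.sum(numeric_only=True)
        totals.name = "total"
        df = pd.concat([df, totals.to_frame().T])
        df.loc["total", "filtered_hopped"] = self.filtered_hopped
        df.loc["total", "undetermined"] = self.undetermined
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def demultiplex(
    source,
    sheet: SampleSheet,
    max_mismatch: int = 1,
) -> tuple[list[ReadAssignment], DemuxReport]:
    """Assign reads to samples and tally a :class:`DemuxReport`.

    ``source`` is either an iterable of :class:`SimulatedRead` (ground truth
    is then carried into the report) or a mapping of FASTQ paths with keys
    ``r1`` and optionally ``i1``/``i2``.
    """
    if isinstance(source, Mapping):
        records = (
            (rid, i7, i5, None, None)
            for rid, i7, i5, _ in read_fastq_indexes(
                source["r1"], source.get("i1"), source.get("i2")
            )
        )
    else:
        records = (
            (r.read_id, r.observed_i7, r.observed_i5, r.true_sample, r.hopped)
            for r in source
        )

    cache: dict[tuple[str, str | None], Assignment] = {}
    assignments: list[ReadAssignment] = []
    samples = sheet.sample_ids()
    tally = {
        s: {"assigned": 0, "perfect": 0, "assigned_correct": 0, "assigned_wrong": 0}
        for s in samples
    }
    filtered = undetermined = total = 0
    has_truth = False
    for rid, i7, i5, true_sample, hopped in records:
        total += 1
        key = (i7, i5)
        a = cache.get(key)
        if a is None:
            a = assign_read(i7, i5, sheet, max_mismatch)
            cache[key] = a
        if true_sample is not None:
            has_truth = True
        if a.sample_id is not None:
            t = tally[a.sample_id]
            t["assigned"] += 1
            if a.perfect:
                t["perfect"] += 1
            if true_sample is not None:
                t["assigned_correct" if a.sample_id == true_sample else
                  "assigned_wrong"] += 1
        elif a.status == FILTERED_HOPPED:
            filtered += 1
        else:
            undetermined += 1
        assignments.append(
            ReadAssignment(rid, a.status, a.sample_id, a.perfect, true_sample, hopped)
        )
    df = pd.DataFrame.from_dict(tally, orient="index")
    df.index.name = "sample_id"
    if not has_truth:
        df[["assigned_correct", "assigned_wrong"]] = pd.NA
    report = DemuxReport(
        per_sample=df,
        filtered_hopped=filtered,
        undetermined=undetermined,
        total=total,
        has_truth=has_truth,
    )
    return assignments, report


@dataclass(frozen=True)
class DemuxMetrics:
    precision: dict[str, float]
    misassignment_rate: float
    hop_capture_rate: float
    n_hopped: int
    n_assigned: int


def score_demux(
    assignments: Sequence[ReadAssignment],
    truth: Mapping[str, tuple[str, bool]] | None = None,
) -> DemuxMetrics:
    """Score assignments against ground truth.

    ``truth`` maps read_id to ``(true_sample, hopped)``; it may be omitted
    when the assignments came from simulated reads (truth embedded).  The
    hop capture rate is the fraction of hopped reads landing in
    ``filtered_hopped``; misassignment is wrong-sample assignments over all
    assignments.
    """
    correct: dict[str, int] = {}
    assigned_per: dict[str, int] = {}
    n_assigned = n_wrong = n_hopped = n_hop_filtered = 0
    for a in assignments:
        if truth is not None:
            if a.read_id not in truth:
                raise KeyError(f"read {a.read_id!r} missing from truth")
            true_sample, hopped = truth[a.read_id]
        else:
            if a.true_sample is None:
                raise ValueError(
                    "assignments carry no ground truth; pass the truth mapping"
                )
            true_sample, hopped = a.true_sample, bool(a.hopped)
        if hopped:
            n_hopped += 1
            if a.status == FILTERED_HOPPED:
                n_hop_filtered += 1
        if a.sample_id is not None:
            n_assigned += 1
            assigned_per[a.sample_id] = assigned_per.get(a.sample_id, 0) + 1
            if a.sample_id == true_sample:
                correct[a.sample_id] = correct.get(a.sample_id, 0) + 1
            else:
                n_wrong += 1
    precision = {
        s: correct.get(s, 0) / n for s, n in assigned_per.items() if n > 0
    }
    return DemuxMetrics(
        precision=precision,
        misassignment_rate=n_wrong / n_assigned if n_assigned else 0.0,
        hop_capture_rate=n_hop_filtered / n_hopped if n_hopped else 0.0,
        n_hopped=n_hopped,
        n_assigned=n_assigned,
    )


@dataclass(frozen=True)
class CollisionLoss:
    discarded: frozenset
    n_discarded: int
    n_barcodes: int

    @property
    def fraction(self) -> float:
        return self.n_discarded / self.n_barcodes if self.n_barcodes else 0.0


def single_index_collision_loss(
    assignments: Sequence[ReadAssignment],
    barcodes: Mapping[str, tuple[str, str]],
) -> CollisionLoss:
    """The single-index computational countermeasure to index hopping.

    Given per-read assignments (single-index demultiplexing output) and each
    read's parsed ``(bc1, bc2)``, any cell barcode observed in the retained
    reads of two or more samples is discarded everywhere.  Returns the
    discarded barcodes and their fraction of all distinct barcodes.
    """
    seen_in: dict[tuple[str, str], set[str]] = {}
    for a in assignments:
        if a.sample_id is None:
            continue
        bc = barcodes.get(a.read_id)
        if bc is None:
            continue
        seen_in.setdefault(bc, set()).add(a.sample_id)
    discarded = frozenset(bc for bc, samples in seen_in.items() if len(samples) >= 2)
    return CollisionLoss(discarded, len(discarded), len(seen_in))
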