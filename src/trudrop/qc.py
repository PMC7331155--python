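"""Sequencing-quality statistics: per-cycle Q30 summaries, region-weighted
mean quality, Phred error probabilities, exact Mann-Whitney tests, and
run-yield arithmetic.

The exact Mann-Whitney two-sided p-value is computed from the exact null
distribution of the U statistic for tie-free data: the number of group-label
arrangements with statistic value ``u`` equals the number of integer
partitions of ``u`` into at most ``min(n1, n2)`` parts, each of size at most
``max(n1, n2)`` (equivalently, the coefficients of the Gaussian binomial
coefficient ``[n1+n2 choose n1]_q``).  The counting is done in exact integer
arithmetic so that p-values at the 1e-9 scale carry no floating-point error;
the two-sided p is twice the smaller tail, clamped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CycleQuality",
    "ExactTestResult",
    "per_cycle_quality",
    "region_mean_quality",
    "q_to_error",
    "error_fold_change",
    "mann_whitney_counts",
    "mann_whitney_exact",
    "mann_whitney_from_samples",
    "percent_of_target",
]


@dataclass(frozen=True)
class CycleQuality:
    """Per-cycle quality summary over a set of reads.

    Arrays are indexed by cycle; ragged reads contribute only to the cycles
    they cover, so ``counts`` may decrease with cycle index.
    """

    mean_q: np.ndarray
    frac_ge: np.ndarray
    counts: np.ndarray
    q_threshold: int
    label: str = ""

    def __len__(self) -> int:
        return len(self.mean_q)


def _iter_quals(source) -> Iterable[Sequence[int]]:
    if isinstance(source, (str, Path)):
        import gzip

        from Bio import SeqIO

        path = Path(source)
        opener = (lambda p: gzip.open(p, "rt")) if path.suffix == ".gz" else open
        with opener(path) as fh:
            for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
                quals = rec.letter_annotations.get("phred_quality")
                if quals is None:
                    raise ValueError(f"{path}: record {i} has no quality scores")
                yield quals
    else:
        yield from source


def per_cycle_quality(source, q_threshold: int = 30, label: str = "") -> CycleQuality:
    """Per-cycle mean Phred score and fraction of bases >= ``q_threshold``.

    ``source`` is a FASTQ path (``.gz`` allowed) or an iterable of per-read
    integer quality sequences.
    """
    sums = np.zeros(0)
    ge = np.zeros(0, dtype=np.int64)
    counts = np.zeros(0, dtype=np.int64)
    for quals in _iter_quals(source):
        q = np.asarray(quals)
        if q.size > sums.size:
            pad = q.size - sums.size
            sums = np.pad(sums, (0, pad))
            ge = np.pad(ge, (0, pad))
            counts = np.pad(counts, (0, pad))
        sums[: q.size] += q
        ge[: q.size] += q >= q_threshold
        counts[: q.size] += 1
    if counts.size == 0:
        raise ValueError("no reads in input")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_q = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        frac = np.where(counts > 0, ge / np.maximum(counts, 1), np.nan)
    return CycleQuality(mean_q, frac, counts, q_threshold, label)


def region_mean_quality(
    cq: CycleQuality, regions: Mapping[str, tuple[int, int]]
) -> dict[str, float]:
    """Weighted mean quality per named cycle region.

    Each region ``(start, end)`` is 0-based half-open; per-cycle means are
    weighted by per-cycle base counts, matching how much each cycle
    contributed.  For uniform-length reads this reduces to a plain mean.
    """
    out: dict[str, float] = {}
    for name, (start, end) in regions.items():
        if not 0 <= start < end <= len(cq):
            raise ValueError(
                f"region {name!r} [{start}, {end}) outside read of {len(cq)} cycles"
            )
        w = cq.counts[start:end]
        if w.sum() == 0:
            raise ValueError(f"region {name!r} covers no bases")
        out[name] = float(np.average(cq.mean_q[start:end], weights=w))
    return out


def q_to_error(q: float) -> float:
    """Base-calling error probability ``p = 10**(-Q/10)``."""
    if q < 0:
        raise ValueError("quality score must be >= 0")
    return 10.0 ** (-q / 10.0)


def error_fold_change(p_before: float, p_after: float) -> float:
    """Fold decrease in error probability, ``p_before / p_after``."""
    if p_after <= 0:
        raise ValueError("p_after must be > 0")
    return p_before / p_after


def mann_whitney_counts(n1: int, n2: int) -> list[int]:
    """Exact null counts of the U statistic for group sizes (n1, n2).

    ``counts[u]`` is the number of the ``C(n1+n2, n1)`` equally likely
    group-label arrangements with U = u — the coefficient of ``q**u`` in the
    Gaussian binomial ``[n1+n2 choose n1]_q``, i.e. the number of partitions
    of ``u`` into at most min(n1, n2) parts each at most max(n1, n2).
    Integer-exact.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    umax = n1 * n2
    c = [0] * (umax + 1)
    c[0] = 1
    # multiply by (1 - q^(n2+i)) and divide by (1 - q^i), i = 1..n1
    for i in range(1, n1 + 1):
        for u in range(umax, n2 + i - 1, -1):
            c[u] -= c[u - (n2 + i)]
        for u in range(i, umax + 1):
            c[u] += c[u - i]
    return c


@dataclass(frozen=True)
class ExactTestResult:
    """Mann-Whitney test result (tie-free data)."""

    U: int
    n1: int
    n2: int
    p_one_sided: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    median1: float | None = None
    median2: float | None = None


def mann_whitney_exact(
    U: int, n1: int, n2: int, method: str = "exact"
) -> ExactTestResult:
    """Two-sided Mann-Whitney p-value from the U statistic.

    The one-sided p is the cumulative null count up to ``min(U, n1*n2 - U)``
    (the smaller tail) over ``C(n1+n2, n1)``; the two-sided p doubles it,
    clamped at 1.  ``method="normal_approx"`` uses the large-sample normal
    approximation with continuity correction instead.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not 0 <= U <= n1 * n2:
        raise ValueError(f"U must be in [0, {n1 * n2}], got {U}")
    tail = min(U, n1 * n2 - U)
    if method == "exact":
        counts = mann_whitney_counts(n1, n2)
        total = math.comb(n1 + n2, n1)
        p_one = Fraction(sum(counts[: tail + 1]), total)
        p_two = min(Fraction(1), 2 * p_one)
        return ExactTestResult(U, n1, n2, float(p_one), float(p_two), "exact")
    if method == "normal_approx":
        mu = n1 * n2 / 2.0
        sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        p_one = float(stats.norm.cdf((tail + 0.5 - mu) / sigma))
        return ExactTestResult(
            U, n1, n2, p_one, min(1.0, 2 * p_one), "normal_approx"
        )
    raise ValueError(f"unknown method {method!r}")


def mann_whitney_from_samples(
    x: Sequence[float], y: Sequence[float], method: str = "exact"
) -> ExactTestResult:
    """Rank-based U from two raw samples, delegated to
    :func:`mann_whitney_exact`.

    Ties across the pooled samples are not supported by the exact partition
    count and raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) != len(pooled):
        raise ValueError("ties present; exact Mann-Whitney requires tie-free data")
    ranks = stats.rankdata(pooled)
    u1 = int(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u = min(u1, n1 * n2 - u1)
    res = mann_whitney_exact(u, n1, n2, method=method)
    return ExactTestResult(
        res.U, n1, n2, res.p_one_sided, res.p_two_sided, res.method,
        median1=float(np.median(x)), median2=float(np.median(y)),
    )


def percent_of_target(observed_reads: int, target_reads: int) -> float:
    """Observed over targeted read depth as a percentage, rounded half-up to
    one decimal."""
    if target_reads <= 0:
        raise ValueError("target_reads must be > 0")
    pct = Decimal(observed_reads) / Decimal(target_reads) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
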