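"""Site-frequency-spectrum container, summary statistics and ``.fs`` file I/O.

The SFS is the lingua franca of the whole pipeline: the forward simulator
emits one per mutation class, the demographic and DFE inference stages
consume and predict them.  Counts are indexed by derived-allele count
``0..n`` for a sample of ``n`` haploid genomes; the monomorphic end bins
(0 and ``n``) are carried in the container but masked out of every
likelihood and diversity computation, following the standard spectrum
convention of the inference ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SFS",
    "DiversitySummary",
    "tally_sfs",
    "pi_from_sfs",
    "pi_over_pi0",
    "sum_sfs",
    "read_fs",
    "write_fs",
]

_CLASS_LABELS = ("synonymous", "nonsynonymous", "neutral", "other")


@dataclass
class SFS:
    """Unfolded (by default) site-frequency spectrum.

    Parameters
    ----------
    counts
        Length ``n + 1`` vector; entry ``k`` is the number of sites with
        derived-allele count ``k``.  Real-valued so observed and expected
        spectra share one type.
    n
        Haploid sample size.
    L
        Callable sequence length (bp) this spectrum summarises, or None.
    class_label
        One of ``synonymous, nonsynonymous, neutral, other``.
    folded
        Whether the spectrum has been folded onto minor-allele counts.
    """

    counts: np.ndarray
    n: int
    L: float | None = None
    class_label: str = "other"
    folded: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.shape[0] != self.n + 1:
            raise ValueError(
                f"counts must have length n+1={self.n + 1}, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")
        if self.class_label not in _CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {_CLASS_LABELS}, got {self.class_label!r}"
            )

    # -- basic views ------------------------------------------------------
    @property
    def polymorphic(self) -> np.ndarray:
        """Counts of the polymorphic bins 1..n-1."""
        return self.counts[1:-1]

    @property
    def num_segregating(self) -> float:
        return float(self.polymorphic.sum())

    def fold(self) -> "SFS":
        """Fold onto minor-allele counts (provided for completeness; the
        study's workflow is entirely unfolded)."""
        if self.folded:
            return replace(self, counts=self.counts.copy())
        n = self.n
        folded = np.zeros_like(self.counts)
        for k in range(n + 1):
            folded[min(k, n - k)] += self.counts[k]
        return replace(self, counts=folded, folded=True)

    def copy(self) -> "SFS":
        return replace(self, counts=self.counts.copy())


@dataclass(frozen=True)
class DiversitySummary:
    """Observed vs neutrally expected pairwise diversity for one class.

    ``pi`` and ``pi0`` are totals over the class's L base pairs;
    ``ratio = pi/pi0`` quantifies the diversity reduction, e.g. from
    background selection or direct purifying selection.
    """

    pi: float
    pi0: float
    ratio: float


def tally_sfs(
    derived_allele_counts: Iterable[int],
    n: int,
    *,
    L: float | None = None,
    class_label: str = "other",
) -> SFS:
    """Tally per-site derived-allele counts into an unfolded SFS.

    Sites fixed in the sample (count 0 or ``n``) land in the monomorphic
    end bins and do not contribute to segregating-site totals.
    """
    counts = np.zeros(n + 1)
    arr = np.asarray(list(derived_allele_counts), dtype=int)
    if arr.size:
        if arr.min() < 0 or arr.max() > n:
            raise ValueError(f"derived-allele counts must lie in [0, {n}]")
        np.add.at(counts, arr, 1.0)
    return SFS(counts, n, L=L, class_label=class_label)


def pi_from_sfs(sfs: SFS) -> float:
    """Average number of pairwise differences, totalled over sites.

    pi = sum_{i=1}^{n-1} X_i * i * (n - i) / C(n, 2).  Monomorphic bins
    contribute zero; equivalent to the mean Hamming distance over all
    C(n, 2) haplotype pairs.
    """
    n = sfs.n
    if n < 2:
        raise ValueError("pi requires a sample of at least 2 haplotypes")
    i = np.arange(1, n)
    weights = i * (n - i) / (n * (n - 1) / 2.0)
    return float(np.dot(sfs.counts[1:-1], weights))


def pi_over_pi0(sfs: SFS, N: float, mu: float, L: float) -> DiversitySummary:
    """Diversity relative to the neutral expectation pi0 = 4*N*mu*L."""
    if N <= 0 or mu <= 0 or L <= 0:
        raise ValueError("N, mu and L must all be positive")
    pi = pi_from_sfs(sfs)
    pi0 = 4.0 * N * mu * L
    return DiversitySummary(pi=pi, pi0=pi0, ratio=pi / pi0)


def sum_sfs(spectra: Sequence[SFS]) -> SFS:
    """Element-wise sum of spectra with identical n, folding and class.

    Realises the aggregation of per-chunk spectra into one replicate
    spectrum; L fields add (None propagates)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    total = np.zeros_like(first.counts)
    L: float | None = 0.0
    for s in spectra:
        if s.n != first.n:
            raise ValueError(f"sample-size mismatch: {s.n} != {first.n}")
        if s.folded != first.folded:
            raise ValueError("cannot sum folded with unfolded spectra")
        if s.class_label != first.class_label:
            raise ValueError("cannot sum spectra of different classes")
        total += s.counts
        L = None if (L is None or s.L is None) else L + s.L
    return SFS(total, first.n, L=L, class_label=first.class_label, folded=first.folded)


class FsParseError(ValueError):
    """Malformed ``.fs`` spectrum file."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_fs(sfs: SFS, path: str | Path) -> None:
    """Write a spectrum in the ``fs`` text convention.

    Header: ``<n+1> <folded|unfolded>``; one whitespace-separated data
    line of n+1 values; one mask line (monomorphic bins masked)."""
    path = Path(path)
    token = "folded" if sfs.folded else "unfolded"
    mask = np.zeros(sfs.n + 1, dtype=int)
    mask[0] = mask[-1] = 1
    with path.open("w") as fh:
        fh.write(f"{sfs.n + 1} {token}\n")
        fh.write(" ".join(repr(float(v)) for v in sfs.counts) + "\n")
        fh.write(" ".join(str(m) for m in mask) + "\n")


def read_fs(path: str | Path, *, class_label: str = "other") -> SFS:
    """Read a spectrum written in the ``fs`` text convention."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FsParseError("expected header, data and mask lines", 1)
    header = lines[0].split()
    if len(header) < 2:
        raise FsParseError("header must be '<n+1> <folded|unfolded>'", 1)
    try:
        n_bins = int(header[0])
    except ValueError as exc:
        raise FsParseError(f"bad bin count {header[0]!r}", 1) from exc
    token = header[1]
    if token not in ("folded", "unfolded"):
        raise FsParseError(f"folding token must be folded/unfolded, got {token!r}", 1)
    try:
        counts = np.array([float(v) for v in lines[1].split()])
    except ValueError as exc:
        raise FsParseError("data line contains a non-numeric value", 2) from exc
    if counts.shape[0] != n_bins:
        raise FsParseError(
            f"expected {n_bins} values on the data line, found {counts.shape[0]}", 2
        )
    return SFS(counts, n_bins - 1, class_label=class_label, folded=(token == "folded"))
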