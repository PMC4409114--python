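"""Domain types for population-scale CNV analysis.

Coordinates are 1-based inclusive throughout: a call spanning positions
``start..end`` has length ``end - start + 1``. Conversion to and from BED
(0-based half-open) happens only at the file boundary (:mod:`cnvpop.io`).

Copy-number (CN) states follow the integer convention 0 (homozygous loss),
1 (heterozygous loss), 2 (sex-chromosome reference-adjacent state), 3
(single gain), 4 (double gain). On autosomes a deletion call must carry CN
0 or 1 and a duplication CN 3 or 4; CN 2 is permitted only on X and Y,
where hemizygosity makes "two copies" a gain or loss depending on sex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"X", "Y"})
AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X", "Y")

#: Longest CNV retained by default (bp). Observational cap: genome-wide
#: surveys at array resolution do not report events beyond ~5.5 Mb, and
#: larger segments are almost always array artifacts. Overridable at read
#: time since it is an observation, not a QC rule.
MAX_CNV_LENGTH = 5_500_000

#: Default minimum length (bp) for the strict size filter; calls of exactly
#: this length are removed (length must be strictly greater).
DEFAULT_MIN_LENGTH = 100_000

CNV_TYPES = ("DUP", "DEL")
CN_STATES = (0, 1, 2, 3, 4)

_DEL_AUTOSOME_STATES = frozenset({0, 1})
_DUP_AUTOSOME_STATES = frozenset({3, 4})


class CNVValidationError(ValueError):
    """A record violates a CNV domain invariant."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and uppercase sex-chromosome labels."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in SEX_CHROMOSOMES:
        return c.upper()
    return c


@dataclass(frozen=True, slots=True)
class CNVCall:
    """One copy-number variant called in one individual.

    Parameters
    ----------
    sample_id, population_id :
        Identifiers of the carrier individual and its population.
    chrom :
        Chromosome label without ``chr`` prefix ("1".."22", "X", "Y").
    start, end :
        1-based inclusive coordinates, ``start <= end``.
    cnv_type :
        ``"DUP"`` or ``"DEL"``.
    cn_state :
        Integer copy-number state in 0..4 consistent with ``cnv_type``.
    """

    sample_id: str
    population_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    cn_state: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def on_sex_chromosome(self) -> bool:
        return self.chrom in SEX_CHROMOSOMES

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def validate_call(call: CNVCall, max_length: int | None = MAX_CNV_LENGTH) -> None:
    """Raise :class:`CNVValidationError` if ``call`` breaks an invariant.

    ``max_length=None`` disables the length cap.
    """
    if call.start < 1:
        raise CNVValidationError(f"start must be >= 1, got {call.start}")
    if call.end < call.start:
        raise CNVValidationError(f"end < start ({call.end} < {call.start})")
    if max_length is not None and call.length > max_length:
        raise CNVValidationError(
            f"length {call.length} bp exceeds the {max_length} bp cap"
        )
    if call.cnv_type not in CNV_TYPES:
        raise CNVValidationError(f"unknown cnv_type {call.cnv_type!r}")
    if call.cn_state not in CN_STATES:
        raise CNVValidationError(f"cn_state must be in 0..4, got {call.cn_state}")
    if call.on_sex_chromosome:
        # hemizygous chromosomes admit CN 2 for either event type
        allowed = (
            _DEL_AUTOSOME_STATES if call.cnv_type == "DEL" else _DUP_AUTOSOME_STATES
        ) | {2}
    else:
        allowed = _DEL_AUTOSOME_STATES if call.cnv_type == "DEL" else _DUP_AUTOSOME_STATES
    if call.cn_state not in allowed:
        raise CNVValidationError(
            f"cn_state {call.cn_state} inconsistent with {call.cnv_type} "
            f"on chromosome {call.chrom}"
        )


def filter_by_size(
    calls: list[CNVCall], min_len: int = DEFAULT_MIN_LENGTH
) -> list[CNVCall]:
    """Keep calls whose length is *strictly* greater than ``min_len`` bp.

    The inclusion rule is strict: a call of exactly ``min_len`` bp is
    removed. Input order is preserved; the number removed is logged.
    """
    if min_len < 0:
        raise ValueError(f"min_len must be non-negative, got {min_len}")
    kept = [c for c in calls if c.length > min_len]
    removed = len(calls) - len(kept)
    if removed:
        logger.info("size filter (> %d bp) removed %d of %d calls", min_len, removed, len(calls))
    return kept


@dataclass(frozen=True)
class CNVLocus:
    """An equivalence class of matched calls across individuals.

    The merged "breakpoint region": coordinates span all member calls and
    every member matches the cluster under the active overlap rule.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    member_calls: tuple[CNVCall, ...]

    @property
    def populations_present(self) -> frozenset[str]:
        return frozenset(c.population_id for c in self.member_calls)

    @property
    def carriers(self) -> frozenset[str]:
        """Distinct (population, sample) carrier pairs."""
        return frozenset((c.population_id, c.sample_id) for c in self.member_calls)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class SharingMatrix:
    """Population x population counts of shared CNV breakpoint regions.

    Entries may be unavailable (NA, stored as NaN). The matrix is symmetric
    where both entries are defined; the diagonal is undefined and ignored.
    """

    def __init__(self, populations: list[str], counts: np.ndarray):
        counts = np.asarray(counts, dtype=float)
        n = len(populations)
        if counts.shape != (n, n):
            raise ValueError(f"counts shape {counts.shape} != ({n}, {n})")
        both = ~np.isnan(counts) & ~np.isnan(counts.T)
        if not np.allclose(counts[both], counts.T[both]):
            raise ValueError("sharing counts are not symmetric where defined")
        off = ~np.eye(n, dtype=bool)
        defined = off & ~np.isnan(counts)
        if np.any(counts[defined] < 0):
            raise ValueError("sharing counts must be non-negative")
        self.populations = list(populations)
        self.counts = counts
        np.fill_diagonal(self.counts, np.nan)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.populations.index(pair[0])
        j = self.populations.index(pair[1])
        return self.counts[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.populations, columns=self.populations)

    def max_pair(self) -> tuple[str, str, float]:
        """Population pair with the largest defined count."""
        return self._extreme_pair(np.nanargmax)

    def min_pair(self) -> tuple[str, str, float]:
        """Population pair with the smallest defined count."""
        return self._extreme_pair(np.nanargmin)

    def _extreme_pair(self, argfn) -> tuple[str, str, float]:
        if np.all(np.isnan(self.counts)):
            raise ValueError("no defined entries")
        flat = argfn(self.counts)
        i, j = np.unravel_index(flat, self.counts.shape)
        i, j = sorted((int(i), int(j)))
        return (self.populations[i], self.populations[j], float(self.counts[i, j]))


@dataclass
class FrequencyTable:
    """Per-locus carrier frequencies per population.

    ``freq`` is a loci x populations DataFrame of carrier fractions in
    [0, 1]; ``counts_individuals`` maps population to cohort size so that
    ``freq * n`` is integral (within rounding).
    """

    freq: pd.DataFrame
    counts_individuals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.freq.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        for p, n in self.counts_individuals.items():
            if n < 1:
                raise ValueError(f"cohort size for {p} must be >= 1, got {n}")
            if p in self.freq.columns:
                carriers = self.freq[p].to_numpy() * n
                if not np.allclose(carriers, np.round(carriers), atol=1e-6):
                    raise ValueError(f"freq * n not integral for population {p}")

    @property
    def loci(self) -> list[str]:
        return list(self.freq.index)

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)


class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    def __init__(self, labels: list[str], d: np.ndarray):
        d = np.asarray(d, dtype=float)
        n = len(labels)
        if d.shape != (n, n):
            raise ValueError(f"distance shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(d < -1e-12):
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(d), 0.0, atol=1e-9):
            raise ValueError("distance diagonal must be zero")
        self.labels = list(labels)
        self.d = np.clip(d, 0.0, None)
        np.fill_diagonal(self.d, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.d[self.labels.index(pair[0]), self.labels.index(pair[1])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.d[np.ix_(idx, idx)])


def genotype_matrix_distance_ready(x: np.ndarray) -> np.ndarray:
    """Validate an individuals x loci genotype matrix and return it as float."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (individuals x loci)")
    if not np.isfinite(x).all():
        raise ValueError("genotype matrix contains non-finite entries")
    return x
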