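"""Descriptive CNV spectra and frequency classification.

Size spectra use half-open bins (lo, hi] so the strict >100 kb inclusion
filter and the first bin edge compose without double counting. Frequency
classes follow the strict conventions: carrier frequency > 70% in a
population is *recurring*, < 5% is *rare*, anything in between (including
the boundaries) *moderately recurring*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CNVCall, FrequencyTable

logger = logging.getLogger(__name__)

DEFAULT_SIZE_BINS: tuple[int, ...] = (
    100_000, 250_000, 500_000, 1_000_000, 2_000_000,
    3_000_000, 4_000_000, 5_000_000, 5_500_000,
)

RECURRING_MIN = 0.70
RARE_MAX = 0.05


@dataclass
class SizeSpectrum:
    bin_edges: tuple[int, ...]
    counts: np.ndarray
    fractions: np.ndarray

    def labels(self) -> list[str]:
        return [
            f"({self.bin_edges[i]},{self.bin_edges[i + 1]}]"
            for i in range(len(self.counts))
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.labels(), "count": self.counts, "fraction": self.fractions}
        )


def size_spectrum(
    calls_or_lengths, bin_edges: tuple[int, ...] = DEFAULT_SIZE_BINS
) -> SizeSpectrum:
    """Bin call lengths into half-open (lo, hi] size bins.

    Accepts CNV calls or raw lengths in bp. Fractions sum to 1 for
    non-empty input; an empty input yields all-zero fractions with a
    warning.
    """
    if list(bin_edges) != sorted(bin_edges) or len(set(bin_edges)) != len(bin_edges):
        raise ValueError("bin_edges must be strictly increasing")
    lengths = np.asarray(
        [c.length if isinstance(c, CNVCall) else int(c) for c in calls_or_lengths],
        dtype=np.int64,
    )
    nbins = len(bin_edges) - 1
    if lengths.size == 0:
        logger.warning("size_spectrum: empty input")
        return SizeSpectrum(tuple(bin_edges), np.zeros(nbins, dtype=int), np.zeros(nbins))
    out = (lengths <= bin_edges[0]) | (lengths > bin_edges[-1])
    if np.any(out):
        raise ValueError(
            f"{int(out.sum())} length(s) outside ({bin_edges[0]}, {bin_edges[-1]}]: "
            "apply the size filter first"
        )
    # right-closed bins
    idx = np.searchsorted(bin_edges, lengths, side="left") - 1
    counts = np.bincount(idx, minlength=nbins)
    return SizeSpectrum(tuple(bin_edges), counts, counts / lengths.size)


def dup_del_share(calls: list[CNVCall]) -> dict[str, float]:
    """Global gain/loss shares over all pooled calls."""
    if not calls:
        return {"DUP": 0.0, "DEL": 0.0}
    n_dup = sum(1 for c in calls if c.cnv_type == "DUP")
    return {"DUP": n_dup / len(calls), "DEL": 1 - n_dup / len(calls)}


def burden_summary(
    calls: list[CNVCall], roster: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-population per-individual CNV burden.

    Returns a DataFrame indexed by population with mean and SD of
    duplication count, deletion count, and total CNV size (Mb, summed
    lengths of an individual's retained calls in the diploid genome).

    ``roster`` maps sample_id -> population_id for the full cohort so
    that individuals with zero calls contribute zeros; when omitted, the
    roster is derived from the calls themselves. A sample assigned to two
    populations is a consistency error.
    """
    derived: dict[str, str] = {}
    for c in calls:
        prev = derived.setdefault(c.sample_id, c.population_id)
        if prev != c.population_id:
            raise ValueError(
                f"sample {c.sample_id} appears in populations {prev} and {c.population_id}"
            )
    if roster is None:
        roster = derived
    else:
        for s, p in derived.items():
            if s in roster and roster[s] != p:
                raise ValueError(f"sample {s} in roster population {roster[s]} but called in {p}")

    per_ind = {
        s: {"dup": 0, "del": 0, "size_mb": 0.0} for s in roster
    }
    for c in calls:
        rec = per_ind.setdefault(c.sample_id, {"dup": 0, "del": 0, "size_mb": 0.0})
        rec["dup" if c.cnv_type == "DUP" else "del"] += 1
        rec["size_mb"] += c.length / 1e6

    rows = []
    for s, rec in per_ind.items():
        pop = roster[s] if s in roster else derived[s]
        rows.append((pop, rec["dup"], rec["del"], rec["size_mb"]))
    df = pd.DataFrame(rows, columns=["population", "dup_count", "del_count", "size_mb"])
    g = df.groupby("population")
    out = pd.DataFrame(
        {
            "n_individuals": g.size(),
            "mean_dup": g["dup_count"].mean(),
            "sd_dup": g["dup_count"].std(ddof=1),
            "mean_del": g["del_count"].mean(),
            "sd_del": g["del_count"].std(ddof=1),
            "mean_size_mb": g["size_mb"].mean(),
            "sd_size_mb": g["size_mb"].std(ddof=1),
        }
    )
    return out.fillna(0.0)


def cn_state_spectrum(calls: list[CNVCall]) -> pd.DataFrame:
    """Per-population fraction of calls in each CN state 0..4.

    Fractions are over the population's own calls and sum to 1. The CN=2
    column reflects sex-chromosome calls only (the autosomal states are
    0/1 for losses and 3/4 for gains); a separate ``sex_chrom_fraction``
    column reports the share of calls on X/Y.
    """
    pops = sorted({c.population_id for c in calls})
    rows = {}
    for p in pops:
        sub = [c for c in calls if c.population_id == p]
        n = len(sub)
        if n == 0:
            logger.warning("cn_state_spectrum: population %s has no calls", p)
            rows[p] = [0.0] * 6
            continue
        states = [sum(1 for c in sub if c.cn_state == s) / n for s in range(5)]
        sex = sum(1 for c in sub if c.on_sex_chromosome) / n
        rows[p] = states + [sex]
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["cn0", "cn1", "cn2", "cn3", "cn4", "sex_chrom_fraction"],
    )


def classify_recurrence(
    freq_table: FrequencyTable,
    recurring_min: float = RECURRING_MIN,
    rare_max: float = RARE_MAX,
) -> pd.DataFrame:
    """Classify each (locus, population) frequency.

    recurring iff freq > recurring_min; rare iff freq < rare_max;
    otherwise moderately_recurring. Both boundaries fall in the middle
    class (strict inequalities).
    """
    if recurring_min <= rare_max:
        raise ValueError("recurring_min must exceed rare_max")
    f = freq_table.freq
    classes = pd.DataFrame("moderately_recurring", index=f.index, columns=f.columns)
    classes = classes.where(~(f > recurring_min), "recurring")
    classes = classes.where(~(f < rare_max), "rare")
    return classes


def class_fractions(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-population fraction of loci in each recurrence class."""
    out = {}
    for p in classes.columns:
        vc = classes[p].value_counts(normalize=True)
        out[p] = [
            float(vc.get(k, 0.0))
            for k in ("rare", "moderately_recurring", "recurring")
        ]
    return pd.DataFrame.from_dict(
        out, orient="index", columns=["rare", "moderately_recurring", "recurring"]
    )
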