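"""Cross-population sharing statistics for CNV loci.

A locus is *shared* between two populations when both appear among its
member calls; the pairwise sharing matrix counts loci, not call pairs.
Loci present in at least ``min_pops`` populations form the conserved
("ancestral") set, bucketed by sharing level into a ladder. Carrier
frequency is per breakpoint region: an individual carries the locus if it
contributes at least one member call, regardless of CN state.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CHROMOSOMES, CNVLocus, FrequencyTable, SharingMatrix

logger = logging.getLogger(__name__)


def sharing_matrix(
    loci: list[CNVLocus],
    populations: list[str],
    mask_pairs: list[tuple[str, str]] | None = None,
) -> SharingMatrix:
    """Count loci shared by each population pair.

    ``counts[i][j]`` = number of loci whose carriers span both populations
    i and j. ``mask_pairs`` marks pairs as unavailable (NA), mirroring
    surveys where some comparisons could not be made.
    """
    pset = set(populations)
    idx = {p: i for i, p in enumerate(populations)}
    n = len(populations)
    counts = np.zeros((n, n), dtype=float)
    for locus in loci:
        present = locus.populations_present
        unknown = present - pset
        if unknown:
            raise ValueError(f"locus {locus.locus_id} has unknown population(s): {sorted(unknown)}")
        for a, b in itertools.combinations(sorted(present), 2):
            counts[idx[a], idx[b]] += 1
            counts[idx[b], idx[a]] += 1
    for a, b in mask_pairs or []:
        counts[idx[a], idx[b]] = np.nan
        counts[idx[b], idx[a]] = np.nan
    np.fill_diagonal(counts, np.nan)
    return SharingMatrix(populations, counts)


def conserved_ladder(
    loci: list[CNVLocus], total_pops: int, min_pops: int = 6
) -> dict[int, list[CNVLocus]]:
    """Bucket loci by sharing level for levels ``min_pops..total_pops``.

    Returns a complete map (empty lists for empty levels). Loci below the
    threshold are excluded; the flat conserved set is the union of all
    buckets.
    """
    if not (2 <= min_pops <= total_pops):
        raise ValueError(f"need 2 <= min_pops <= total_pops, got {min_pops}, {total_pops}")
    ladder: dict[int, list[CNVLocus]] = {k: [] for k in range(min_pops, total_pops + 1)}
    for locus in loci:
        k = len(locus.populations_present)
        if k > total_pops:
            raise ValueError(
                f"locus {locus.locus_id} spans {k} populations > total_pops={total_pops}"
            )
        if k >= min_pops:
            ladder[k].append(locus)
    return ladder


def conserved_loci(ladder: dict[int, list[CNVLocus]]) -> list[CNVLocus]:
    """Flatten a ladder into the conserved ("singleton") locus list."""
    return [l for level in sorted(ladder) for l in ladder[level]]


def ladder_counts(ladder: dict[int, list[CNVLocus]]) -> dict[int, int]:
    return {k: len(v) for k, v in ladder.items()}


def locus_frequency(
    locus: CNVLocus, cohort_sizes: dict[str, int]
) -> tuple[dict[str, float], float]:
    """Per-population and global carrier frequency of one locus.

    freq[p] = distinct carrier samples in p / cohort size of p; the global
    frequency pools all carriers over all individuals.
    """
    carriers_by_pop: dict[str, set[str]] = {}
    for pop, sample in locus.carriers:
        if pop not in cohort_sizes:
            raise ValueError(f"locus {locus.locus_id}: population {pop!r} missing from cohort sizes")
        carriers_by_pop.setdefault(pop, set()).add(sample)
    freqs = {
        p: len(carriers_by_pop.get(p, set())) / n for p, n in cohort_sizes.items()
    }
    total_carriers = sum(len(s) for s in carriers_by_pop.values())
    global_freq = total_carriers / sum(cohort_sizes.values())
    return freqs, global_freq


def frequency_table(
    loci: list[CNVLocus], cohort_sizes: dict[str, int]
) -> FrequencyTable:
    """Carrier-frequency table (loci x populations) for downstream stages."""
    pops = list(cohort_sizes)
    rows = {}
    for locus in loci:
        freqs, _ = locus_frequency(locus, cohort_sizes)
        rows[locus.locus_id] = [freqs[p] for p in pops]
    freq = pd.DataFrame.from_dict(rows, orient="index", columns=pops)
    return FrequencyTable(freq=freq, counts_individuals=dict(cohort_sizes))


def chromosome_coverage(
    loci: list[CNVLocus], chromosomes: tuple[str, ...] = CHROMOSOMES
) -> dict[str, int]:
    """Per-chromosome locus counts, zeros included for empty chromosomes."""
    cov = {c: 0 for c in chromosomes}
    for locus in loci:
        cov[locus.chrom] = cov.get(locus.chrom, 0) + 1
    return cov


def write_ladder_report(ladder: dict[int, list[CNVLocus]], path: str | Path) -> None:
    rows = [
        {"level": k, "count": len(v), "locus_ids": ",".join(l.locus_id for l in v)}
        for k, v in sorted(ladder.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_circos_links(loci: list[CNVLocus], path: str | Path) -> None:
    """Export shared loci as a Circos-style link track.

    One line per unordered pair of member calls from different
    populations: chrom, start, end, chrom, start, end, value where value
    is the locus's sharing level. Plain data only; rendering is out of
    scope.
    """
    rows = []
    for locus in loci:
        level = len(locus.populations_present)
        # one representative call per population, leftmost
        per_pop = {}
        for c in locus.member_calls:
            cur = per_pop.get(c.population_id)
            if cur is None or (c.start, c.end) < (cur.start, cur.end):
                per_pop[c.population_id] = c
        for a, b in itertools.combinations(sorted(per_pop), 2):
            ca, cb = per_pop[a], per_pop[b]
            rows.append((ca.chrom, ca.start, ca.end, cb.chrom, cb.start, cb.end, level))
    pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "value"]
    ).to_csv(path, sep="\t", index=False)
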