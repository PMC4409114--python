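"""Synthetic multi-population CNV cohort generator.

Emulates the called-CNV output of a genome-wide array survey of 12 world
populations: per-individual duplication and deletion counts are Poisson
with population-specific means, call sizes follow the empirical size-bin
spectrum (about two thirds of calls in 100-250 kb, declining to a handful
beyond 3 Mb), duplications outnumber deletions roughly 3:1 globally, and a
configurable set of *ancestral loci* is planted with exact coordinates and
per-population carrier frequencies so that sharing and phylogeny stages
have ground truth.

The generator is a statistical null, not a demographic model: background
calls are placed uniformly on a length-weighted random chromosome, with no
linkage, hotspots, or mutation process over a population tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AUTOSOMES, CNVCall, SEX_CHROMOSOMES

#: hg18-like chromosome lengths (bp), 22 autosomes + X, Y.
DEFAULT_GENOME: dict[str, int] = {
    "1": 247_249_719, "2": 242_951_149, "3": 199_501_827, "4": 191_273_063,
    "5": 180_857_866, "6": 170_899_992, "7": 158_821_424, "8": 146_274_826,
    "9": 140_273_252, "10": 135_374_737, "11": 134_452_384, "12": 132_349_534,
    "13": 114_142_980, "14": 106_368_585, "15": 100_338_915, "16": 88_827_254,
    "17": 78_774_742, "18": 76_117_153, "19": 63_811_651, "20": 62_435_964,
    "21": 46_944_323, "22": 49_691_432, "X": 154_913_754, "Y": 57_772_954,
}

#: CN-state distribution conditional on call type, autosomes. Loose
#: calibration to published per-state spectra (heterozygous losses and
#: single gains dominate); non-canonical and exposed in config.
DEFAULT_CN_PROBS: dict[str, dict[int, float]] = {
    "DEL": {0: 0.15, 1: 0.85},
    "DUP": {3: 0.8, 4: 0.2},
}

#: Fraction of background calls placed on X/Y (emitted with CN state 2).
DEFAULT_SEX_CHROM_FRACTION = 0.05

#: Global duplication share among all calls (gain:loss roughly 3:1).
DEFAULT_DUP_FRACTION = 0.7471


@dataclass(frozen=True)
class SizeModel:
    """Piecewise size distribution for CNV lengths.

    ``bin_edges`` delimit half-open bins (lo, hi]; ``bin_probs`` are the
    per-bin masses; within a bin, lengths are log-uniform. The default
    reproduces the canonical array-survey spectrum: 66.3%, 22.3%, 7.5%,
    3%, 0.65%, 0.1% in 100-250 kb, 250-500 kb, 500 kb-1 Mb, 1-2 Mb,
    2-3 Mb, 3-4 Mb, remainder in 4-5.5 Mb.
    """

    bin_edges: tuple[int, ...] = (
        100_000, 250_000, 500_000, 1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_500_000
    )
    bin_probs: tuple[float, ...] = (0.663, 0.223, 0.075, 0.03, 0.0065, 0.001, 0.0015)

    def __post_init__(self) -> None:
        if len(self.bin_probs) != len(self.bin_edges) - 1:
            raise ValueError("need one probability per bin")
        if list(self.bin_edges) != sorted(self.bin_edges):
            raise ValueError("bin_edges must be increasing")
        if abs(sum(self.bin_probs) - 1.0) > 1e-9:
            raise ValueError(f"bin_probs sum to {sum(self.bin_probs)}, expected 1")

    def sample_lengths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` integer lengths in (min_edge, max_edge]."""
        bins = rng.choice(len(self.bin_probs), size=n, p=self.bin_probs)
        lo = np.asarray(self.bin_edges, dtype=float)[bins]
        hi = np.asarray(self.bin_edges, dtype=float)[bins + 1]
        u = rng.uniform(np.log(lo + 1), np.log(hi), size=n)
        return np.clip(np.rint(np.exp(u)), lo + 1, hi).astype(np.int64)


@dataclass(frozen=True)
class PopulationProfile:
    """Per-population generator settings.

    Poisson means are per-individual counts of retained (>100 kb) calls.
    """

    population_id: str
    n_individuals: int
    mean_dup_count: float
    mean_del_count: float
    cn_state_probs: dict[str, dict[int, float]] = field(
        default_factory=lambda: {t: dict(p) for t, p in DEFAULT_CN_PROBS.items()}
    )
    sex_chrom_fraction: float = DEFAULT_SEX_CHROM_FRACTION

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.mean_dup_count < 0 or self.mean_del_count < 0:
            raise ValueError("Poisson means must be non-negative")
        for t, probs in self.cn_state_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"cn_state_probs[{t}] must sum to 1")
        if not (0.0 <= self.sex_chrom_fraction <= 1.0):
            raise ValueError("sex_chrom_fraction must be in [0, 1]")

    @property
    def dup_fraction(self) -> float:
        tot = self.mean_dup_count + self.mean_del_count
        return self.mean_dup_count / tot if tot else 0.0


#: Packaged default cohort: 12 world populations with the per-individual
#: mean duplication/deletion burdens of the survey the generator emulates.
DEFAULT_PROFILES: tuple[PopulationProfile, ...] = tuple(
    PopulationProfile(pid, n, dup, dl)
    for pid, n, dup, dl in [
        ("YRI", 90, 5.35, 4.30),
        ("CEU", 90, 5.77, 5.90),
        ("AshkenaziJews1", 464, 21.11, 6.72),
        ("AshkenaziJews2", 480, 20.80, 5.53),
        ("CHB", 44, 3.91, 5.79),
        ("China", 155, 12.75, 5.89),
        ("Tibet", 31, 27.00, 6.91),
        ("India", 38, 23.18, 7.52),
        ("JPT", 45, 4.88, 5.84),
        ("Australia", 53, 35.21, 7.83),
        ("NewWorld", 41, 33.61, 13.90),
        ("Taiwan", 184, 26.16, 8.22),
    ]
)


@dataclass(frozen=True)
class AncestralLocusSpec:
    """A planted shared locus with per-population carrier frequencies."""

    locus_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    carrier_freq: dict[str, float]

    def __post_init__(self) -> None:
        for p, f in self.carrier_freq.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"carrier_freq[{p}] must be in (0, 1], got {f}")

    @property
    def populations_present(self) -> frozenset[str]:
        return frozenset(self.carrier_freq)


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort.

    ``ancestral_call_locus`` maps call index (into the returned call list)
    to the planted locus id; background calls are absent from the map.
    ``carrier_counts`` is a locus x population table of realized carrier
    counts.
    """

    ancestral_loci: list[AncestralLocusSpec]
    ancestral_call_locus: dict[int, str]
    carrier_counts: pd.DataFrame

    def write(self, path: str | Path) -> None:
        rows = []
        for spec in self.ancestral_loci:
            row = {
                "locus_id": spec.locus_id,
                "chrom": spec.chrom,
                "start": spec.start,
                "end": spec.end,
                "cnv_type": spec.cnv_type,
                "n_populations": len(spec.carrier_freq),
            }
            for p in self.carrier_counts.columns:
                row[f"carriers_{p}"] = int(self.carrier_counts.loc[spec.locus_id, p])
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _choose_chrom(
    rng: np.random.Generator, chroms: list[str], weights: np.ndarray
) -> str:
    return chroms[int(rng.choice(len(chroms), p=weights))]


def _cn_for(rng: np.random.Generator, probs: dict[int, float]) -> int:
    states = sorted(probs)
    p = np.array([probs[s] for s in states])
    return int(states[int(rng.choice(len(states), p=p))])


def generate_cohort(
    profiles: list[PopulationProfile] | tuple[PopulationProfile, ...] = DEFAULT_PROFILES,
    size_model: SizeModel | None = None,
    ancestral: list[AncestralLocusSpec] | None = None,
    genome: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[list[CNVCall], CohortTruth]:
    """Generate a multi-population CNV cohort. Deterministic given ``seed``.

    Per individual: Poisson duplication and deletion counts, each
    background call placed uniformly on a length-weighted chromosome with
    a :class:`SizeModel` length; each ancestral locus carried with its
    per-population probability and emitted at its exact coordinates.
    """
    size_model = size_model or SizeModel()
    ancestral = list(ancestral or [])
    genome = dict(genome or DEFAULT_GENOME)
    for spec in ancestral:
        if spec.chrom not in genome:
            raise ValueError(f"ancestral locus {spec.locus_id} on unknown chromosome {spec.chrom}")
        if spec.end > genome[spec.chrom] or spec.start < 1:
            raise ValueError(f"ancestral locus {spec.locus_id} outside chromosome bounds")
    rng = np.random.default_rng(seed)

    autosomes = [c for c in genome if c in AUTOSOMES]
    sex = [c for c in genome if c in SEX_CHROMOSOMES]
    auto_w = np.array([genome[c] for c in autosomes], dtype=float)
    auto_w /= auto_w.sum()
    sex_w = np.array([genome[c] for c in sex], dtype=float) if sex else np.array([])
    if sex:
        sex_w /= sex_w.sum()

    calls: list[CNVCall] = []
    ancestral_call_locus: dict[int, str] = {}
    pops = [pr.population_id for pr in profiles]
    carrier_counts = pd.DataFrame(
        0, index=[s.locus_id for s in ancestral], columns=pops, dtype=int
    )

    for pr in profiles:
        pop_anc = [s for s in ancestral if pr.population_id in s.carrier_freq]
        for i in range(pr.n_individuals):
            sample = f"{pr.population_id}_{i:04d}"
            for cnv_type, mean in (("DUP", pr.mean_dup_count), ("DEL", pr.mean_del_count)):
                n = int(rng.poisson(mean))
                if n == 0:
                    continue
                lengths = size_model.sample_lengths(n, rng)
                for L in lengths:
                    on_sex = bool(sex) and rng.random() < pr.sex_chrom_fraction
                    if on_sex:
                        chrom = _choose_chrom(rng, sex, sex_w)
                        cn = 2
                    else:
                        chrom = _choose_chrom(rng, autosomes, auto_w)
                        cn = _cn_for(rng, pr.cn_state_probs[cnv_type])
                    L = int(min(L, genome[chrom]))
                    start = int(rng.integers(1, genome[chrom] - L + 2))
                    calls.append(
                        CNVCall(sample, pr.population_id, chrom, start, start + L - 1, cnv_type, cn)
                    )
            for spec in pop_anc:
                if rng.random() < spec.carrier_freq[pr.population_id]:
                    cn = _cn_for(rng, pr.cn_state_probs[spec.cnv_type])
                    if spec.chrom in SEX_CHROMOSOMES:
                        cn = 2
                    ancestral_call_locus[len(calls)] = spec.locus_id
                    carrier_counts.loc[spec.locus_id, pr.population_id] += 1
                    calls.append(
                        CNVCall(
                            sample, pr.population_id, spec.chrom,
                            spec.start, spec.end, spec.cnv_type, cn,
                        )
                    )

    truth = CohortTruth(ancestral, ancestral_call_locus, carrier_counts)
    return calls, truth


def plant_sharing_ladder(
    populations: list[str],
    ladder_spec: dict[int, int],
    genome: dict[str, int] | None = None,
    seed: int = 0,
    freq_beta: tuple[float, float] = (2.0, 5.0),
    min_freq: float = 0.05,
    size_model: SizeModel | None = None,
    chromosomes: list[str] | None = None,
    dup_fraction: float = DEFAULT_DUP_FRACTION,
    max_retries: int = 1000,
) -> list[AncestralLocusSpec]:
    """Plant non-overlapping ancestral loci with requested sharing levels.

    ``ladder_spec`` maps a sharing level k (number of populations carrying
    the locus) to a count of loci; the k populations of each locus are
    chosen uniformly at random. Carrier frequencies are Beta(a, b) draws
    floored at ``min_freq`` (the survey reports a broad 0.01-55% spread;
    the floor keeps planted loci recoverable in small cohorts).
    """
    genome = dict(genome or DEFAULT_GENOME)
    size_model = size_model or SizeModel()
    chroms = list(chromosomes or [c for c in genome if c in AUTOSOMES])
    for k in ladder_spec:
        if not (1 <= k <= len(populations)):
            raise ValueError(f"sharing level {k} outside 1..{len(populations)}")
    rng = np.random.default_rng(seed)
    w = np.array([genome[c] for c in chroms], dtype=float)
    w /= w.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[AncestralLocusSpec] = []
    idx = 0
    for level in sorted(ladder_spec):
        for _ in range(ladder_spec[level]):
            idx += 1
            chrom, start, end = _place_nonoverlapping(
                rng, chroms, w, genome, size_model, placed, max_retries
            )
            members = [populations[j] for j in sorted(rng.choice(len(populations), size=level, replace=False))]
            freqs = {
                p: float(min(1.0, max(min_freq, rng.beta(*freq_beta)))) for p in members
            }
            cnv_type = "DUP" if rng.random() < dup_fraction else "DEL"
            out.append(AncestralLocusSpec(f"A{idx:05d}", chrom, start, end, cnv_type, freqs))
    return out


def _place_nonoverlapping(rng, chroms, w, genome, size_model, placed, max_retries):
    for _ in range(max_retries):
        chrom = _choose_chrom(rng, chroms, w)
        L = int(size_model.sample_lengths(1, rng)[0])
        if L >= genome[chrom]:
            continue
        start = int(rng.integers(1, genome[chrom] - L + 2))
        end = start + L - 1
        if all(e < start or s > end for s, e in placed[chrom]):
            placed[chrom].append((start, end))
            return chrom, start, end
    raise RuntimeError(f"could not place a non-overlapping locus after {max_retries} tries")


def sample_call_types(
    n: int, dup_fraction: float = DEFAULT_DUP_FRACTION, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` call types ("DUP"/"DEL") at the global gain share."""
    rng = np.random.default_rng(seed)
    return np.where(rng.random(n) < dup_fraction, "DUP", "DEL")
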