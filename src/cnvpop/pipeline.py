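"""Config-driven end-to-end CNV population analysis.

Stage order: acquire calls (file or synthetic cohort) -> size filter ->
same-sample dedup -> locus clustering -> sharing matrix -> conserved
ladder -> carrier frequencies & classification -> descriptive spectra ->
novelty vs reference -> distances -> NJ/UPGMA/consensus trees -> report
bundle (TSVs, Newick, JSON summary, log). Deterministic given config +
seed.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import yaml

from . import intervals, io, phylo, sharing, simulate, spectra
from .model import filter_by_size

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "min_size": 100_000,
    "overlap": 0.5,
    "ladder_min_pops": 6,
    "recurring_min": 0.70,
    "rare_max": 0.05,
}

_TOP_KEYS = {
    "seed", "input", "reference", "sharing_matrix", "thresholds",
    "dedup", "output_dir", "stages",
}
_INPUT_KEYS = {"calls", "synthetic"}
_SYNTH_KEYS = {"profiles", "ladder", "seed"}
ALL_STAGES = ("spectra", "loci", "sharing", "classification", "novelty", "trees")


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg, base_dir=Path(path).parent)


def validate_config(cfg: dict, base_dir: str | Path | None = None) -> dict:
    """Normalize a pipeline config: inject defaults, resolve paths, reject
    unknown keys and out-of-range thresholds."""
    cfg = copy.deepcopy(cfg)
    errors: list[str] = []
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown key(s): {', '.join(sorted(unknown))}")

    inp = cfg.get("input") or {}
    if set(inp) - _INPUT_KEYS:
        errors.append(f"unknown input key(s): {', '.join(sorted(set(inp) - _INPUT_KEYS))}")
    if "calls" in inp and "synthetic" in inp:
        errors.append("ambiguous input: both a call table and a synthetic spec given")
    if not inp and not cfg.get("sharing_matrix"):
        errors.append("no input: need input.calls, input.synthetic, or sharing_matrix")
    if "synthetic" in inp:
        synth = inp["synthetic"] or {}
        if isinstance(synth, dict) and set(synth) - _SYNTH_KEYS:
            errors.append(f"unknown synthetic key(s): {', '.join(sorted(set(synth) - _SYNTH_KEYS))}")
        if cfg.get("seed") is None and (not isinstance(synth, dict) or synth.get("seed") is None):
            errors.append("a seed is mandatory for a synthetic run")

    th = dict(DEFAULT_THRESHOLDS)
    th.update(cfg.get("thresholds") or {})
    if set(th) - set(DEFAULT_THRESHOLDS):
        errors.append(
            f"unknown threshold(s): {', '.join(sorted(set(th) - set(DEFAULT_THRESHOLDS)))}"
        )
    else:
        if not (0 < th["overlap"] <= 1):
            errors.append(f"overlap threshold {th['overlap']} outside (0, 1]")
        if th["min_size"] < 0:
            errors.append(f"min_size {th['min_size']} is negative")
        if th["ladder_min_pops"] < 2:
            errors.append(f"ladder_min_pops {th['ladder_min_pops']} must be >= 2")
        if not (0 <= th["rare_max"] < th["recurring_min"] <= 1):
            errors.append("need 0 <= rare_max < recurring_min <= 1")
    cfg["thresholds"] = th
    cfg.setdefault("dedup", True)
    cfg.setdefault("stages", list(ALL_STAGES))
    bad_stages = set(cfg["stages"]) - set(ALL_STAGES)
    if bad_stages:
        errors.append(f"unknown stage(s): {', '.join(sorted(bad_stages))}")

    if base_dir is not None:
        base = Path(base_dir)
        for key in ("reference", "sharing_matrix", "output_dir"):
            if cfg.get(key):
                cfg[key] = str((base / cfg[key]).resolve())
        if "calls" in inp and inp["calls"]:
            inp["calls"] = str((base / inp["calls"]).resolve())
    cfg["input"] = inp
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _acquire_calls(cfg: dict, out: Path):
    inp = cfg.get("input") or {}
    if "calls" in inp:
        return io.read_cnv_table(inp["calls"]), None, None
    synth = inp.get("synthetic") or {}
    seed = synth.get("seed", cfg.get("seed"))
    profiles = synth.get("profiles", "default")
    if profiles == "default":
        profiles = simulate.DEFAULT_PROFILES
    else:
        profiles = tuple(simulate.PopulationProfile(**p) for p in profiles)
    ancestral = []
    if synth.get("ladder"):
        ladder = {int(k): int(v) for k, v in synth["ladder"].items()}
        ancestral = simulate.plant_sharing_ladder(
            [p.population_id for p in profiles], ladder, seed=seed
        )
    calls, truth = simulate.generate_cohort(
        profiles=profiles, ancestral=ancestral, seed=seed
    )
    io.write_cnv_table(calls, out / "calls.tsv")
    truth.write(out / "truth.tsv")
    sizes = {p.population_id: p.n_individuals for p in profiles}
    return calls, truth, sizes


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run the pipeline; returns the summary dict (also written as JSON)."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    out = Path(output_dir or cfg.get("output_dir") or ".")
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cnvpop")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    th = cfg["thresholds"]
    stages = set(cfg["stages"])
    rule = intervals.OverlapRule(threshold=th["overlap"])
    summary: dict = {"thresholds": th, "stages": sorted(stages)}
    try:
        calls, truth, cohort_sizes = ([], None, None)
        if cfg.get("input"):
            calls, truth, cohort_sizes = _acquire_calls(cfg, out)
            summary["n_calls_raw"] = len(calls)
            calls = filter_by_size(calls, th["min_size"])
            summary["n_calls_after_size_filter"] = len(calls)
            if cfg["dedup"]:
                calls = intervals.dedup_same_sample(calls, rule)
                summary["n_calls_after_dedup"] = len(calls)
            if not calls:
                logger.warning("no calls survive filtering; downstream stages will be empty")
        if cohort_sizes is None and calls:
            roster: dict[str, str] = {}
            for c in calls:
                roster[c.sample_id] = c.population_id
            cohort_sizes = {}
            for p in roster.values():
                cohort_sizes[p] = cohort_sizes.get(p, 0) + 1
        populations = sorted(cohort_sizes) if cohort_sizes else []

        if "spectra" in stages and calls:
            _run_spectra(calls, out, summary)

        loci = []
        if calls and ({"loci", "sharing", "classification", "trees"} & stages):
            loci = intervals.cluster_loci(calls, rule)
            summary["n_loci"] = len(loci)

        conserved = []
        if loci and "sharing" in stages:
            sm = sharing.sharing_matrix(loci, populations)
            io.write_sharing_matrix(sm, out / "sharing_matrix.tsv")
            ladder = sharing.conserved_ladder(
                loci, total_pops=len(populations), min_pops=th["ladder_min_pops"]
            )
            conserved = sharing.conserved_loci(ladder)
            sharing.write_ladder_report(ladder, out / "ladder_report.tsv")
            sharing.write_circos_links(conserved, out / "circos_links.tsv")
            summary["ladder_counts"] = {str(k): len(v) for k, v in ladder.items()}
            summary["n_conserved_loci"] = len(conserved)
            cov = sharing.chromosome_coverage(conserved)
            summary["conserved_chromosome_coverage"] = cov

        freq_table = None
        if loci and cohort_sizes and ({"classification", "trees"} & stages):
            freq_table = sharing.frequency_table(conserved or loci, cohort_sizes)
            freq_table.freq.to_csv(out / "frequency_table.tsv", sep="\t")

        if freq_table is not None and "classification" in stages:
            classes = spectra.classify_recurrence(
                freq_table, th["recurring_min"], th["rare_max"]
            )
            classes.to_csv(out / "recurrence_classes.tsv", sep="\t")
            fracs = spectra.class_fractions(classes)
            fracs.to_csv(out / "recurrence_fractions.tsv", sep="\t")
            summary["recurrence_fractions"] = {
                p: {k: round(v, 6) for k, v in row.items()}
                for p, row in fracs.to_dict(orient="index").items()
            }

        if "novelty" in stages and cfg.get("reference") and calls:
            reference = io.read_cnv_table(cfg["reference"])
            flags, nov = intervals.flag_novel(calls, reference, rule)
            _write_novelty(calls, flags, out / "novelty.tsv")
            summary["novelty"] = {
                "n_calls": nov.n_calls,
                "n_novel": nov.n_novel,
                "novel_fraction": round(nov.novel_fraction, 6),
                "by_type": {k: round(v, 6) for k, v in nov.by_type.items()},
            }

        if "trees" in stages:
            summary["trees"] = _run_trees(cfg, freq_table, out)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        root.removeHandler(handler)
        handler.close()
        raise
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    root.removeHandler(handler)
    handler.close()
    return summary


def _run_spectra(calls, out: Path, summary: dict) -> None:
    spec = spectra.size_spectrum(calls)
    spec.to_frame().to_csv(out / "size_spectrum.tsv", sep="\t", index=False)
    share = spectra.dup_del_share(calls)
    burden = spectra.burden_summary(calls)
    burden.to_csv(out / "burden.tsv", sep="\t")
    cn = spectra.cn_state_spectrum(calls)
    cn.to_csv(out / "cn_spectrum.tsv", sep="\t")
    summary["n_calls"] = len(calls)
    summary["dup_share"] = round(share["DUP"], 6)
    summary["del_share"] = round(share["DEL"], 6)
    summary["size_bin_fractions"] = {
        lab: round(float(f), 6) for lab, f in zip(spec.labels(), spec.fractions)
    }


def _run_trees(cfg: dict, freq_table, out: Path) -> dict:
    info: dict = {}
    trees_built = []
    if freq_table is not None and len(freq_table.populations) >= 3 and len(freq_table.loci) > 0:
        dm = phylo.nei_distance_matrix(freq_table)
        io.write_distance_matrix(dm, out / "nei_distances.tsv")
        nj = phylo.build_nj(dm)
        upgma = phylo.build_upgma(dm)
        io.write_newick(nj, out / "nj_frequencies.nwk")
        io.write_newick(upgma, out / "upgma_frequencies.nwk")
        trees_built += ["nj_frequencies.nwk", "upgma_frequencies.nwk"]
        con = phylo.consensus_tree([nj, upgma], method="majority")
        io.write_newick(con, out / "consensus_frequencies.nwk")
        trees_built.append("consensus_frequencies.nwk")
    if cfg.get("sharing_matrix"):
        sm = io.read_sharing_matrix(cfg["sharing_matrix"])
        dm = phylo.sharing_to_distance(sm, method="max_minus")
        io.write_distance_matrix(dm, out / "sharing_distances.tsv")
        nj = phylo.build_nj(dm)
        upgma = phylo.build_upgma(dm)
        io.write_newick(nj, out / "nj_sharing.nwk")
        io.write_newick(upgma, out / "upgma_sharing.nwk")
        trees_built += ["nj_sharing.nwk", "upgma_sharing.nwk"]
        merges = phylo.upgma_merge_order(dm)
        _write_merge_log(merges, out / "upgma_sharing_merges.tsv")
        info["first_sharing_merge"] = list(merges[0][:2])
    info["files"] = trees_built
    return info


def _write_merge_log(merges, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(merges, columns=["cluster_a", "cluster_b", "height"]).to_csv(
        path, sep="\t", index=False
    )


def _write_novelty(calls, flags, path: Path) -> None:
    import pandas as pd

    rows = [
        (c.sample_id, c.population_id, c.chrom, c.start, c.end, c.cnv_type, c.cn_state, bool(f))
        for c, f in zip(calls, flags)
    ]
    pd.DataFrame(
        rows, columns=io.CALL_COLUMNS + ["novel"]
    ).to_csv(path, sep="\t", index=False)
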