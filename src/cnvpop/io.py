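"""Readers and writers for the CNV call dialect, matrices, and trees.

The native call dialect is a TSV with header columns ``sample_id``,
``population_id``, ``chrom``, ``start``, ``end``, ``cnv_type``,
``cn_state`` and 1-based inclusive coordinates. A BED6-derived reader is
also provided (0-based half-open, converted at the boundary).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .model import (
    MAX_CNV_LENGTH,
    CNVCall,
    CNVValidationError,
    DistanceMatrix,
    SharingMatrix,
    normalize_chrom,
    validate_call,
)

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["sample_id", "population_id", "chrom", "start", "end", "cnv_type", "cn_state"]


class FormatError(ValueError):
    """File-level format problem (e.g. a missing required column)."""


def read_cnv_table(
    path: str | Path,
    max_length: int | None = MAX_CNV_LENGTH,
    on_bad_rows: str = "warn",
) -> list[CNVCall]:
    """Read a native-dialect CNV call table.

    Rows violating a domain invariant are rejected with a row-numbered
    diagnostic. ``on_bad_rows`` is ``"warn"`` (log and skip, the default)
    or ``"raise"``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    calls: list[CNVCall] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            calls.append(_parse_row(row, max_length))
        except (CNVValidationError, ValueError) as exc:
            msg = f"{path}: row {idx}: {exc}"
            if on_bad_rows == "raise":
                raise CNVValidationError(msg) from exc
            logger.warning("rejected %s", msg)
    return calls


def _parse_row(row, max_length: int | None) -> CNVCall:
    try:
        start = int(getattr(row, "start"))
        end = int(getattr(row, "end"))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-integer coordinate ({row.start!r}, {row.end!r})") from exc
    try:
        cn = int(getattr(row, "cn_state"))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-integer cn_state {row.cn_state!r}") from exc
    call = CNVCall(
        sample_id=str(row.sample_id),
        population_id=str(row.population_id),
        chrom=normalize_chrom(row.chrom),
        start=start,
        end=end,
        cnv_type=str(row.cnv_type).upper(),
        cn_state=cn,
    )
    validate_call(call, max_length=max_length)
    return call


def write_cnv_table(calls: list[CNVCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (c.sample_id, c.population_id, c.chrom, c.start, c.end, c.cnv_type, c.cn_state)
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_cnv_bed(
    path: str | Path, max_length: int | None = MAX_CNV_LENGTH, on_bad_rows: str = "warn"
) -> list[CNVCall]:
    """Read calls from a BED6-derived file.

    Columns: chrom, start (0-based), end (half-open), name encoded as
    ``sample|population|type|cn``, score and strand ignored. Coordinates
    are converted to 1-based inclusive on read.
    """
    calls: list[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: need >= 4 BED columns")
            try:
                name = parts[3].split("|")
                if len(name) != 4:
                    raise ValueError(f"name field {parts[3]!r} is not sample|population|type|cn")
                call = CNVCall(
                    sample_id=name[0],
                    population_id=name[1],
                    chrom=normalize_chrom(parts[0]),
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    cnv_type=name[2].upper(),
                    cn_state=int(name[3]),
                )
                validate_call(call, max_length=max_length)
                calls.append(call)
            except (CNVValidationError, ValueError) as exc:
                msg = f"{path}: line {lineno}: {exc}"
                if on_bad_rows == "raise":
                    raise CNVValidationError(msg) from exc
                logger.warning("rejected %s", msg)
    return calls


def read_sharing_matrix(path: str | Path) -> SharingMatrix:
    """Read a population sharing matrix TSV (first row/column = labels).

    The literal ``NA`` marks unavailable pairs; the diagonal may be ``-``
    or ``NA`` and is ignored either way.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "-"])
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    return SharingMatrix(list(df.index), df.to_numpy(dtype=float))


def write_sharing_matrix(m: SharingMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_distance_matrix(m: DistanceMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize a tree as standard Newick with branch lengths."""
    Path(path).write_text(tree_to_newick(tree) + "\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def load_shared_breakpoint_counts() -> SharingMatrix:
    """Load the packaged example sharing matrix.

    Pairwise counts of shared CNV breakpoint regions across 12 world
    populations (grouped into 10 panels) from a published genome-wide CNV
    survey; two pairs are unavailable (NA).
    """
    ref = resources.files("cnvpop.data") / "shared_breakpoint_counts.tsv"
    with resources.as_file(ref) as p:
        return read_sharing_matrix(p)
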