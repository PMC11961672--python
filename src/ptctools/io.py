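"""Readers and writers for the plain-text and image formats the package touches.

BED intervals are 0-based half-open.  Tables travel as TSV through pandas;
image stacks as multi-page TIFF through tifffile.  Malformed BED rows are
reported with their line number.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import DataError


class GenomicInterval(NamedTuple):
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path) -> list[GenomicInterval]:
    """Read intervals from a BED file (first three columns; extra columns ignored).

    Track, browser and ``#`` comment lines are skipped.  A row with fewer
    than three columns, non-integer coordinates or start >= end raises a
    :class:`DataError` naming the offending line.
    """
    path = Path(path)
    intervals = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise DataError(f"{path}:{lineno}: invalid interval "
                                f"[{start}, {end}) (need 0 <= start < end)")
            intervals.append(GenomicInterval(fields[0], start, end))
    return intervals


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_snps(path) -> list[tuple[str, int]]:
    """Read SNPs stored as 1-bp BED features, returning (chrom, position) points."""
    out = []
    for iv in read_bed(path):
        if iv.length != 1:
            raise DataError(f"SNP feature {iv} is not a 1-bp interval")
        out.append((iv.chrom, iv.start))
    return out


def read_genome_table(path) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV into an ordered mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], dtype={"chrom": str})
    genome = {}
    for chrom, length in zip(df["chrom"], df["length"]):
        length = int(length)
        if length <= 0:
            raise DataError(f"chromosome {chrom} has non-positive length {length}")
        genome[chrom] = length
    return genome


def write_genome_table(path, chrom_lengths: dict[str, int]) -> None:
    with Path(path).open("w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_expression_table(path) -> pd.DataFrame:
    """Read an expression-by-genotype table (batch, replicate, x1, x2, expression)."""
    df = read_table(path)
    required = {"batch", "replicate", "x1", "x2", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required columns {sorted(missing)}")
    if (df["expression"] < 0).any():
        raise DataError(f"{path}: raw expression must be non-negative")
    return df


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF into a (Z, H, W) float array scaled to [0, 1]."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    arr = arr.astype(float)
    if arr.max() > 1.0:  # integer-typed acquisitions
        arr = arr / np.iinfo(np.uint16).max if arr.max() > 255 else arr / 255.0
    return arr


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (Z, H, W) array in [0, 1] as a 16-bit multi-page TIFF."""
    import tifffile

    data = np.clip(stack, 0.0, 1.0)
    tifffile.imwrite(path, (data * np.iinfo(np.uint16).max).astype(np.uint16),
                     photometric="minisblack")


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def write_manifest(path, command: str, seed: int, inputs: dict, params: dict) -> None:
    """Write the JSON run manifest every CLI stage emits alongside its outputs."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "params": params,
        "config_hash": config_hash({"inputs": inputs, "params": params, "seed": seed}),
        "version": __version__,
    }
    with Path(path).open("w") as fh:
        json.dump(manifest, fh, indent=2)
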