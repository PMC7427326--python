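"""Readers and writers for the standard formats the pipeline touches.

Sequences travel as FASTA (via Biopython), per-nucleotide tracks as
bedGraph (0-based half-open) or wiggle (1-based fixedStep), tabular results
as TSV (via pandas), model parameters as YAML.  BigWig occupancy tracks
from external experiments are read through pyBigWig when it is installed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .params import ModelParams
from .energy import EnergyTrack


def write_fasta(path, sequences: dict) -> None:
    """Write ``{name: sequence}`` to FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bedgraph(path, values: np.ndarray, chrom: str = "unit") -> None:
    """Run-length-merged bedGraph (0-based half-open); NaN spans skipped."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={chrom}\n")
        start = 0
        n = len(values)
        while start < n:
            if np.isnan(values[start]):
                start += 1
                continue
            end = start + 1
            while end < n and values[end] == values[start]:
                end += 1
            fh.write(f"{chrom}\t{start}\t{end}\t{values[start]:.6f}\n")
            start = end


def read_bedgraph(path, length: Optional[int] = None, chrom: Optional[str] = None) -> np.ndarray:
    """Read a single-chromosome bedGraph into a NaN-padded array."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            c, start, end, value = line.split()[:4]
            if chrom is not None and c != chrom:
                continue
            rows.append((int(start), int(end), float(value)))
    if not rows:
        raise ValueError(f"no intervals read from {path}")
    n = length or max(end for _, end, _ in rows)
    values = np.full(n, np.nan)
    for start, end, value in rows:
        values[start:end] = value
    return values


def write_wiggle(path, values: np.ndarray, chrom: str = "unit") -> None:
    """fixedStep wiggle, 1-based starts per the format; NaN written as 'NA'-skip."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"track type=wiggle_0 name={chrom}\n")
        fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
        for v in values:
            fh.write(f"{0.0 if np.isnan(v) else v:.6f}\n")


def write_track(path, track: EnergyTrack, chrom: str = "unit", fmt: str = "bedgraph") -> None:
    if fmt == "bedgraph":
        write_bedgraph(path, track.values, chrom)
    elif fmt == "wiggle":
        write_wiggle(path, track.values, chrom)
    else:
        raise ValueError("fmt must be 'bedgraph' or 'wiggle'")


def read_track(path, window: int, offset: int = 0, kind: str = "structure",
               length: Optional[int] = None) -> EnergyTrack:
    values = read_bedgraph(path, length=length)
    return EnergyTrack(values, window=window, offset=offset, kind=kind)


def read_bigwig(path, chrom: str, start: int = 0, end: Optional[int] = None) -> np.ndarray:
    """Read a per-nucleotide slice of a BigWig track (requires pyBigWig)."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading BigWig tracks requires pyBigWig") from exc
    bw = pyBigWig.open(str(path))
    try:
        end = end or bw.chroms()[chrom]
        return np.array(bw.values(chrom, start, end), dtype=float)
    finally:
        bw.close()


def write_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_params(path, params: ModelParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_params(path) -> ModelParams:
    with open(path) as fh:
        return ModelParams.from_dict(yaml.safe_load(fh))


def save_events(path, events: dict) -> None:
    write_tsv(path, pd.DataFrame([events]))
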