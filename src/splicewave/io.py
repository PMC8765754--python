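"""Plain-text readers/writers: bedGraph coverage tracks, FASTA, TSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import CoverageTimeCourse


def write_bedgraph(path: str | Path, coverage: Mapping[str, tuple[np.ndarray, np.ndarray]], bin_size: int) -> None:
    """Write per-gene coverage as bedGraph (chrom = gene_id, transcript coords).

    ``coverage`` maps gene_id -> (positions, values) with positions = bin starts.
    """
    with open(path, "w") as fh:
        for gene_id in coverage:
            positions, values = coverage[gene_id]
            for p, val in zip(positions, values):
                fh.write(f"{gene_id}\t{int(p)}\t{int(p) + bin_size}\t{val:g}\n")


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a bedGraph written by `write_bedgraph`; returns gene -> (positions, values)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for gene_id, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        out[str(gene_id)] = (grp["start"].to_numpy(), grp["value"].to_numpy(float))
    return out


def write_timecourses(
    outdir: str | Path,
    timecourses: Mapping[str, CoverageTimeCourse],
    prefix: str = "coverage",
) -> list[Path]:
    """One bedGraph per time point covering all genes; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    any_tc = next(iter(timecourses.values()))
    paths = []
    for j, t in enumerate(any_tc.times):
        track = {g: (tc.positions, tc.matrix[:, j]) for g, tc in timecourses.items()}
        p = outdir / f"{prefix}_t{t:g}.bedGraph"
        write_bedgraph(p, track, any_tc.bin_size)
        paths.append(p)
    return paths


def read_timecourses(
    paths: Sequence[str | Path], times: Sequence[float], bin_size: int
) -> dict[str, CoverageTimeCourse]:
    """Assemble per-gene CoverageTimeCourse objects from per-time bedGraphs."""
    if len(paths) != len(times):
        raise ValueError("need one path per time point")
    per_time = [read_bedgraph(p) for p in paths]
    genes = list(per_time[0].keys())
    out = {}
    for g in genes:
        positions = per_time[0][g][0]
        matrix = np.column_stack([pt[g][1] for pt in per_time])
        out[g] = CoverageTimeCourse(
            gene_id=g, bin_size=bin_size, positions=positions,
            times=np.asarray(times, float), matrix=matrix,
        )
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}
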