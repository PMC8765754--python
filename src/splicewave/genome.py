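"""Gene-structure data model, annotation I/O, intron features, splice-site profiles.

All coordinates are transcript-relative, 0-based, half-open, with the
transcription start site (TSS) at 0 and the transcription end site (TES) at
``L``.  Strand is resolved at parse time: on the minus strand genomic
coordinates are mirrored so that position increases in the direction of
transcription.  This is the coordinate frame in which all kinetic quantities
(elongation, splicing delay, distance to the TES) are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


INTRON_CLASSES = ("constitutive", "cassette-flank", "alt5", "alt3")


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


@dataclass(frozen=True)
class Intron:
    """A single intron in transcript-relative coordinates.

    ``end`` is the coordinate at which the 3' splice site is completely
    transcribed (e3); the splicing clock of the kinetic model starts there.
    """

    index: int
    start: int
    end: int
    dist_to_tes: int
    klass: str = "constitutive"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"intron [{self.start},{self.end}) has non-positive length")
        if self.dist_to_tes < 0:
            raise ValueError("dist_to_tes must be >= 0")
        if self.klass not in INTRON_CLASSES:
            raise ValueError(f"unknown intron class {self.klass!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Single-isoform gene structure in transcript-relative coordinates.

    Exons and introns tile ``[0, L)`` without gaps or overlap.  The genomic
    anchor (``chrom``, ``genomic_start``, ``genomic_end``, ``strand``) is
    retained so transcript coordinates can be mapped back to the genome.
    """

    gene_id: str
    strand: str
    length: int
    exons: list[tuple[int, int]]
    introns: list[Intron] = field(default_factory=list)
    chrom: str | None = None
    genomic_start: int | None = None
    genomic_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.validate()

    def validate(self) -> None:
        """Check that exons and introns tile [0, L) and flank each other."""
        blocks = sorted(
            [(s, e, "E") for s, e in self.exons]
            + [(i.start, i.end, "I") for i in self.introns]
        )
        if not blocks:
            raise ValueError(f"{self.gene_id}: no exons")
        if blocks[0][0] != 0 or blocks[-1][1] != self.length:
            raise ValueError(f"{self.gene_id}: blocks do not span [0, {self.length})")
        for (s0, e0, k0), (s1, e1, k1) in zip(blocks, blocks[1:]):
            if e0 != s1:
                raise ValueError(f"{self.gene_id}: gap or overlap at {e0}/{s1}")
            if k0 == "I" and k1 == "I":
                raise ValueError(f"{self.gene_id}: adjacent introns at {s1}")
        if blocks[0][2] == "I" or blocks[-1][2] == "I":
            raise ValueError(f"{self.gene_id}: terminal intron (introns must be exon-flanked)")
        for intron in self.introns:
            if intron.dist_to_tes != self.length - intron.end:
                raise ValueError(f"{self.gene_id}: intron {intron.index} dist_to_tes inconsistent")
            if intron.end >= self.length:
                raise ValueError(f"{self.gene_id}: intron 3'SS at/after TES")

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def to_genomic(self, pos: int) -> int:
        """Map a transcript-relative position to a genomic coordinate."""
        if self.genomic_start is None:
            raise ValueError("gene has no genomic anchor")
        if self.strand == "+":
            return self.genomic_start + pos
        return self.genomic_end - 1 - pos

    def from_genomic(self, gpos: int) -> int:
        if self.genomic_start is None:
            raise ValueError("gene has no genomic anchor")
        if self.strand == "+":
            return gpos - self.genomic_start
        return self.genomic_end - 1 - gpos


@dataclass
class SpliceSiteProfile:
    """Per-position nucleotide probability matrix around a splice site.

    ``matrix`` has rows A, C, G, T and one column per position offset.
    Offsets use the field convention with no zero: negative offsets are on
    the exon side of a 5' site (intron side of a 3' site), positive offsets
    on the other side; +1/+2 of a 5' site are the canonical GT.
    """

    site: str  # "5prime" or "3prime"
    window: tuple[int, ...]
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if self.site not in ("5prime", "3prime"):
            raise ValueError("site must be '5prime' or '3prime'")
        colsums = self.matrix.sum(axis=0).to_numpy()
        ok = np.isnan(colsums) | (np.abs(colsums - 1.0) < 1e-9)
        if not ok.all():
            raise ValueError("profile columns must sum to 1")
        vals = self.matrix.to_numpy()
        if np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12:
            raise ValueError("probabilities must lie in [0,1]")


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def _model_from_genomic_exons(
    gene_id: str,
    chrom: str,
    strand: str,
    exons_genomic: list[tuple[int, int]],
) -> GeneModel:
    """Build a transcript-relative GeneModel from genomic exon intervals."""
    exons_genomic = sorted(exons_genomic)
    gstart = exons_genomic[0][0]
    gend = exons_genomic[-1][1]
    length = gend - gstart
    if strand == "+":
        rel = [(s - gstart, e - gstart) for s, e in exons_genomic]
    else:
        rel = sorted((gend - e, gend - s) for s, e in exons_genomic)
    introns = []
    for idx, ((_, e0), (s1, _)) in enumerate(zip(rel, rel[1:])):
        introns.append(Intron(index=idx, start=e0, end=s1, dist_to_tes=length - s1))
    return GeneModel(
        gene_id=gene_id,
        strand=strand,
        length=length,
        exons=rel,
        introns=introns,
        chrom=chrom,
        genomic_start=gstart,
        genomic_end=gend,
    )


def _parse_bed12(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path}:{lineno}: BED12 requires 12 fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                if n_blocks == 0:
                    warnings.warn(f"{path}:{lineno}: zero-block record {name!r} skipped")
                    continue
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: blockCount does not match block lists")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            models.append(_model_from_genomic_exons(name, chrom, strand, exons))
    return models


def _parse_gtf(path: Path) -> list[GeneModel]:
    import gffutils

    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # one representative transcript per gene: longest genomic span wins,
    # ties broken by transcript_id for determinism
    by_gene: dict[str, list] = {}
    for tx in db.features_of_type("transcript"):
        gene_id = tx.attributes.get("gene_id", [tx.id])[0]
        by_gene.setdefault(gene_id, []).append(tx)
    models = []
    for gene_id in sorted(by_gene):
        txs = sorted(by_gene[gene_id], key=lambda t: (-(t.end - t.start), t.id))
        tx = txs[0]
        exons = [
            (ex.start - 1, ex.end)  # GTF is 1-based inclusive
            for ex in db.children(tx, featuretype="exon")
        ]
        if not exons:
            warnings.warn(f"transcript {tx.id} has no exons; skipped")
            continue
        models.append(_model_from_genomic_exons(gene_id, tx.seqid, tx.strand, exons))
    return models


def read_annotation(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from a GTF or BED12 file.

    One representative transcript is kept per gene (the longest).  All
    coordinates are converted to the transcript-relative, strand-normalized
    frame (TSS = 0).

    Parameters
    ----------
    path : file path
    format : "GTF", "BED12", or None to infer from the extension.
    """
    path = Path(path)
    if format is None:
        format = "BED12" if path.suffix.lower() in (".bed", ".bed12") else "GTF"
    format = format.upper()
    if format == "BED12":
        return _parse_bed12(path)
    if format == "GTF":
        return _parse_gtf(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_gtf(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GTF (gene/transcript/exon features)."""
    with open(path, "w") as fh:
        for m in models:
            chrom = m.chrom or m.gene_id
            gstart = m.genomic_start if m.genomic_start is not None else 0
            gend = m.genomic_end if m.genomic_end is not None else gstart + m.length
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.1";'
            fh.write(f"{chrom}\tsplicewave\tgene\t{gstart + 1}\t{gend}\t.\t{m.strand}\t.\t{attrs}\n")
            fh.write(f"{chrom}\tsplicewave\ttranscript\t{gstart + 1}\t{gend}\t.\t{m.strand}\t.\t{attrs}\n")
            for s, e in m.exons:
                if m.strand == "+":
                    gs, ge = gstart + s, gstart + e
                else:
                    gs, ge = gend - e, gend - s
                fh.write(f"{chrom}\tsplicewave\texon\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Intron features
# ---------------------------------------------------------------------------

def intron_features(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-intron feature table: length and distance to the TES.

    Both features are also reported in log10(kilobases), the scale on which
    retained-intron length and TES-proximity shifts are usually displayed.
    ``dist_to_tes`` of 0 yields -inf in log space and is left as such.
    """
    rows = []
    for m in models:
        for intr in m.introns:
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "intron_index": intr.index,
                    "intron_id": f"{m.gene_id}:{intr.index}",
                    "length_nt": intr.length,
                    "dist_to_tes_nt": intr.dist_to_tes,
                    "klass": intr.klass,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "intron_index", "intron_id", "length_nt", "dist_to_tes_nt", "klass"],
    )
    with np.errstate(divide="ignore"):
        df["length_log10_kb"] = np.log10(df["length_nt"].to_numpy(float) / 1000.0)
        df["dist_to_tes_log10_kb"] = np.log10(df["dist_to_tes_nt"].to_numpy(float) / 1000.0)
    return df


# ---------------------------------------------------------------------------
# Splice-site profiles
# ---------------------------------------------------------------------------

DEFAULT_WINDOW_5P = tuple(o for o in range(-3, 7) if o != 0)
DEFAULT_WINDOW_3P = tuple(o for o in range(-20, 4) if o != 0)

_BASES = ("A", "C", "G", "T")


def _offset_to_index(anchor: int, offset: int) -> int:
    # no-zero offset convention: +1 is the base at `anchor`, -1 the base before
    return anchor + offset - 1 if offset > 0 else anchor + offset


def splice_site_profiles(
    models: Sequence[GeneModel],
    sequences: Mapping[str, str] | str | Path,
    window5: Sequence[int] = DEFAULT_WINDOW_5P,
    window3: Sequence[int] = DEFAULT_WINDOW_3P,
) -> tuple[SpliceSiteProfile, SpliceSiteProfile]:
    """Nucleotide probability profiles at the 5' and 3' splice sites.

    ``sequences`` maps gene_id to the pre-mRNA (sense-strand,
    transcript-relative) sequence, or is a FASTA path keyed by gene_id.
    For the 5' site, offset +1 is the first intron base (canonical G);
    for the 3' site, offset -1 is the last intron base (canonical G of AG)
    and positive offsets are exonic.  Ambiguous bases (N) are excluded from
    the column denominator.
    """
    if isinstance(sequences, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(sequences))
        sequences = {name: str(fa[name][:]) for name in fa.keys()}

    def count_matrix(window: Sequence[int], site: str) -> pd.DataFrame:
        counts = pd.DataFrame(0.0, index=list(_BASES), columns=list(window))
        for m in models:
            seq = sequences.get(m.gene_id)
            if seq is None:
                continue
            seq = seq.upper()
            for intr in m.introns:
                anchor = intr.start if site == "5prime" else intr.end
                for off in window:
                    idx = _offset_to_index(anchor, off)
                    if idx < 0 or idx >= len(seq):
                        raise ValueError(
                            f"{m.gene_id} intron {intr.index}: window offset {off} "
                            f"outside gene sequence"
                        )
                    base = seq[idx]
                    if base in _BASES:
                        counts.loc[base, off] += 1
        return counts

    profiles = []
    for window, site in ((tuple(window5), "5prime"), (tuple(window3), "3prime")):
        counts = count_matrix(window, site)
        totals = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = counts / totals.replace(0, np.nan)
        profiles.append(SpliceSiteProfile(site=site, window=window, matrix=probs))
    return profiles[0], profiles[1]
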