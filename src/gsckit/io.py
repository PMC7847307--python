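"""Readers and writers for the pipeline's plain-text formats.

narrowPeak (10-column BED dialect, q-value stored as -log10), MTX count
matrices with barcode/region sidecars, TSV expression and survival tables,
JASPAR PWM files with a TSV motif->family map, and FASTA region sequences.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .intervals import GeneAnnotation, Interval, PeakCall, SamplePeaks
from .motifs import PWM
from .sc import CellMatrix
from .survival import SurvivalRecord

__all__ = [
    "write_narrowpeak",
    "read_narrowpeak",
    "write_cell_matrix",
    "read_cell_matrix",
    "write_expression",
    "read_expression",
    "write_survival",
    "read_survival",
    "read_jaspar",
    "read_family_map",
    "read_fasta",
    "read_gene_bed",
]

_MAX_NEGLOG10 = 350.0


def write_narrowpeak(sample: SamplePeaks, path: str | Path) -> None:
    """Write peak calls as 10-column narrowPeak (q as -log10(q))."""
    with open(path, "w") as fh:
        for i, c in enumerate(sample.calls):
            neglog_q = _MAX_NEGLOG10 if c.q <= 0 else min(-np.log10(c.q), _MAX_NEGLOG10)
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{sample.sample_id}_peak{i + 1}\t0\t.\t{c.signal:.6g}\t-1\t"
                f"{neglog_q:.6g}\t-1\n"
            )


def read_narrowpeak(path: str | Path, sample_id: str | None = None, state: str | None = None) -> SamplePeaks:
    """Read a narrowPeak file; malformed lines raise with their line number."""
    calls: list[PeakCall] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path.name}:{lineno}: expected >= 9 narrowPeak columns")
            try:
                iv = Interval(parts[0], int(parts[1]), int(parts[2]))
                signal = float(parts[6])
                q = float(10.0 ** (-float(parts[8])))
            except (ValueError, IndexError) as err:
                raise ValueError(f"{path.name}:{lineno}: {err}") from err
            calls.append(PeakCall(iv, q=min(q, 1.0), signal=signal))
    return SamplePeaks(sample_id=sample_id or path.stem, calls=calls, state=state)


def write_cell_matrix(cells: CellMatrix, outdir: str | Path, regions: list[Interval] | None = None) -> None:
    """MTX counts + barcodes.tsv + regions.bed (+ GC as 4th BED column)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(cells.counts))
    (outdir / "barcodes.tsv").write_text("\n".join(cells.cell_ids) + "\n")
    with open(outdir / "regions.bed", "w") as fh:
        for j in range(cells.n_regions):
            if regions is not None:
                iv = regions[j]
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = "chr1", j * 1000, j * 1000 + 300
            fh.write(f"{chrom}\t{start}\t{end}\t{cells.region_gc[j]:.4f}\n")


def read_cell_matrix(outdir: str | Path) -> tuple[CellMatrix, list[Interval]]:
    outdir = Path(outdir)
    counts = sp.csr_matrix(scipy.io.mmread(str(outdir / "matrix.mtx")))
    barcodes = (outdir / "barcodes.tsv").read_text().splitlines()
    bed = pd.read_csv(
        outdir / "regions.bed", sep="\t", header=None, names=["chrom", "start", "end", "gc"]
    )
    regions = [Interval(r.chrom, int(r.start), int(r.end)) for r in bed.itertuples()]
    cells = CellMatrix(counts=counts, region_gc=bed["gc"].to_numpy(), cell_ids=barcodes)
    return cells, regions


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_survival(records: list[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SurvivalRecord(str(r.id), float(r.time), int(r.event), str(r.group))
        for r in df.itertuples()
    ]


def read_jaspar(path: str | Path, families: dict[str, str] | None = None) -> list[PWM]:
    """Read JASPAR-format PWMs (via Biopython), normalized to probabilities."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        colsum = counts.sum(axis=0)
        colsum[colsum == 0] = 1.0
        mid = m.matrix_id or m.name
        out.append(
            PWM(motif_id=mid, matrix=counts / colsum, family=(families or {}).get(mid))
        )
    return out


def read_family_map(path: str | Path) -> dict[str, str]:
    """TSV motif_id -> DNA-binding-domain family."""
    df = pd.read_csv(path, sep="\t", header=None, names=["motif_id", "family"], comment="#")
    return dict(zip(df["motif_id"].astype(str), df["family"].astype(str)))


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Gene annotation BED6: chrom start end gene_id score strand; TSS from strand."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"], comment="#",
    )
    out = []
    for r in df.itertuples():
        tss = int(r.start) if r.strand == "+" else int(r.end) - 1
        out.append(GeneAnnotation(str(r.gene_id), str(r.chrom), tss, str(r.strand)))
    return out
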