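"""Readers and writers for the standard and package-dialect formats.

Coordinate conventions: everything internal is 0-based half-open. GFF3 is
1-based inclusive on disk and converted on the way in and out; BED and
bedGraph are 0-based half-open and pass through unchanged. The single-c TSV
(per-cytosine calls) writes 1-based positions; the w50 TSV (window table)
writes 0-based tile starts.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mossmeth.genome import Genome
from mossmeth.simulate import ReadSet
from mossmeth.tracks import WindowTracks


# ---------------------------------------------------------------- sequences

def read_fasta(path) -> Genome:
    """Read a genome from FASTA; sequences uppercased, N preserved."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(seqs)


def write_fasta(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(genome[name]), id=name, description="") for name in genome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads, path) -> None:
    """Write (id, seq) pairs (or a ReadSet) as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# -------------------------------------------------------------- annotations

def read_gff(path) -> pd.DataFrame:
    """GFF3 -> internal frame (chrom, start, end, strand, type, id).

    GFF coordinates are 1-based inclusive; internally 0-based half-open
    (feature 101-200 becomes (100, 200)).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF fields")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            fid = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    fid = kv[3:]
            rows.append(
                {"chrom": chrom, "start": s - 1, "end": e, "strand": strand,
                 "type": ftype, "id": fid}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "type", "id"])


def write_gff3(annotations: pd.DataFrame, path, source: str = "mossmeth") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotations.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\t{row.type}\t{row.start + 1}\t{row.end}\t."
                f"\t{row.strand}\t.\tID={row.id}\n"
            )


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> internal frame, coordinates unchanged."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            row = {"chrom": fields[0], "start": int(fields[1]), "end": int(fields[2])}
            if len(fields) > 3:
                row["name"] = fields[3]
            if len(fields) > 5:
                row["strand"] = fields[5]
            rows.append(row)
    return pd.DataFrame(rows)


def write_bed(frame: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    frame[cols].to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------------- tracks

def read_bedgraph(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    if frame[["start", "end"]].isna().any().any():
        raise ValueError(f"malformed bedGraph {path}")
    return frame


def write_bedgraph(tracks: WindowTracks, feature: str, path) -> None:
    tracks.to_frame(feature).to_csv(path, sep="\t", header=False, index=False)


def tracks_from_bedgraphs(
    paths: dict[str, os.PathLike | str], window: int, chrom_lengths: dict[str, int]
) -> WindowTracks:
    """Load one bedGraph per feature onto a common window tiling."""
    tracks = WindowTracks(window, chrom_lengths)
    for feature, path in paths.items():
        frame = read_bedgraph(path)
        per_chrom = {
            chrom: np.full(tracks.n_windows(chrom), np.nan)
            for chrom in chrom_lengths
        }
        for row in frame.itertuples(index=False):
            if row.chrom in per_chrom:
                per_chrom[row.chrom][int(row.start) // window] = row.value
        for chrom, vals in per_chrom.items():
            tracks.set(feature, chrom, vals)
    return tracks


# ------------------------------------------------------- methylation tables

SINGLE_C_COLUMNS = ["chrom", "pos", "strand", "context", "subcontext",
                    "retained", "converted", "level"]


def write_single_c(calls: pd.DataFrame, path) -> None:
    """Write the per-cytosine table; positions 1-based on disk."""
    out = calls[SINGLE_C_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_single_c(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", dtype={"subcontext": str})
    calls["subcontext"] = calls["subcontext"].fillna("")
    calls["pos"] = calls["pos"] - 1
    return calls


def write_w50(windows: pd.DataFrame, path) -> None:
    """Write the window table; tile starts stay 0-based."""
    windows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_w50(path, window_size: int = 50) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame.attrs["window_size"] = window_size
    return frame


def write_dmr_bed(records: pd.DataFrame, path, window_size: int = 50) -> None:
    """DMR windows as BED (0-based half-open) with p-value and percent
    change columns."""
    out = records.copy()
    out["end"] = out["start"] + window_size
    cols = ["chrom", "start", "end", "direction", "p_value", "percent_change"]
    out[cols].to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_truth_sidecar(readset: ReadSet, path) -> None:
    readset.truth.to_csv(path, sep="\t", index=False)


def read_truth_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_sam_alignments(path, genome: Genome):
    """Adapter for an external bisulfite aligner: SAM/BAM -> pileup inputs.

    Returns ``(alignments, reads_by_id)`` in the shape
    :func:`mossmeth.align.pileup` expects. Only primary, mapped, ungapped
    records are used; the origin strand comes from the reverse flag and the
    read sequence is restored to as-sequenced orientation (SAM stores the
    forward-aligned sequence).
    """
    import pysam

    from mossmeth.genome import revcomp

    records, reads = [], {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.query_sequence is None):
                continue
            if any(op != 0 for op, _n in (rec.cigartuples or [])):
                continue  # ungapped only
            chrom = rec.reference_name
            if chrom not in genome:
                raise ValueError(f"SAM reference {chrom!r} not in genome")
            seq = rec.query_sequence.upper()
            if rec.is_reverse:
                seq = revcomp(seq)
            records.append(
                {"read_id": rec.query_name, "chrom": chrom,
                 "start": rec.reference_start,
                 "strand": "-" if rec.is_reverse else "+",
                 "mismatches": rec.get_tag("NM") if rec.has_tag("NM") else 0,
                 "unique": True}
            )
            reads[rec.query_name] = seq
    cols = ["read_id", "chrom", "start", "strand", "mismatches", "unique"]
    return pd.DataFrame(records, columns=cols), reads


def write_pileup(pile: pd.DataFrame, path) -> None:
    pile.to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
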