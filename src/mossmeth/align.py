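"""Three-letter bisulfite alignment and cytosine pileup.

Directional bisulfite libraries collapse the alphabet: a forward-strand read
can show C or T wherever the reference has C, and a reverse-strand read
shows G or A wherever the reference has G. Alignment therefore happens in
converted space — reads with C->T applied are matched against a C->T copy of
the reference (forward origins) and, reverse-complemented, against a G->A
copy (reverse origins). Note that reverse-complementing the C->T read equals
applying G->A to the reverse-complemented read, so both reduced-alphabet
read variants are exercised.

The internal aligner is exact-k-mer seed (first k bases of the converted
read) plus ungapped extension with mismatch counting; only unique best hits
within ``max_mismatches`` are kept, and reads whose best score is tied at
several loci are discarded as multi-mapped. :func:`exhaustive_align` scans
every position of both converted spaces and serves as the slow, seed-free
reference for the same contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mossmeth.genome import Genome

logger = logging.getLogger(__name__)

_C, _G, _T, _A, _N = (ord(b) for b in "CGTAN")
_CT = bytes.maketrans(b"C", b"T")
_GA = bytes.maketrans(b"G", b"A")
_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def convert_reads(reads):
    """Yield (read_id, original, c_to_t, g_to_a) per read.

    c_to_t replaces every C with T, g_to_a every G with A; the original is
    retained for the pileup. Empty reads are skipped with a warning.
    """
    for rid, seq in reads:
        if len(seq) == 0:
            logger.warning("skipping empty read %s", rid)
            continue
        b = seq.encode()
        yield rid, seq, b.translate(_CT).decode(), b.translate(_GA).decode()


@dataclass
class AlignStats:
    n_reads: int = 0
    n_usable: int = 0
    n_multimapped: int = 0
    n_unaligned: int = 0


class ConvertedIndex:
    """k-mer seed index over the two reduced-alphabet reference copies."""

    def __init__(self, genome: Genome, k: int = 20):
        if k < 4:
            raise ValueError("seed length k must be >= 4")
        self.genome = genome
        self.k = k
        self.chroms = list(genome)
        self.fwd_arrays: dict[str, np.ndarray] = {}   # C->T copy
        self.rev_arrays: dict[str, np.ndarray] = {}   # G->A copy
        self._fwd_index: dict[bytes, list] = {}
        self._rev_index: dict[bytes, list] = {}
        for chrom in self.chroms:
            raw = genome[chrom].encode()
            ct = raw.translate(_CT)
            ga = raw.translate(_GA)
            self.fwd_arrays[chrom] = np.frombuffer(ct, dtype=np.uint8)
            self.rev_arrays[chrom] = np.frombuffer(ga, dtype=np.uint8)
            for seq, index in ((ct, self._fwd_index), (ga, self._rev_index)):
                for i in range(len(seq) - k + 1):
                    index.setdefault(seq[i : i + k], []).append((chrom, i))

    def lookup(self, kmer: bytes, space: str) -> list:
        index = self._fwd_index if space == "fwd" else self._rev_index
        return index.get(kmer, [])


def _candidates(index: ConvertedIndex, ct: bytes, rc_ct: bytes):
    """Seed hits as (chrom, start, strand) triples, deduplicated."""
    k = index.k
    out = set()
    for chrom, i in index.lookup(ct[:k], "fwd"):
        out.add((chrom, i, "+"))
    for chrom, i in index.lookup(rc_ct[:k], "rev"):
        out.add((chrom, i, "-"))
    return out


def _mismatches(index: ConvertedIndex, query: np.ndarray, chrom: str,
                start: int, strand: str) -> int | None:
    ref = index.fwd_arrays[chrom] if strand == "+" else index.rev_arrays[chrom]
    if start + len(query) > len(ref):
        return None
    return int(np.count_nonzero(ref[start : start + len(query)] != query))


def align(reads, index: ConvertedIndex, max_mismatches: int = 2):
    """Seed-and-extend alignment of bisulfite reads.

    Returns ``(alignments, stats)`` where alignments is a frame with columns
    read_id, chrom, start, strand, mismatches, unique — usable (unique best)
    alignments only.
    """
    records = []
    stats = AlignStats()
    for rid, orig, ct, _ga in convert_reads(reads):
        stats.n_reads += 1
        if len(ct) < index.k:
            stats.n_unaligned += 1
            continue
        ctb = ct.encode()
        rc_ctb = ctb[::-1].translate(_COMP)
        best_mm, best_hits = None, []
        for chrom, start, strand in _candidates(index, ctb, rc_ctb):
            query = np.frombuffer(ctb if strand == "+" else rc_ctb, dtype=np.uint8)
            mm = _mismatches(index, query, chrom, start, strand)
            if mm is None or mm > max_mismatches:
                continue
            if best_mm is None or mm < best_mm:
                best_mm, best_hits = mm, [(chrom, start, strand)]
            elif mm == best_mm:
                best_hits.append((chrom, start, strand))
        if best_mm is None:
            stats.n_unaligned += 1
        elif len(best_hits) > 1:
            stats.n_multimapped += 1
        else:
            chrom, start, strand = best_hits[0]
            stats.n_usable += 1
            records.append(
                {"read_id": rid, "chrom": chrom, "start": start,
                 "strand": strand, "mismatches": best_mm, "unique": True}
            )
    cols = ["read_id", "chrom", "start", "strand", "mismatches", "unique"]
    return pd.DataFrame(records, columns=cols), stats


def exhaustive_align(reads, genome: Genome, max_mismatches: int = 2):
    """Full-scan alignment: every start position of both converted spaces.

    Same uniqueness/tie contract as :func:`align`, with no seeding heuristic;
    quadratic and intended for verification at small scale.
    """
    conv = {}
    for chrom in genome:
        raw = genome[chrom].encode()
        conv[chrom] = (
            np.frombuffer(raw.translate(_CT), dtype=np.uint8),
            np.frombuffer(raw.translate(_GA), dtype=np.uint8),
        )
    records = []
    stats = AlignStats()
    for rid, orig, ct, _ga in convert_reads(reads):
        stats.n_reads += 1
        ctb = ct.encode()
        rc_ctb = ctb[::-1].translate(_COMP)
        L = len(ctb)
        best_mm, best_hits = None, []
        for chrom, (fwd_ref, rev_ref) in conv.items():
            n = len(fwd_ref) - L + 1
            if n <= 0:
                continue
            for query_b, ref, strand in ((ctb, fwd_ref, "+"), (rc_ctb, rev_ref, "-")):
                query = np.frombuffer(query_b, dtype=np.uint8)
                mism = np.zeros(n, dtype=np.int32)
                for j in range(L):
                    mism += ref[j : j + n] != query[j]
                cap = max_mismatches if best_mm is None else min(best_mm, max_mismatches)
                hits = np.flatnonzero(mism <= cap)
                for h in hits:
                    mm = int(mism[h])
                    if best_mm is None or mm < best_mm:
                        best_mm, best_hits = mm, [(chrom, int(h), strand)]
                    elif mm == best_mm:
                        best_hits.append((chrom, int(h), strand))
        if best_mm is None:
            stats.n_unaligned += 1
        elif len(best_hits) > 1:
            stats.n_multimapped += 1
        else:
            chrom, start, strand = best_hits[0]
            stats.n_usable += 1
            records.append(
                {"read_id": rid, "chrom": chrom, "start": start,
                 "strand": strand, "mismatches": best_mm, "unique": True}
            )
    cols = ["read_id", "chrom", "start", "strand", "mismatches", "unique"]
    return pd.DataFrame(records, columns=cols), stats


def pileup(alignments: pd.DataFrame, reads_by_id: dict, genome: Genome) -> pd.DataFrame:
    """Per-cytosine retention/conversion counts from usable alignments.

    For a (+)-origin read, genomic C positions under the read count C as
    retention and T as conversion; for a (-)-origin read, genomic G positions
    count a read G (in forward orientation) as retention and A as conversion.
    Bases of the non-informative strand are never counted. Returns a frame
    with columns chrom, pos, strand, retained, converted for covered
    cytosines.
    """
    acc = {
        chrom: {
            "+": (np.zeros(L, np.int64), np.zeros(L, np.int64)),
            "-": (np.zeros(L, np.int64), np.zeros(L, np.int64)),
        }
        for chrom, L in genome.lengths.items()
    }
    for row in alignments.itertuples(index=False):
        seq = reads_by_id[row.read_id]
        arr = genome.array(row.chrom)
        L = len(seq)
        if row.start + L > len(arr):
            raise ValueError(
                f"alignment of {row.read_id} overhangs {row.chrom} end"
            )
        ref = arr[row.start : row.start + L]
        fwd_read = seq.encode()
        if row.strand == "-":
            fwd_read = fwd_read.translate(_COMP)[::-1]
        read = np.frombuffer(fwd_read, dtype=np.uint8)
        if row.strand == "+":
            cmask = ref == _C
            ret, conv = acc[row.chrom]["+"]
            hit_ret = cmask & (read == _C)
            hit_conv = cmask & (read == _T)
        else:
            gmask = ref == _G
            ret, conv = acc[row.chrom]["-"]
            hit_ret = gmask & (read == _G)
            hit_conv = gmask & (read == _A)
        np.add.at(ret, row.start + np.flatnonzero(hit_ret), 1)
        np.add.at(conv, row.start + np.flatnonzero(hit_conv), 1)

    parts = []
    for chrom in genome:
        for strand in "+-":
            ret, conv = acc[chrom][strand]
            covered = np.flatnonzero((ret > 0) | (conv > 0))
            if len(covered):
                parts.append(
                    pd.DataFrame(
                        {"chrom": chrom, "pos": covered, "strand": strand,
                         "retained": ret[covered], "converted": conv[covered]}
                    )
                )
    cols = ["chrom", "pos", "strand", "retained", "converted"]
    if not parts:
        return pd.DataFrame(columns=cols)
    out = pd.concat(parts, ignore_index=True)
    out.sort_values(["chrom", "pos", "strand"], inplace=True, kind="mergesort")
    return out.reset_index(drop=True)
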