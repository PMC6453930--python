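"""Genome container: named chromosomes of A/C/G/T/N.

All internal coordinates in the package are 0-based half-open; this module
holds the reference sequence they index into.
"""

from __future__ import annotations

from collections.abc import Mapping, Iterator

import numpy as np

VALID_BASES = frozenset(b"ACGTN")

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str | bytes) -> str | bytes:
    """Reverse complement of a sequence (N self-complements)."""
    if isinstance(seq, str):
        return seq.encode()[::-1].translate(_COMPLEMENT).decode()
    return seq[::-1].translate(_COMPLEMENT)


class Genome(Mapping):
    """Mapping of chromosome name -> uppercase sequence string.

    Sequences are validated and uppercased on construction. Byte-level numpy
    views (:meth:`array`) are cached because alignment and calling touch the
    sequence position-wise.
    """

    def __init__(self, chromosomes: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in chromosomes.items():
            up = seq.upper()
            bad = set(up.encode()) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid bases: "
                    f"{sorted(chr(b) for b in bad)}"
                )
            self._seqs[str(name)] = up
        self._arrays: dict[str, np.ndarray] = {}

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def array(self, name: str) -> np.ndarray:
        """Sequence as a read-only uint8 (ASCII) array."""
        if name not in self._arrays:
            arr = np.frombuffer(self._seqs[name].encode(), dtype=np.uint8)
            arr.flags.writeable = False
            self._arrays[name] = arr
        return self._arrays[name]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self._seqs.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self._seqs == other._seqs

    def __repr__(self) -> str:
        return f"Genome({len(self)} chromosomes, {self.total_length} bp)"
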