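"""Windowed numeric tracks (chromatin marks, siRNA counts, GC, TE length).

A :class:`WindowTracks` holds, per feature name and chromosome, one value per
fixed-size genomic window, on the same tiling the window-level methylation
tables use. Missing signal is represented as NaN for continuous features and
0 for count features; the histone "ND" rule is applied downstream where the
centile stratification needs it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mossmeth.genome import Genome


class WindowTracks:
    """Per-window numeric tracks aligned to a fixed genomic tiling."""

    def __init__(self, window: int, chrom_lengths: dict[str, int]):
        if window <= 0:
            raise ValueError("window size must be positive")
        self.window = int(window)
        self.chrom_lengths = dict(chrom_lengths)
        self._data: dict[str, dict[str, np.ndarray]] = {}

    def n_windows(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.window)

    @property
    def features(self) -> list[str]:
        return sorted(self._data)

    def set(self, feature: str, chrom: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_windows(chrom),):
            raise ValueError(
                f"track {feature!r}/{chrom}: expected "
                f"{self.n_windows(chrom)} windows, got {values.shape}"
            )
        self._data.setdefault(feature, {})[chrom] = values

    def get(self, feature: str, chrom: str) -> np.ndarray:
        return self._data[feature][chrom]

    def window_index(self, positions: np.ndarray) -> np.ndarray:
        return np.asarray(positions) // self.window

    def values_at(self, feature: str, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Track value of the window containing each (chrom, pos)."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.full(len(pos), np.nan)
        for name in np.unique(chrom):
            mask = chrom == name
            out[mask] = self._data[feature][name][pos[mask] // self.window]
        return out

    def to_frame(self, feature: str) -> pd.DataFrame:
        """Long-format frame: chrom, start, end, value."""
        parts = []
        for chrom, vals in sorted(self._data[feature].items()):
            starts = np.arange(len(vals)) * self.window
            ends = np.minimum(starts + self.window, self.chrom_lengths[chrom])
            parts.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "value": vals}
                )
            )
        return pd.concat(parts, ignore_index=True)

    def window_table(self) -> pd.DataFrame:
        """All features as columns over the full tiling."""
        frames = {}
        for feature in self.features:
            f = self.to_frame(feature).set_index(["chrom", "start"])
            frames[feature] = f["value"]
        return pd.DataFrame(frames).reset_index()

    @classmethod
    def gc_from_genome(cls, genome: Genome, window: int = 50) -> "WindowTracks":
        """GC fraction per window (N bases excluded from the denominator)."""
        tracks = cls(window, genome.lengths)
        for chrom in genome:
            arr = genome.array(chrom)
            n_win = tracks.n_windows(chrom)
            gc = np.zeros(n_win)
            for i in range(n_win):
                sub = arr[i * window : (i + 1) * window]
                acgt = np.isin(sub, np.frombuffer(b"ACGT", dtype=np.uint8)).sum()
                if acgt:
                    g_or_c = np.isin(sub, np.frombuffer(b"GC", dtype=np.uint8)).sum()
                    gc[i] = g_or_c / acgt
                else:
                    gc[i] = np.nan
            tracks.set("GC", chrom, gc)
        return tracks

    def add_gc(self, genome: Genome) -> None:
        gc = WindowTracks.gc_from_genome(genome, self.window)
        for chrom in genome:
            self.set("GC", chrom, gc.get("GC", chrom))

    def add_te_length(self, annotations: pd.DataFrame) -> None:
        """Per-window length of the covering TE (NaN outside TEs).

        Windows overlapped by a TE take that TE's length; with the simulator's
        non-overlapping annotations at most one TE touches a window.
        """
        for chrom, length in self.chrom_lengths.items():
            vals = np.full(self.n_windows(chrom), np.nan)
            tes = annotations[
                (annotations["chrom"] == chrom) & (annotations["type"] == "TE")
            ]
            for _, te in tes.iterrows():
                first = int(te["start"]) // self.window
                last = (int(te["end"]) - 1) // self.window
                vals[first : last + 1] = te["end"] - te["start"]
            self.set("TE_length", chrom, vals)
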