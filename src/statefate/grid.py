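"""Fixed-width genomic bin grid and per-bin chromatin-state tracks.

The genome is partitioned into consecutive ``bin_size``-bp bins per
chromosome (0-based, half-open: bin *b* covers ``[b*bin_size, (b+1)*bin_size)``).
Chromosomes are concatenated in declaration order so that every bin also has
a *global* index, which is what the transition machinery operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default chromatin-state alphabet (10-state model with the two quiescent
#: states fused into ``Quies``).
DEFAULT_STATES: tuple[str, ...] = (
    "TssA", "Tss", "TssFlnk", "TssBiv", "ReprPC",
    "EnhA", "EnhPr", "EnhBiv", "Quies",
)

#: State assigned to bins not covered by any segment.
QUIESCENT = "Quies"


@dataclass(frozen=True)
class GenomeGrid:
    """A genome partitioned into fixed-width bins.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp. Declaration order fixes
        the global bin order.
    bin_size
        Bin width in bp (default 200).
    """

    chrom_sizes: dict[str, int]
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)  # ceil division

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_sizes)

    @property
    def offsets(self) -> dict[str, int]:
        """Global index of the first bin of each chromosome."""
        out, acc = {}, 0
        for c in self.chrom_sizes:
            out[c] = acc
            acc += self.n_bins(c)
        return out

    def bin_index(self, chrom: str, pos) -> np.ndarray:
        """Global bin index of position(s) on ``chrom``.

        Raises
        ------
        KeyError
            Unknown chromosome.
        ValueError
            Position outside ``[0, chrom length)``.
        """
        size = self.chrom_sizes[chrom]  # KeyError if unknown
        pos = np.asarray(pos)
        if np.any((pos < 0) | (pos >= size)):
            bad = pos[(pos < 0) | (pos >= size)]
            raise ValueError(
                f"position(s) {bad.tolist()} outside chromosome {chrom!r} [0, {size})"
            )
        return self.offsets[chrom] + pos // self.bin_size

    def bin_start(self, chrom: str, local_bin) -> np.ndarray:
        return np.asarray(local_bin) * self.bin_size


@dataclass
class StateTrack:
    """Per-bin chromatin-state labels for one condition on a grid.

    ``codes`` holds one integer per global bin, indexing into ``alphabet``.
    """

    grid: GenomeGrid
    condition: str
    alphabet: tuple[str, ...]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.shape != (self.grid.total_bins,):
            raise ValueError(
                f"codes length {self.codes.shape} != grid total bins "
                f"({self.grid.total_bins},)"
            )
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= len(self.alphabet)):
            raise ValueError("state codes outside alphabet range")

    @property
    def states(self) -> np.ndarray:
        """Per-bin state labels as strings."""
        return np.asarray(self.alphabet, dtype=object)[self.codes]

    def state_counts(self) -> dict[str, int]:
        counts = np.bincount(self.codes, minlength=len(self.alphabet))
        return dict(zip(self.alphabet, counts.tolist()))

    @classmethod
    def from_states(
        cls,
        grid: GenomeGrid,
        condition: str,
        states,
        alphabet: tuple[str, ...] = DEFAULT_STATES,
    ) -> "StateTrack":
        index = {s: i for i, s in enumerate(alphabet)}
        try:
            codes = np.array([index[s] for s in states], dtype=np.int32)
        except KeyError as e:
            raise ValueError(f"state {e.args[0]!r} not in alphabet {alphabet}") from None
        return cls(grid=grid, condition=condition, alphabet=tuple(alphabet), codes=codes)
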