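"""Seven-bin transcript-length scheme shared by the simulator, the lane
quantifier and the kinetics statistics.

Bin 1 holds only the stalled 58-nt species; bin 7 contains the full-length
231-nt transcript.  Each bin is represented in mean-length calculations by
its midpoint ("theoretical RNA length"): the arithmetic middle of the bin
interval, except bin 1 whose midpoint is pinned at the stall length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BinScheme", "default_bin_scheme"]


@dataclass(frozen=True)
class BinScheme:
    """Partition of [stall, full_length] into seven length bins.

    ``edges`` are the seven interval boundaries as (lo, hi] pairs except the
    first bin which is the single stalled length {lo}.  Constructed from the
    eight boundary values ``(58, 58, 87, 116, 145, 174, 202, 231)`` by
    default: bin 1 = {58}, bin b = (edges[b-1], edges[b]] for b >= 2.
    """

    boundaries: tuple[float, ...] = (58, 58, 87, 116, 145, 174, 202, 231)

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != 8:
            raise ValueError("a seven-bin scheme needs 8 boundary values")
        if b[0] != b[1]:
            raise ValueError("bin 1 must be the single stalled length")
        if any(x >= y for x, y in zip(b[1:], b[2:])):
            raise ValueError("boundaries must be strictly increasing after bin 1")

    @property
    def n_bins(self) -> int:
        return 7

    @property
    def stall_length(self) -> float:
        return self.boundaries[0]

    @property
    def full_length(self) -> float:
        return self.boundaries[-1]

    @property
    def midpoints(self) -> np.ndarray:
        """Representative length per bin; bin 1 is the stalled length itself."""
        b = self.boundaries
        mids = [(b[i] + b[i + 1]) / 2.0 for i in range(1, 7)]
        return np.array([b[0]] + mids)

    def assign(self, lengths: np.ndarray) -> np.ndarray:
        """Map transcript lengths to 0-based bin indices.

        Lengths equal to the stall go to bin 0; otherwise bin b such that
        ``boundaries[b] < L <= boundaries[b+1]``.
        """
        lengths = np.asarray(lengths, dtype=float)
        # side='left' on the upper boundaries makes intervals right-closed
        idx = np.searchsorted(self.boundaries[2:], lengths, side="left") + 1
        idx = np.where(lengths <= self.boundaries[0], 0, idx)
        if np.any(lengths < self.boundaries[0]) or np.any(
            lengths > self.boundaries[-1]
        ):
            raise ValueError("length outside the bin scheme's support")
        return idx.astype(int)

    def fractions(self, lengths: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Seven bin fractions for a weighted length distribution."""
        idx = self.assign(lengths)
        w = np.asarray(weights, dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError("total weight must be positive")
        return np.bincount(idx, weights=w, minlength=7) / total

    def integration_edges(self) -> np.ndarray:
        """Boundaries on the continuous length axis for densitometry.

        Half-integer offsets ensure each integer transcript length's band
        center lies strictly inside its bin (58 -> bin 1, 59 -> bin 2, ...).
        """
        b = self.boundaries
        return np.array([b[0] - 0.5] + [x + 0.5 for x in b[1:]])


def default_bin_scheme() -> BinScheme:
    """The 58..231 template's conventional seven-bin partition."""
    return BinScheme()
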