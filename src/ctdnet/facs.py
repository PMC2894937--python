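"""DNA-content bracket gating for flow-cytometry event vectors.

Propidium-iodide fluorescence is proportional to DNA content, so an
asynchronous haploid yeast culture shows a 1C peak (G1 cells), a 2C peak
(G2/M cells) and an S-phase valley between them.  Gating anchors everything
on the strongest G1 signal peak (SSP) and a marker range MR = SSP/4:

    G1 bracket   = [SSP - MR, SSP + MR]
    G2 bracket   = [2*SSP - MR, 2*SSP + MR]
    S-phase      = the open interval between the G1 and G2 brackets

Events below the G1 bracket are reported as sub-G1 debris, events beyond the
G2 bracket as ">2C" content (the aneuploidy signal).  The five regions
partition the signal axis, so the five percentages sum to 100.  For a time
course, a fixed SSP can be imposed so gating stays consistent across
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FacsSample",
    "GatingBrackets",
    "BracketPercentages",
    "find_ssp",
    "compute_brackets",
    "bracket_percentages",
    "gate_sample",
]


@dataclass
class FacsSample:
    """One fluorescence event vector (one DNA-content signal per cell)."""

    events: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 1 or self.events.size == 0:
            raise ValueError("events must be a non-empty 1-D vector")
        if np.any(~np.isfinite(self.events)) or np.any(self.events < 0):
            raise ValueError("events must be non-negative finite numbers")

    @property
    def n_events(self) -> int:
        return int(self.events.size)


@dataclass(frozen=True)
class GatingBrackets:
    """Gating intervals derived from the strongest G1 signal peak (SSP)."""

    ssp: float
    mr: float
    g1: tuple[float, float]
    g2: tuple[float, float]

    @classmethod
    def from_ssp(cls, ssp: float) -> "GatingBrackets":
        ssp = float(ssp)
        if not np.isfinite(ssp) or ssp <= 0:
            raise ValueError(f"SSP must be a positive finite number, got {ssp!r}")
        mr = ssp / 4.0
        return cls(ssp=ssp, mr=mr, g1=(ssp - mr, ssp + mr), g2=(2.0 * ssp - mr, 2.0 * ssp + mr))

    @property
    def s(self) -> tuple[float, float]:
        """The open S-phase interval between the G1 and G2 brackets."""
        return (self.g1[1], self.g2[0])

    @property
    def beyond_2c(self) -> tuple[float, float]:
        return (self.g2[1], np.inf)


@dataclass(frozen=True)
class BracketPercentages:
    """Percent of events in each gating region; the five sum to 100."""

    pct_below: float
    pct_g1: float
    pct_s: float
    pct_g2: float
    pct_beyond: float

    @property
    def pct_2c_and_greater(self) -> float:
        """G2 bracket plus the >2C tail merged into one '2C and greater' figure."""
        return self.pct_g2 + self.pct_beyond

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_below": self.pct_below,
            "pct_g1": self.pct_g1,
            "pct_s": self.pct_s,
            "pct_g2": self.pct_g2,
            "pct_beyond": self.pct_beyond,
        }


def find_ssp(events: np.ndarray, bins: int = 256, smooth_window: int = 5) -> float:
    """Estimate the strongest G1 signal peak from a fluorescence histogram.

    Events are histogrammed into ``bins`` equal-width bins over
    ``[0, max(events)]``, counts are smoothed with a centered moving average
    of width ``smooth_window``, and the SSP is the center of the global
    maximum bin, with ties broken toward the lower channel.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("cannot estimate SSP from an empty event vector")
    if bins < 2:
        raise ValueError("bins must be at least 2")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd count")
    if np.ptp(events) == 0.0:
        return float(events[0])
    counts, edges = np.histogram(events, bins=bins, range=(0.0, float(events.max())))
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        smoothed = np.convolve(counts.astype(float), kernel, mode="same")
        norm = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
        counts = smoothed / norm
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[int(np.argmax(counts))])  # argmax takes the lowest tied bin


def compute_brackets(ssp: float) -> GatingBrackets:
    """Gating brackets from an SSP value: MR = SSP/4, G1 = SSP +/- MR, G2 = 2*SSP +/- MR."""
    return GatingBrackets.from_ssp(ssp)


def bracket_percentages(events: np.ndarray, brackets: GatingBrackets) -> BracketPercentages:
    """Percent of events in each gating region.

    The G1 and G2 brackets are closed, the S interval open; shared endpoints
    therefore belong to the closed brackets and the five regions partition
    the axis.
    """
    e = np.asarray(events, dtype=float)
    if e.size == 0:
        raise ValueError("events must be non-empty")
    g1_lo, g1_hi = brackets.g1
    g2_lo, g2_hi = brackets.g2
    n = e.size
    below = np.count_nonzero(e < g1_lo)
    g1 = np.count_nonzero((e >= g1_lo) & (e <= g1_hi))
    s = np.count_nonzero((e > g1_hi) & (e < g2_lo))
    g2 = np.count_nonzero((e >= g2_lo) & (e <= g2_hi))
    beyond = np.count_nonzero(e > g2_hi)
    return BracketPercentages(
        pct_below=100.0 * below / n,
        pct_g1=100.0 * g1 / n,
        pct_s=100.0 * s / n,
        pct_g2=100.0 * g2 / n,
        pct_beyond=100.0 * beyond / n,
    )


def gate_sample(
    sample: FacsSample,
    bins: int = 256,
    smooth_window: int = 5,
    fixed_ssp: float | None = None,
) -> tuple[GatingBrackets, BracketPercentages]:
    """Gate one sample: estimate (or impose) the SSP and compute percentages.

    Passing ``fixed_ssp`` applies the same brackets to every sample of a time
    course — the conservative consistent-gating mode.
    """
    ssp = float(fixed_ssp) if fixed_ssp is not None else find_ssp(
        sample.events, bins=bins, smooth_window=smooth_window
    )
    brackets = compute_brackets(ssp)
    return brackets, bracket_percentages(sample.events, brackets)
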