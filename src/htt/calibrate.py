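"""Divergence calibration from CDS identity histograms.

The identity of best-nonoverlapping sample-read hits against a reference
CDS set approximates the vertical divergence between the two lineages: the
modal histogram bin marks the speciation-level identity, and the fraction
of hits above a proposed HT threshold says how often vertical homology
alone would breach it.  Hits to paralogs are deliberately not removed —
they cannot be told from orthologs in short unassembled reads — which
biases the peak conservatively low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import Hit

__all__ = ["IdentityHistogram", "cds_identity_histogram", "validate_threshold"]


@dataclass
class IdentityHistogram:
    """Identity histogram over [0, 100] with bins of ``bin_width`` percent."""

    bin_width: float
    counts: np.ndarray          # one count per bin, bin b covers [b*w, (b+1)*w)
    n_total: int
    identities: np.ndarray = field(repr=False)

    @property
    def peak_bin(self) -> float:
        """Lower edge of the modal bin; ties resolve to the lowest-identity
        bin for a conservative (older) divergence estimate."""
        return float(np.argmax(self.counts) * self.bin_width)

    def frac_above(self, threshold: float) -> float:
        """Fraction of hits with identity strictly above ``threshold``."""
        return float(np.count_nonzero(self.identities > threshold) / self.n_total)


def cds_identity_histogram(
    sample_read_hits: Sequence[Hit],
    bin_width: float = 1.0,
) -> IdentityHistogram:
    """Histogram of per-hit identities (hits already best-nonoverlapping).

    One count per retained hit at ``floor(pct_identity / bin_width)``.
    Raises on empty input: there is nothing to calibrate from.
    """
    if not sample_read_hits:
        raise ValueError("cannot calibrate from zero hits")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idents = np.array([h.pct_identity for h in sample_read_hits])
    n_bins = int(math.floor(100.0 / bin_width)) + 1
    bins = np.minimum((idents // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    return IdentityHistogram(
        bin_width=bin_width, counts=counts, n_total=len(idents), identities=idents
    )


def validate_threshold(hist: IdentityHistogram, threshold: float) -> dict:
    """Judge whether an HT identity threshold clears the vertical background.

    Passes iff the threshold sits at least 5 points above the modal
    (speciation) identity and fewer than 5% of CDS hits exceed it.
    """
    peak = hist.peak_bin
    frac = hist.frac_above(threshold)
    return {
        "peak": peak,
        "threshold": threshold,
        "frac_above": frac,
        "n_hits": hist.n_total,
        "pass": bool(threshold >= peak + 5 and frac < 0.05),
    }
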