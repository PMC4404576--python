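"""Regulatory-loop annotation around the master transcription factor.

Two motifs are flagged. Feedforward loop type 2: an over-represented
miRNA family that is also predicted to target the master itself (the
family then regulates both the master and the master's regulon). Negative
feedback: a miRNA gene with a master binding peak close by, i.e. the
master plausibly drives a miRNA that may in turn target it or its regulon.
Whether a loop is coherent or incoherent depends on regulatory signs the
tool does not compute, so only the topology is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .background import Background
from .errors import MbisonError, TableFormatError
from .peakassoc import Peak

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MirnaLocus:
    """A miRNA gene locus (0-based half-open span)."""

    mirna_name: str
    family_id: str | None
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("start must be < end")


@dataclass
class LoopReport:
    ffl_families: list[str] = field(default_factory=list)
    feedback_mirnas: list[tuple[str, int]] = field(default_factory=list)


def load_mirna_loci(path: str | Path) -> list[MirnaLocus]:
    """Read the miRNA locus TSV (columns: mirna_name, family_id, chrom, strand, start, end)."""
    loci: list[MirnaLocus] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["mirna_name", "family_id", "chrom", "strand", "start", "end"]
        if header != expected:
            raise TableFormatError(f"miRNA locus table header {header} != {expected}")
        for line_no, raw in enumerate(fh, start=2):
            f = raw.rstrip("\n").split("\t")
            if len(f) != 6:
                raise TableFormatError(f"expected 6 columns, got {len(f)}", line=line_no)
            loci.append(
                MirnaLocus(f[0], f[1] or None, f[2], f[3], int(f[4]), int(f[5]))
            )
    return loci


def find_feedforward(
    over_represented: Iterable[str],
    master_gene: int,
    background: Background,
) -> list[str]:
    """Over-represented families predicted to target the master gene.

    A master outside the gene universe simply has no predicted sites; the
    result is empty with a warning, not an error.
    """
    over = list(over_represented)
    if master_gene not in background.gene_universe:
        logger.warning("master gene %d has no predicted miRNA sites in the background", master_gene)
        return []
    return [f for f in over if (f, master_gene) in background.pairs]


def find_feedback(
    peaks: Sequence[Peak],
    loci: Sequence[MirnaLocus],
    window_kb: float = 10,
) -> list[tuple[str, int]]:
    """miRNA genes with a master peak close by.

    Distance from a peak midpoint to a locus is 0 inside the span, else the
    gap to the nearest edge; a miRNA is reported (once, with its minimum
    distance) when any peak lies within ``window_kb * 1000`` bp. Sorted by
    distance, then name.
    """
    if not loci:
        raise MbisonError("empty miRNA locus table")
    window = window_kb * 1000
    best: dict[str, int] = {}
    for locus in loci:
        for peak in peaks:
            if peak.chrom != locus.chrom:
                continue
            mid = peak.midpoint
            if locus.start <= mid < locus.end:
                d = 0
            elif mid < locus.start:
                d = locus.start - mid
            else:
                d = mid - (locus.end - 1)
            if d <= window and (locus.mirna_name not in best or d < best[locus.mirna_name]):
                best[locus.mirna_name] = d
    return sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
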