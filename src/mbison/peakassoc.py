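"""ChIP-seq peak to gene assignment.

Two association methods mirror typical transcription-factor binding
behaviour: (a) nearest TSS within a 5/10/20 kb window, and (b) a ranked
method preferring the core promoter over the first intron. The reference
point of a peak is its interval midpoint throughout; coordinates are
0-based half-open (BED convention) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import BedError, MbisonError

WINDOW_CHOICES_KB = (5, 10, 20)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    source_index: int = 0

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene coordinates from a representative transcript.

    ``exon_starts``/``exon_ends`` are parallel, genomically sorted lists.
    The TSS is the 5' end in transcription order: tx_start on +, the last
    base (tx_end - 1) on -. The first intron is the gap between exon 1 and
    exon 2 in transcription order; single-exon genes have none.
    """

    gene_id: int
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError("tx_start must be < tx_end")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError("exon coordinate lists must be parallel")
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ValueError("exon start must be < exon end")
        if list(self.exon_starts) != sorted(self.exon_starts):
            raise ValueError("exons must be genomically sorted")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def first_intron(self) -> tuple[int, int] | None:
        """Half-open interval of the first intron in transcription order."""
        if len(self.exon_starts) < 2:
            return None
        if self.strand == "+":
            return (self.exon_ends[0], self.exon_starts[1])
        return (self.exon_ends[-2], self.exon_starts[-1])


@dataclass
class AssociationResult:
    peak_to_gene: list[tuple[Peak, int, str, int]]
    orphan_peaks: list[Peak]

    @property
    def genes(self) -> frozenset[int]:
        return frozenset(g for _, g, _, _ in self.peak_to_gene)


def read_bed(path: str | Path, source_index: int = 0) -> list[Peak]:
    """Parse a BED3+ file; track/browser/# lines are skipped, extra columns ignored."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedError(f"expected >= 3 columns, got {len(fields)}", line=line_no)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedError(f"non-integer coordinate in {fields[1:3]}", line=line_no) from None
            if start >= end:
                raise BedError(f"start {start} >= end {end}", line=line_no)
            peaks.append(Peak(chrom, start, end, source_index))
    return peaks


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the gene-model TSV, keeping one representative transcript per gene.

    Columns: gene_id, chrom, strand, tx_start, tx_end, exon_starts,
    exon_ends (comma-separated lists). When a gene has several transcripts
    the longest span wins; ties go to the smallest tx_start (deterministic).
    """
    candidates: dict[int, GeneModel] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "chrom", "strand", "tx_start", "tx_end", "exon_starts", "exon_ends"]
        if header != expected:
            raise MbisonError(f"gene-model table header {header} != {expected}")
        for raw in fh:
            f = raw.rstrip("\n").split("\t")
            model = GeneModel(
                gene_id=int(f[0]),
                chrom=f[1],
                strand=f[2],
                tx_start=int(f[3]),
                tx_end=int(f[4]),
                exon_starts=tuple(int(x) for x in f[5].split(",") if x),
                exon_ends=tuple(int(x) for x in f[6].split(",") if x),
            )
            cur = candidates.get(model.gene_id)
            if cur is None:
                candidates[model.gene_id] = model
            else:
                key = (model.tx_end - model.tx_start, -model.tx_start)
                cur_key = (cur.tx_end - cur.tx_start, -cur.tx_start)
                if key > cur_key:
                    candidates[model.gene_id] = model
    return [candidates[g] for g in sorted(candidates)]


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttx_start\ttx_end\texon_starts\texon_ends\n")
        for m in models:
            fh.write(
                f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{m.tx_start}\t{m.tx_end}\t"
                f"{','.join(map(str, m.exon_starts))}\t{','.join(map(str, m.exon_ends))}\n"
            )


def associate_nearest(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window_kb: float = 10,
) -> AssociationResult:
    """Assign each peak to the gene with the nearest TSS within the window.

    Distance is the unsigned separation between the peak midpoint and the
    TSS; ties go to the smaller gene_id. Peaks with no same-chromosome TSS
    within ``window_kb * 1000`` bp are orphans.
    """
    if not genes:
        raise MbisonError("empty gene model list")
    window = window_kb * 1000
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    assigned: list[tuple[Peak, int, str, int]] = []
    orphans: list[Peak] = []
    for peak in peaks:
        mid = peak.midpoint
        best: tuple[int, int] | None = None  # (distance, gene_id)
        for g in by_chrom.get(peak.chrom, ()):
            d = abs(mid - g.tss)
            if d <= window and (best is None or (d, g.gene_id) < best):
                best = (d, g.gene_id)
        if best is None:
            orphans.append(peak)
        else:
            assigned.append((peak, best[1], "nearest", best[0]))
    return AssociationResult(assigned, orphans)


def associate_ranked(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 500,
) -> AssociationResult:
    """Ranked assignment: core promoter beats first intron.

    A peak midpoint inside a gene's strand-aware core-promoter window
    ([TSS - upstream, TSS + downstream] in transcription orientation, both
    ends inclusive) is a promoter hit; failing that, a midpoint inside the
    first intron is an intron hit. Among candidates of equal rank the
    nearest TSS wins; ties break to the smaller gene_id.
    """
    if not genes:
        raise MbisonError("empty gene model list")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    assigned: list[tuple[Peak, int, str, int]] = []
    orphans: list[Peak] = []
    for peak in peaks:
        mid = peak.midpoint
        # (rank, distance, gene_id, tag): promoter rank 0 < intron rank 1
        best: tuple[int, int, int, str] | None = None
        for g in by_chrom.get(peak.chrom, ()):
            if g.strand == "+":
                lo, hi = g.tss - promoter_upstream, g.tss + promoter_downstream
            else:
                lo, hi = g.tss - promoter_downstream, g.tss + promoter_upstream
            d = abs(mid - g.tss)
            if lo <= mid <= hi:
                cand = (0, d, g.gene_id, "promoter")
            else:
                intron = g.first_intron
                if intron is not None and intron[0] <= mid < intron[1]:
                    cand = (1, d, g.gene_id, "first_intron")
                else:
                    continue
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is None:
            orphans.append(peak)
        else:
            assigned.append((peak, best[2], best[3], best[1]))
    return AssociationResult(assigned, orphans)


def combine_datasets(results: Sequence[AssociationResult], min_support: int = 2) -> frozenset[int]:
    """Genes supported by >= min_support distinct input files.

    A single input passes through unchanged; with several inputs a gene
    counts once per file regardless of how many of that file's peaks hit it.
    """
    if not results:
        raise MbisonError("empty results list")
    if len(results) == 1:
        return results[0].genes
    support: dict[int, int] = {}
    for r in results:
        for g in r.genes:
            support[g] = support.get(g, 0) + 1
    return frozenset(g for g, c in support.items() if c >= min_support)
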