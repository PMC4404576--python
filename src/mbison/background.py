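"""Target-prediction background construction and gene-set restriction.

The enrichment test judges a gene set against the universe of unique
(miRNA-family, gene) prediction pairs — genes without any predicted
conserved 3'UTR binding site are outside the universe and are excluded
from the analysis. Predictions are supplied per transcript (TargetScan
"conserved family info"-style tables reduced to five columns); isoforms
of one gene are pooled, so two transcripts of a gene hit by the same
family contribute a single pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import (
    EmptyBackgroundError,
    GeneSetTooLargeError,
    GeneSetTooSmallError,
    TableFormatError,
)

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse")
Namespace = Literal["entrez", "symbol", "ensembl", "refseq"]
NAMESPACES = ("entrez", "symbol", "ensembl", "refseq")

#: conservation-column values accepted by default; everything else is dropped
DEFAULT_CONSERVATION = frozenset({"conserved", "broadly conserved"})

PREDICTION_COLUMNS = ["family_id", "transcript_id", "gene_id", "species", "conservation"]
IDMAP_COLUMNS = ["entrez_id", "symbol", "ensembl_gene", "refseq_transcript"]

# run bounds for the background-restricted gene set size N
DEFAULT_MIN_N = 20
DEFAULT_MAX_N = 4000


@dataclass(frozen=True)
class TargetPrediction:
    """One per-transcript miRNA-family target prediction row."""

    family_id: str
    transcript_id: str
    gene_id: int
    species: str

    def __post_init__(self):
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        if self.gene_id <= 0:
            raise ValueError("gene_id must be positive")


@dataclass(frozen=True)
class Background:
    """Universe of unique (family, gene) pairs used by the randomization test."""

    species: str
    pairs: frozenset[tuple[str, int]]
    families: tuple[str, ...]
    gene_universe: frozenset[int]
    per_family_count: dict[str, int]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]], species: str = "human") -> "Background":
        pairset = frozenset((str(f), int(g)) for f, g in pairs)
        if not pairset:
            raise EmptyBackgroundError("empty background")
        families = tuple(sorted({f for f, _ in pairset}))
        universe = frozenset(g for _, g in pairset)
        counts = {f: 0 for f in families}
        for f, _ in pairset:
            counts[f] += 1
        return cls(species, pairset, families, universe, counts)

    def membership_matrix(self) -> tuple[np.ndarray, tuple[str, ...], np.ndarray]:
        """Dense family x gene indicator matrix.

        Returns ``(M, families, genes)`` where ``M[i, j]`` is 1 iff
        ``(families[i], genes[j])`` is a predicted pair. Genes are sorted so
        the layout is deterministic.
        """
        genes = np.array(sorted(self.gene_universe))
        gene_index = {g: j for j, g in enumerate(genes)}
        fam_index = {f: i for i, f in enumerate(self.families)}
        m = np.zeros((len(self.families), len(genes)), dtype=np.uint8)
        for f, g in self.pairs:
            m[fam_index[f], gene_index[g]] = 1
        return m, self.families, genes

    def targets_of(self, family_id: str) -> frozenset[int]:
        return frozenset(g for f, g in self.pairs if f == family_id)


@dataclass
class GeneSet:
    """A user gene set after mapping and restriction to the background."""

    requested_ids: tuple[str, ...]
    mapped_genes: frozenset[int]
    background_genes: frozenset[int]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.background_genes)

    #: alias matching the quantity's usual name in the method's description
    N = n


class IdMap:
    """Entrez / symbol / Ensembl / RefSeq identifier cross-reference.

    One row per transcript; entrez_id is the pivot namespace. Symbol lookup
    is case-insensitive.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in IDMAP_COLUMNS if c not in table.columns]
        if missing:
            raise TableFormatError(f"idmap table missing columns: {missing}")
        df = table.copy()
        df["entrez_id"] = df["entrez_id"].astype(int)
        self.table = df
        self._by_symbol: dict[str, set[int]] = {}
        self._by_ensembl: dict[str, set[int]] = {}
        self._by_refseq: dict[str, set[int]] = {}
        self._entrez: set[int] = set(df["entrez_id"])
        for row in df.itertuples(index=False):
            if isinstance(row.symbol, str) and row.symbol:
                self._by_symbol.setdefault(row.symbol.lower(), set()).add(row.entrez_id)
            if isinstance(row.ensembl_gene, str) and row.ensembl_gene:
                self._by_ensembl.setdefault(row.ensembl_gene, set()).add(row.entrez_id)
            if isinstance(row.refseq_transcript, str) and row.refseq_transcript:
                self._by_refseq.setdefault(row.refseq_transcript, set()).add(row.entrez_id)

    @classmethod
    def from_table(cls, path: str | Path) -> "IdMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "entrez_id" not in df.columns:
            raise TableFormatError(f"idmap file {path} has no entrez_id column")
        try:
            df["entrez_id"] = df["entrez_id"].astype(int)
        except (TypeError, ValueError) as exc:
            raise TableFormatError(f"non-integer entrez_id in {path}: {exc}") from exc
        return cls(df)

    def transcript_to_gene(self, transcript_id: str) -> int | None:
        hits = self._by_refseq.get(transcript_id)
        if not hits:
            return None
        return min(hits)

    def lookup(self, token: str, namespace: Namespace) -> set[int]:
        if namespace == "entrez":
            try:
                g = int(token)
            except ValueError:
                return set()
            return {g} if g in self._entrez else set()
        if namespace == "symbol":
            return set(self._by_symbol.get(token.lower(), set()))
        if namespace == "ensembl":
            return set(self._by_ensembl.get(token, set()))
        if namespace == "refseq":
            return set(self._by_refseq.get(token, set()))
        raise ValueError(f"unknown namespace: {namespace!r}")


def load_predictions(
    path: str | Path,
    species: str,
    accepted_conservation: frozenset[str] = DEFAULT_CONSERVATION,
) -> list[TargetPrediction]:
    """Read a prediction TSV, keeping only conservation-accepted rows.

    Rows whose ``conservation`` value is outside ``accepted_conservation``
    (default: conserved / broadly conserved) are dropped; duplicates are
    preserved at this stage — deduplication to unique (family, gene) pairs
    happens in :func:`build_background`.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"prediction table missing columns: {missing}")
    out: list[TargetPrediction] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        if not isinstance(row.family_id, str) or not row.family_id:
            raise TableFormatError("empty family_id", line=line_no)
        try:
            gene_id = int(row.gene_id)
        except (TypeError, ValueError):
            raise TableFormatError(f"non-integer gene_id {row.gene_id!r}", line=line_no) from None
        if gene_id <= 0:
            raise TableFormatError(f"non-positive gene_id {gene_id}", line=line_no)
        if row.species != species:
            continue
        if row.conservation not in accepted_conservation:
            continue
        out.append(TargetPrediction(row.family_id, str(row.transcript_id), gene_id, species))
    return out


def build_background(
    predictions: list[TargetPrediction],
    transcript_to_gene: IdMap | None = None,
) -> Background:
    """Pool isoforms and collect the unique (family, gene) pair background.

    When an :class:`IdMap` is given, each prediction's transcript is resolved
    through it; a transcript absent from the map falls back to the row's own
    gene_id. Unresolvable rows are excluded with a warning rather than
    aborting the build.
    """
    if not predictions:
        raise EmptyBackgroundError("empty background")
    species = predictions[0].species
    pairs: set[tuple[str, int]] = set()
    n_excluded = 0
    for p in predictions:
        gene = None
        if transcript_to_gene is not None:
            gene = transcript_to_gene.transcript_to_gene(p.transcript_id)
        if gene is None:
            gene = p.gene_id if p.gene_id > 0 else None
        if gene is None:
            n_excluded += 1
            logger.warning("transcript %s unresolvable to a gene; excluded", p.transcript_id)
            continue
        pairs.add((p.family_id, gene))
    if n_excluded:
        logger.warning("%d prediction rows excluded (unresolvable transcripts)", n_excluded)
    if not pairs:
        raise EmptyBackgroundError("empty background")
    return Background.from_pairs(pairs, species)


def load_background(
    prediction_path: str | Path,
    idmap: IdMap,
    species: str,
    accepted_conservation: frozenset[str] = DEFAULT_CONSERVATION,
) -> Background:
    """Convenience: load predictions and build the background in one step."""
    preds = load_predictions(prediction_path, species, accepted_conservation)
    return build_background(preds, idmap)


def map_gene_ids(
    tokens: Iterable[str],
    namespace: Namespace,
    idmap: IdMap,
) -> tuple[set[int], list[str]]:
    """Map raw user tokens to entrez-style gene ids.

    Tokens mapping to several entrez ids contribute all of them (the
    expansion is logged); mapping failures are collected, never fatal.
    Returns ``(mapped_ids, unmapped_tokens)``; unmapped tokens keep first-
    occurrence order.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}; expected one of {NAMESPACES}")
    mapped: set[int] = set()
    unmapped: list[str] = []
    seen_unmapped: set[str] = set()
    for token in tokens:
        token = token.strip()
        if not token:
            continue
        hits = idmap.lookup(token, namespace)
        if not hits:
            if token not in seen_unmapped:
                seen_unmapped.add(token)
                unmapped.append(token)
            continue
        if len(hits) > 1:
            logger.info("token %r maps to %d entrez ids: %s", token, len(hits), sorted(hits))
        mapped |= hits
    return mapped, unmapped


def restrict_to_background(
    mapped_genes: Iterable[int],
    background: Background,
    min_n: int = DEFAULT_MIN_N,
    max_n: int = DEFAULT_MAX_N,
    requested_ids: Iterable[str] = (),
) -> GeneSet:
    """Intersect mapped genes with the background universe and validate N.

    Genes without predicted binding sites fall outside the universe and are
    excluded (recorded in ``excluded``). The run proceeds only when
    ``min_n <= N <= max_n`` (bounds inclusive); otherwise a
    :class:`~mbison.errors.GeneSetSizeError` carrying N is raised.
    """
    mapped = frozenset(int(g) for g in mapped_genes)
    in_bg = frozenset(g for g in mapped if g in background.gene_universe)
    excluded = [(str(g), "no predicted sites") for g in sorted(mapped - in_bg)]
    n = len(in_bg)
    if n < min_n:
        raise GeneSetTooSmallError(n, min_n)
    if n > max_n:
        raise GeneSetTooLargeError(n, max_n)
    return GeneSet(tuple(requested_ids), mapped, in_bg, excluded)
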