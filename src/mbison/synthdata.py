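"""Synthetic fixture generators for every input the tool consumes.

Toy prediction tables, identifier maps, gene models, peak files, miRNA
loci and gene sets with known planted structure — all pure functions of
(spec, seed), so each emitted file is byte-reproducible and described
exactly by its manifest. The long-UTR confounder is modelled as a target
*density* multiplier applied to a fraction of genes: the enrichment test
only ever sees counts, so a higher per-gene pair probability is the
minimal faithful analogue of a longer 3'UTR attracting more predicted
sites across all families at once.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .background import Background
from .errors import MbisonError
from .peakassoc import GeneModel, Peak, write_gene_models
from .loops import MirnaLocus


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic prediction background.

    ``base_density`` is the probability that any given (family, gene) pair
    exists; genes in the long-UTR group have it multiplied by
    ``bias_factor`` (capped at 1).
    """

    n_genes: int = 40
    n_families: int = 6
    base_density: float = 0.3
    long_utr_fraction: float = 0.5
    bias_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_families < 1:
            raise ValueError("n_genes and n_families must be >= 1")
        if not (0 <= self.base_density <= 1) or not (0 <= self.long_utr_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.bias_factor < 1:
            raise ValueError("bias_factor must be >= 1")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _plan_background(spec: FixtureSpec) -> dict:
    """Deterministic draw of genes, families, pairs and transcripts."""
    rng = np.random.default_rng(spec.seed)
    genes = [1001 + i for i in range(spec.n_genes)]
    families = [f"miR-{i + 1}" for i in range(spec.n_families)]
    n_long = int(round(spec.long_utr_fraction * spec.n_genes))
    long_genes = set(int(g) for g in rng.choice(genes, size=n_long, replace=False)) if n_long else set()
    density = np.full(spec.n_genes, spec.base_density)
    for j, g in enumerate(genes):
        if g in long_genes:
            density[j] = min(1.0, spec.base_density * spec.bias_factor)
    draw = rng.random((spec.n_families, spec.n_genes))
    pairs = [
        (families[i], genes[j])
        for i in range(spec.n_families)
        for j in range(spec.n_genes)
        if draw[i, j] < density[j]
    ]
    if not pairs:
        raise MbisonError("fixture parameters yield an empty background")
    tx_per_gene = {g: int(rng.integers(1, 4)) for g in genes}
    return {
        "genes": genes,
        "families": families,
        "long_genes": sorted(long_genes),
        "pairs": pairs,
        "tx_per_gene": tx_per_gene,
        "rng": rng,
    }


def synthetic_background(spec: FixtureSpec, species: str = "human") -> Background:
    """In-memory background with exactly the pairs the table generator emits."""
    return Background.from_pairs(_plan_background(spec)["pairs"], species)


def generate_background_table(
    spec: FixtureSpec,
    outdir: str | Path,
    species: str = "human",
) -> tuple[Path, Path, dict]:
    """Emit a prediction TSV and matching IdMap TSV plus a manifest.

    Each (family, gene) pair is written once per transcript of the gene
    (1-3 transcripts per gene) so the isoform-pooling step has work to do;
    conservation flags alternate between the two accepted labels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = _plan_background(spec)
    rng = plan["rng"]
    genes, families, pairs = plan["genes"], plan["families"], plan["pairs"]
    tx_ids = {
        g: [f"NM_{g}{t:02d}" for t in range(1, plan["tx_per_gene"][g] + 1)] for g in genes
    }
    cons_labels = ("conserved", "broadly conserved")

    pred_path = outdir / "predictions.tsv"
    n_rows = 0
    with open(pred_path, "w") as fh:
        fh.write("family_id\ttranscript_id\tgene_id\tspecies\tconservation\n")
        for fam, g in pairs:
            for tx in tx_ids[g]:
                cons = cons_labels[int(rng.integers(0, 2))]
                fh.write(f"{fam}\t{tx}\t{g}\t{species}\t{cons}\n")
                n_rows += 1

    idmap_path = outdir / "idmap.tsv"
    with open(idmap_path, "w") as fh:
        fh.write("entrez_id\tsymbol\tensembl_gene\trefseq_transcript\n")
        for g in genes:
            for tx in tx_ids[g]:
                fh.write(f"{g}\tGENE{g}\tENSG{g:011d}\t{tx}\n")

    per_family = {f: 0 for f in families}
    for fam, _ in set(pairs):
        per_family[fam] += 1
    manifest = {
        "spec": asdict(spec),
        "species": species,
        "n_prediction_rows": n_rows,
        "n_pairs": len(set(pairs)),
        "genes": genes,
        "families": families,
        "long_utr_genes": plan["long_genes"],
        "per_family_count": per_family,
        "prediction_file": pred_path.name,
        "idmap_file": idmap_path.name,
    }
    write_manifest(manifest, outdir / "background_manifest.json")
    return pred_path, idmap_path, manifest


def generate_enriched_geneset(
    background: Background,
    target_family: str,
    n_set: int,
    enrichment_prob: float,
    seed: int,
    path: str | Path | None = None,
) -> tuple[list[int], dict]:
    """Draw a gene set biased toward one family's targets.

    Each member is drawn without replacement; with probability
    ``enrichment_prob`` from the family's remaining targets, otherwise
    uniformly from the remaining universe. ``enrichment_prob=0`` is a pure
    null draw; ``enrichment_prob=1`` (with enough targets) yields a set
    consisting entirely of targets.
    """
    universe = sorted(background.gene_universe)
    if n_set > len(universe):
        raise MbisonError(f"n_set {n_set} exceeds universe size {len(universe)}")
    if target_family not in background.families:
        raise MbisonError(f"unknown family {target_family!r}")
    rng = np.random.default_rng(seed)
    targets = sorted(background.targets_of(target_family))
    chosen: list[int] = []
    chosen_set: set[int] = set()
    while len(chosen) < n_set:
        pool = None
        if rng.random() < enrichment_prob:
            pool = [g for g in targets if g not in chosen_set]
        if not pool:
            pool = [g for g in universe if g not in chosen_set]
        g = int(pool[rng.integers(0, len(pool))])
        chosen.append(g)
        chosen_set.add(g)
    m_target = sum(1 for g in chosen if (target_family, g) in background.pairs)
    manifest = {
        "target_family": target_family,
        "n_set": n_set,
        "enrichment_prob": enrichment_prob,
        "seed": seed,
        "genes": sorted(chosen),
        "planted_m_target": m_target,
    }
    if path is not None:
        with open(path, "w") as fh:
            for g in sorted(chosen):
                fh.write(f"{g}\n")
        manifest["file"] = str(Path(path).name)
    return chosen, manifest


def generate_gene_models(
    n_genes: int = 10,
    seed: int = 0,
    chrom: str = "chrT",
    spacing: int = 100_000,
    start_gene_id: int = 1001,
) -> list[GeneModel]:
    """Gene models spaced >= ``spacing`` apart on one synthetic chromosome.

    The wide spacing keeps window-based association unambiguous: with the
    largest menu window (20 kb) every peak has at most one plausible gene.
    """
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n_genes):
        tx_start = 50_000 + i * spacing + int(rng.integers(0, 10_000))
        length = int(rng.integers(3_000, 12_000))
        tx_end = tx_start + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        if n_exons == 1:
            exon_starts, exon_ends = (tx_start,), (tx_end,)
        else:
            # cut the span into exon/intron alternation
            cuts = sorted(int(c) for c in rng.choice(
                np.arange(tx_start + 100, tx_end - 100), size=2 * (n_exons - 1), replace=False))
            bounds = [tx_start, *cuts, tx_end]
            exon_starts = tuple(bounds[k] for k in range(0, len(bounds), 2))
            exon_ends = tuple(bounds[k] for k in range(1, len(bounds), 2))
        models.append(GeneModel(start_gene_id + i, chrom, strand, tx_start, tx_end,
                                exon_starts, exon_ends))
    return models


def generate_peak_fixture(
    genes: Sequence[GeneModel],
    hit_genes: Sequence[int],
    window_kb: float = 10,
    n_noise_peaks: int = 0,
    seed: int = 0,
    path: str | Path | None = None,
    source_index: int = 0,
) -> tuple[list[Peak], dict]:
    """A BED fixture: one peak near each hit gene's TSS plus far-away noise.

    Hit peaks have their midpoint within half the window of the intended
    TSS; noise peaks are placed >= 2x window from every TSS (bounded
    retries, error if the layout is too crowded).
    """
    rng = np.random.default_rng(seed)
    window = int(window_kb * 1000)
    by_id = {g.gene_id: g for g in genes}
    tss = np.array([g.tss for g in genes])
    peaks: list[Peak] = []
    intended: list[tuple[int, int]] = []
    for gid in hit_genes:
        g = by_id[gid]
        offset = int(rng.integers(-window // 2, window // 2 + 1))
        mid = max(60, g.tss + offset)
        peaks.append(Peak(g.chrom, mid - 50, mid + 50, source_index))
        intended.append((gid, abs(mid - g.tss)))
    span_hi = int(tss.max()) + 300_000 if len(tss) else 300_000
    placed = 0
    attempts = 0
    while placed < n_noise_peaks:
        attempts += 1
        if attempts > 1000 * max(1, n_noise_peaks):
            raise MbisonError("could not place noise peaks away from all TSSs")
        mid = int(rng.integers(60, span_hi))
        if len(tss) and np.abs(tss - mid).min() < 2 * window:
            continue
        peaks.append(Peak(genes[0].chrom if genes else "chrT", mid - 50, mid + 50, source_index))
        placed += 1
    manifest = {
        "window_kb": window_kb,
        "seed": seed,
        "intended_associations": [[gid, d] for gid, d in intended],
        "hit_genes": sorted(int(g) for g in hit_genes),
        "n_noise_peaks": n_noise_peaks,
        "n_peaks": len(peaks),
    }
    if path is not None:
        with open(path, "w") as fh:
            fh.write('track name="synthetic_peaks"\n')
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
        manifest["file"] = str(Path(path).name)
    return peaks, manifest


def generate_mirna_loci(
    n_loci: int = 8,
    seed: int = 0,
    chrom: str = "chrT",
    families: Sequence[str] | None = None,
    spacing: int = 150_000,
    path: str | Path | None = None,
) -> list[MirnaLocus]:
    """miRNA gene loci spaced along the synthetic chromosome."""
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(n_loci):
        start = 30_000 + i * spacing + int(rng.integers(0, 20_000))
        end = start + int(rng.integers(80, 2_000))
        fam = families[i % len(families)] if families else f"miR-{i + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(MirnaLocus(f"hsa-mir-{i + 1:03d}", fam, chrom, strand, start, end))
    if path is not None:
        with open(path, "w") as fh:
            fh.write("mirna_name\tfamily_id\tchrom\tstrand\tstart\tend\n")
            for l in loci:
                fh.write(f"{l.mirna_name}\t{l.family_id or ''}\t{l.chrom}\t{l.strand}\t{l.start}\t{l.end}\n")
    return loci
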