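"""Monte-Carlo over-representation test with total-target scaling correction.

For each miRNA family A the observed target count ``m_A`` in the input gene
set is compared against the count ``z_A`` in random gene sets of the same
size drawn uniformly from the background universe. To neutralise gene-set
level confounders (e.g. longer average 3'UTRs inflate every family's count
at once), each repetition's ``z_A`` is multiplied by the ratio of total
predicted targets in the gene set to total predicted targets in that random
set before the comparison:

    ratio   = T_set / T_rand,      T_set = sum_A m_A,  T_rand = sum_A z_A
    success = z_A * ratio >= m_A                    (equality counts against)
    p_A     = (1 + #successes) / (n_reps + 1)       (add-one estimator)

Raw p-values are adjusted across all families by Benjamini-Hochberg, and
the over-representation call applies the FDR cutoff together with a
minimum-target-percentage cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .background import Background, GeneSet

# repetitions per Monte-Carlo block; fixed so results do not depend on
# memory layout or execution order
_CHUNK = 8192

#: interface menus enforced at the CLI level only
N_REPS_CHOICES = (1_000, 10_000, 100_000)
FDR_CUTOFF_RANGE = (0.005, 0.2)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Run parameters for the randomization test.

    ``n_reps``, ``fdr_cutoff`` etc. may take any sensible value at library
    level; :meth:`validate_cli` enforces the tool's interface menus
    (repetitions in {1000, 10000, 100000}, FDR cutoff in [0.005, 0.2]).
    """

    n_reps: int = 10_000
    fdr_cutoff: float = 0.05
    min_target_pct: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0 < self.fdr_cutoff <= 1):
            raise ValueError("fdr_cutoff must be in (0, 1]")
        if self.min_target_pct < 0:
            raise ValueError("min_target_pct must be >= 0")

    def validate_cli(self) -> None:
        if self.n_reps not in N_REPS_CHOICES:
            raise ValueError(f"n_reps must be one of {N_REPS_CHOICES}, got {self.n_reps}")
        lo, hi = FDR_CUTOFF_RANGE
        if not (lo <= self.fdr_cutoff <= hi):
            raise ValueError(f"fdr_cutoff must be within [{lo}, {hi}], got {self.fdr_cutoff}")


@dataclass(frozen=True)
class ObservedCounts:
    """Per-family observed target counts m_A and their total T_set."""

    m: dict[str, int]
    t_set: int


@dataclass(frozen=True)
class NullCounts:
    """Counts for one random gene set: z_A, T_rand, the scaling ratio and z_scaled."""

    z: dict[str, int]
    t_rand: int
    ratio: float
    z_scaled: dict[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.z_scaled is None:
            object.__setattr__(self, "z_scaled", {f: z * self.ratio for f, z in self.z.items()})


@dataclass(frozen=True)
class EnrichmentResult:
    family_id: str
    m_a: int
    target_pct: float
    p_raw: float
    fdr: float
    over_represented: bool


def count_targets(gene_set: GeneSet | Iterable[int], background: Background) -> ObservedCounts:
    """Count, per family, how many gene-set members are predicted targets.

    Families with zero targets in the set are included with ``m_A = 0``.
    """
    genes = gene_set.background_genes if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    m = {f: 0 for f in background.families}
    for f, g in background.pairs:
        if g in genes:
            m[f] += 1
    return ObservedCounts(m, sum(m.values()))


def sample_random_set(background: Background, n: int, rng: np.random.Generator) -> frozenset[int]:
    """Draw n distinct genes uniformly without replacement from the universe."""
    universe = sorted(background.gene_universe)
    if n > len(universe):
        raise ValueError(f"cannot draw {n} genes from a universe of {len(universe)}")
    if n == 0:
        return frozenset()
    idx = rng.choice(len(universe), size=n, replace=False)
    return frozenset(universe[i] for i in idx)


def null_counts(observed: ObservedCounts, background: Background, random_genes: Iterable[int]) -> NullCounts:
    """Null counts for a single random set, with the scaling ratio applied.

    T_rand = 0 defines ratio = 0 (all z_scaled are 0), so such repetitions
    count as successes only for families with m_A = 0.
    """
    zc = count_targets(frozenset(random_genes), background)
    t_rand = zc.t_set
    ratio = observed.t_set / t_rand if t_rand > 0 else 0.0
    return NullCounts(zc.m, t_rand, ratio)


def randomization_pvalues(
    observed: ObservedCounts,
    background: Background,
    n: int,
    config: EnrichmentConfig,
    correction: bool = True,
) -> dict[str, float]:
    """Monte-Carlo raw p-values per family.

    Each repetition draws one random set serving all families, scales its
    per-family counts by T_set/T_rand, and scores a success for family A
    when the scaled count reaches m_A. ``correction=False`` forces the ratio
    to 1 (exposed for testing the effect of the correction; the tool itself
    always corrects). The comparison is evaluated in integer arithmetic
    (z * T_set >= m * T_rand), which is exact and identical to comparing
    z * ratio >= m as real numbers.
    """
    mat, families, genes = background.membership_matrix()
    universe_size = len(genes)
    if n > universe_size:
        raise ValueError(f"gene set size {n} exceeds universe size {universe_size}")
    m = np.array([observed.m[f] for f in families], dtype=np.int64)
    t_set = observed.t_set
    mat_t = mat.T.astype(np.int64)  # genes x families

    rng = np.random.default_rng(config.seed)
    successes = np.zeros(len(families), dtype=np.int64)
    done = 0
    while done < config.n_reps:
        block = min(_CHUNK, config.n_reps - done)
        if n == 0:
            z = np.zeros((block, len(families)), dtype=np.int64)
        else:
            # uniform n-subsets: argpartition of iid uniforms
            u = rng.random((block, universe_size))
            idx = np.argpartition(u, n - 1, axis=1)[:, :n]
            ind = np.zeros((block, universe_size), dtype=np.int64)
            np.put_along_axis(ind, idx, 1, axis=1)
            z = ind @ mat_t
        t_rand = z.sum(axis=1)
        if correction:
            succ = z * t_set >= m[None, :] * t_rand[:, None]
            degenerate = t_rand == 0
            if degenerate.any():
                succ[degenerate] = (m == 0)[None, :]
        else:
            succ = z >= m[None, :]
        successes += succ.sum(axis=0)
        done += block
    return {f: float((1 + s) / (config.n_reps + 1)) for f, s in zip(families, successes)}


def bh_adjust(p: Mapping[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg step-up adjustment across the supplied families."""
    if not p:
        return {}
    families = list(p)
    raw = np.array([p[f] for f in families], dtype=float)
    if np.any((raw <= 0) | (raw > 1)):
        raise ValueError("raw p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    return {f: float(v) for f, v in zip(families, adj)}


def min_target_threshold(min_target_pct: float, n: int) -> int:
    """ceil(min_target_pct/100 * N), guarded against float representation noise."""
    return math.ceil(min_target_pct * n / 100 - 1e-9)


def _sort_results(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["fdr", "m_a", "family_id"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)


def enrich(
    gene_set: GeneSet,
    background: Background,
    config: EnrichmentConfig,
    correction: bool = True,
) -> pd.DataFrame:
    """Full per-family enrichment table for a restricted gene set.

    Columns: family_id, m_a, target_pct, p_raw, fdr, over_represented;
    sorted ascending by fdr, ties broken by descending m_a then label.
    """
    n = gene_set.n
    observed = count_targets(gene_set, background)
    p_raw = randomization_pvalues(observed, background, n, config, correction=correction)
    fdr = bh_adjust(p_raw)
    thresh = min_target_threshold(config.min_target_pct, n)
    rows = []
    for f in background.families:
        m_a = observed.m[f]
        rows.append(
            {
                "family_id": f,
                "m_a": m_a,
                "target_pct": 100.0 * m_a / n if n else 0.0,
                "p_raw": p_raw[f],
                "fdr": fdr[f],
                "over_represented": bool(fdr[f] <= config.fdr_cutoff and m_a >= thresh),
            }
        )
    return _sort_results(pd.DataFrame(rows))


def apply_cutoffs(results: pd.DataFrame, config: EnrichmentConfig, n: int) -> pd.DataFrame:
    """Over-represented sublist: fdr <= cutoff and m_A >= ceil(pct/100 * N).

    Both cutoffs are inclusive. The result keeps the canonical sort order.
    """
    thresh = min_target_threshold(config.min_target_pct, n)
    kept = results[(results["fdr"] <= config.fdr_cutoff) & (results["m_a"] >= thresh)]
    return _sort_results(kept.copy())
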