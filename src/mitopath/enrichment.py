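"""Running-sum pathway enrichment on a fold-change-ranked gene list.

The statistic is a running sum over the ranked universe: every rank
contributes a fixed increment depending on whether the gene belongs to the
query set, and the score is the extremum of the partial sums.  Significance
comes from a membership-permutation null (exact enumeration for small
problems, Monte-Carlo otherwise), with Benjamini-Hochberg control across
the tested collection and a signed standard-normal quantile for heatmap
export.

Two increment conventions are supported:

``balanced`` (default)
    members get ``+sqrt((N-G)/G)``, non-members ``-sqrt(G/(N-G))``; the
    increments sum to zero so that a set concentrated at the top of the
    ranking drives the running sum up (positive score = up-regulated).
``as_printed``
    the sign-swapped variant (members negative) kept for literal
    replication of the published formulas.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

logger = logging.getLogger(__name__)

CONVENTIONS = ("balanced", "as_printed")
MES_MODES = ("signed_extremum", "literal_max")

__all__ = [
    "RankedGeneList",
    "GeneSet",
    "GeneSetCollection",
    "IncrementVector",
    "PermutationResult",
    "EnrichmentResult",
    "EnrichmentConfig",
    "rank_genes",
    "increment_values",
    "compute_increments",
    "compute_mes",
    "permutation_test",
    "bh_fdr",
    "call_significance",
    "pvalue_to_z",
    "run_enrichment",
    "results_to_frame",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by decreasing log2 fold change."""

    genes: tuple[str, ...]
    log2fc: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("ranked list needs at least two genes")
        if len(self.genes) != len(self.log2fc):
            raise ValueError("genes and log2fc length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")
        fc = np.asarray(self.log2fc, dtype=float)
        if not np.all(np.isfinite(fc)):
            raise ValueError("non-finite log2fc in ranked list")
        if np.any(np.diff(fc) > 0):
            raise ValueError("log2fc must be non-increasing along the ranking")

    @property
    def n(self) -> int:
        return len(self.genes)

    def member_mask(self, members: Iterable[str]) -> np.ndarray:
        members = set(members)
        return np.fromiter((g in members for g in self.genes), dtype=bool, count=self.n)


@dataclass(frozen=True)
class GeneSet:
    """Named gene set; ``size`` is evaluated after universe intersection."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(members))

    @property
    def size(self) -> int:
        return len(self.members)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        return GeneSet(self.name, self.members & frozenset(universe))


class GeneSetCollection:
    """Ordered, name-keyed collection of :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene-set name: {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def names(self) -> list[str]:
        return list(self._sets)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls(GeneSet.from_iterable(name, members) for name, members in mapping.items())


@dataclass(frozen=True)
class IncrementVector:
    """Per-rank step values of the running sum."""

    values: tuple[float, ...]
    convention: str
    member_value: float
    nonmember_value: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class PermutationResult:
    mes: float
    p: float
    direction: str
    method: str  # "exhaustive" | "sampled"
    n_perm: int
    null_abs_mean: float
    null_abs_sd: float


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    mes: float
    p: float
    q: float
    z: float
    direction: str
    significant: bool
    g: int
    n: int


@dataclass(frozen=True)
class EnrichmentConfig:
    n_perm: int = 1000
    seed: int = 0
    convention: str = "balanced"
    mode: str = "signed_extremum"
    min_size: int = 5
    exhaustive_threshold: int = 10_000
    alpha: float = 0.05
    fdr_cut: float = 0.1

    def __post_init__(self) -> None:
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.mode not in MES_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def rank_genes(de_table: pd.DataFrame, gene_col: str = "gene", lfc_col: str = "log2fc") -> RankedGeneList:
    """Order genes by decreasing log2 fold change, ties broken by gene id.

    The sort is deterministic: a stable descending sort on log2fc with
    lexicographic gene id as tie-breaker.
    """
    if len(de_table) == 0:
        raise ValueError("empty differential-expression table")
    if de_table[gene_col].duplicated().any():
        dups = de_table.loc[de_table[gene_col].duplicated(), gene_col].tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    fc = pd.to_numeric(de_table[lfc_col], errors="raise")
    if not np.isfinite(fc.to_numpy(dtype=float)).all():
        raise ValueError("log2fc contains NaN or infinite values")
    ordered = de_table.assign(**{lfc_col: fc}).sort_values(
        [lfc_col, gene_col], ascending=[False, True], kind="mergesort"
    )
    return RankedGeneList(
        genes=tuple(ordered[gene_col].astype(str)),
        log2fc=tuple(float(x) for x in ordered[lfc_col]),
    )


def increment_values(n: int, g: int, convention: str = "balanced") -> tuple[float, float]:
    """Return ``(member_value, nonmember_value)`` for a set of size *g* in a universe of *n*."""
    if not 0 < g < n:
        raise ValueError(f"degenerate gene set: G={g} with N={n}")
    big = math.sqrt((n - g) / g)
    small = math.sqrt(g / (n - g))
    if convention == "balanced":
        return big, -small
    if convention == "as_printed":
        return -small, big
    raise ValueError(f"unknown convention {convention!r}")


def compute_increments(
    ranked: RankedGeneList, geneset: GeneSet, convention: str = "balanced"
) -> IncrementVector:
    """Per-rank increments for *geneset* after intersection with the ranked universe."""
    effective = geneset.intersect(ranked.genes)
    member_val, nonmember_val = increment_values(ranked.n, effective.size, convention)
    mask = ranked.member_mask(effective.members)
    values = np.where(mask, member_val, nonmember_val)
    return IncrementVector(
        values=tuple(values.tolist()),
        convention=convention,
        member_value=member_val,
        nonmember_value=nonmember_val,
    )


def _signed_extremum(running: np.ndarray) -> float:
    hi = float(running.max())
    lo = float(running.min())
    return hi if hi >= -lo else lo  # exact-magnitude ties go positive


def compute_mes(increments: IncrementVector, mode: str = "signed_extremum") -> float:
    """Extremum of the running sum of *increments*.

    ``signed_extremum`` returns the partial sum of maximal absolute value
    (sign encodes direction); ``literal_max`` returns ``max_j S_j``.
    """
    running = np.cumsum(increments.as_array())
    if mode == "literal_max":
        return float(running.max())
    if mode == "signed_extremum":
        return _signed_extremum(running)
    raise ValueError(f"unknown mode {mode!r}")


def _mes_from_masks(masks: np.ndarray, member_val: float, nonmember_val: float, mode: str) -> np.ndarray:
    """Vectorised score for a batch of boolean membership patterns (rows)."""
    increments = np.where(masks, member_val, nonmember_val)
    running = np.cumsum(increments, axis=1)
    if mode == "literal_max":
        return running.max(axis=1)
    hi = running.max(axis=1)
    lo = running.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def permutation_test(
    ranked: RankedGeneList,
    geneset: GeneSet,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive_threshold: int = 10_000,
    convention: str = "balanced",
    mode: str = "signed_extremum",
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Membership-permutation null for the running-sum score.

    Positions of set members within the ranking are permuted uniformly.
    When the number of membership patterns ``C(N, G)`` is at most
    *exhaustive_threshold* all patterns are enumerated and the exact tail
    proportion is returned; otherwise *n_perm* patterns are sampled and the
    add-one-corrected estimator ``(1 + hits) / (n_perm + 1)`` is used.
    Two-sidedness is on the absolute score.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    effective = geneset.intersect(ranked.genes)
    member_val, nonmember_val = increment_values(ranked.n, effective.size, convention)
    obs_mask = ranked.member_mask(effective.members)
    obs = _mes_from_masks(obs_mask[None, :], member_val, nonmember_val, mode)[0]

    n, g = ranked.n, effective.size
    if math.comb(n, g) <= exhaustive_threshold:
        null = _exhaustive_null(n, g, member_val, nonmember_val, mode)
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        method = "exhaustive"
        n_used = len(null)
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        base = np.tile(obs_mask, (n_perm, 1))
        perm_masks = rng.permuted(base, axis=1)
        null = _mes_from_masks(perm_masks, member_val, nonmember_val, mode)
        hits = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
        p = (1 + hits) / (n_perm + 1)
        method = "sampled"
        n_used = n_perm
    direction = "up" if obs >= 0 else "down"
    return PermutationResult(
        mes=float(obs),
        p=float(p),
        direction=direction,
        method=method,
        n_perm=n_used,
        null_abs_mean=float(np.mean(np.abs(null))),
        null_abs_sd=float(np.std(np.abs(null))),
    )


def _exhaustive_null(n: int, g: int, member_val: float, nonmember_val: float, mode: str) -> np.ndarray:
    patterns = list(itertools.combinations(range(n), g))
    masks = np.zeros((len(patterns), n), dtype=bool)
    for row, idx in enumerate(patterns):
        masks[row, list(idx)] = True
    return _mes_from_masks(masks, member_val, nonmember_val, mode)


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, ``q_(i) = min_{j>=i} p_(j) m / j``."""
    p = np.asarray(list(pvalues) if not isinstance(pvalues, np.ndarray) else pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_significance(p: float, q: float, alpha_nominal: float = 0.05, fdr_cut: float = 0.1) -> bool:
    """Joint call: nominal permutation p below *alpha_nominal* and BH q below *fdr_cut*."""
    return bool(p < alpha_nominal and q < fdr_cut)


def pvalue_to_z(p: float, direction: str) -> float:
    """Signed standard-normal quantile of a two-sided p, ``sign * ndtri(1 - p/2)``."""
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    z = float(ndtri(1.0 - p / 2.0))
    return z if direction == "up" else -z


def run_enrichment(
    de_table: pd.DataFrame,
    collection: GeneSetCollection | Mapping[str, Iterable[str]],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Full per-contrast procedure: rank, score, permute, BH-adjust, call, convert.

    Sets reduced below ``min_size`` members (or above ``N - min_size``) by
    universe intersection are skipped and logged.  The BH family is the
    collection tested within this one contrast.
    """
    config = config or EnrichmentConfig()
    if not isinstance(collection, GeneSetCollection):
        collection = GeneSetCollection.from_mapping(collection)
    ranked = rank_genes(de_table)
    n = ranked.n

    tested: list[tuple[GeneSet, PermutationResult]] = []
    seeds = np.random.SeedSequence(config.seed).spawn(len(collection))
    for gene_set, ss in zip(collection, seeds):
        effective = gene_set.intersect(ranked.genes)
        if effective.size < config.min_size or effective.size > n - config.min_size:
            logger.warning(
                "skipping gene set %r: G=%d outside [%d, %d] after universe intersection",
                gene_set.name, effective.size, config.min_size, n - config.min_size,
            )
            continue
        perm = permutation_test(
            ranked,
            effective,
            n_perm=config.n_perm,
            exhaustive_threshold=config.exhaustive_threshold,
            convention=config.convention,
            mode=config.mode,
            rng=np.random.default_rng(ss),
        )
        tested.append((effective, perm))
    if not tested:
        raise ValueError("no testable gene sets after size filtering")

    qvals = bh_fdr([perm.p for _, perm in tested])
    results = []
    for (gene_set, perm), q in zip(tested, qvals):
        z = pvalue_to_z(perm.p, perm.direction)
        results.append(
            EnrichmentResult(
                pathway=gene_set.name,
                mes=perm.mes,
                p=perm.p,
                q=float(q),
                z=z,
                direction=perm.direction,
                significant=call_significance(perm.p, q, config.alpha, config.fdr_cut),
                g=gene_set.size,
                n=n,
            )
        )
    return results


def results_to_frame(results: Iterable[EnrichmentResult], contrast: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "mes": r.mes,
                "p": r.p,
                "q": r.q,
                "z": r.z,
                "direction": r.direction,
                "significant": r.significant,
                "g": r.g,
                "n": r.n,
            }
            for r in results
        ]
    )
    if contrast is not None:
        df.insert(1, "contrast", contrast)
    return df
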