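"""Target-set overlap statistics with a permutation null.

The question: does a differential-expression gene list intersect a pathway
target set (NF-kB, TNF, IL-6, IFN-beta targets and the like) more than
random gene lists of the same size would?  Gene labels are permuted --
``B`` random subsets of the DE-list size are drawn uniformly without
replacement from the measurable universe -- and the empirical P-value uses
the plus-one rule, p = (1 + #{overlap >= observed}) / (B + 1), so p is never
zero and never exceeds 1.  Because draws are uniform the exact null is
hypergeometric; ``hypergeom_tail`` computes that tail by direct summation
with integer arithmetic and serves as the analytic oracle for the
permutation machinery.

The universe defaults to the genes actually measured on the chip after
collapsing probe sets to unique symbols (the measurable background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .iotables import GeneSetCollection


@dataclass
class EnrichmentResult:
    """Permutation enrichment of one target set against one DE list."""

    set_name: str
    universe_size: int          # N
    de_size: int                # m
    target_size: int            # K, restricted to the universe
    overlap: int                # k observed
    expected_overlap: float     # m * K / N
    p: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= min(self.de_size, self.target_size):
            raise ValueError("overlap outside [0, min(m, K)]")
        lo = 1.0 / (self.n_permutations + 1)
        if not lo - 1e-12 <= self.p <= 1.0 + 1e-12:
            raise ValueError(f"empirical p {self.p} outside [1/(B+1), 1]")


def hypergeom_tail(N: int, K: int, m: int, k: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, m), by direct summation.

    N balls, K marked, m drawn without replacement; integer binomials keep
    the sum exact to double rounding only.
    """
    if not (0 <= K <= N and 0 <= m <= N):
        raise ValueError("need 0 <= K, m <= N")
    if k < 0 or k > min(m, K):
        raise ValueError(f"overlap k={k} impossible for N={N}, K={K}, m={m}")
    if k <= max(0, m + K - N):
        return 1.0  # k at or below the support floor: the event is certain
    total = comb(N, m)
    acc = 0
    for i in range(k, min(m, K) + 1):
        acc += comb(K, i) * comb(N - K, m - i)
    return acc / total


def _draw_null_overlaps(
    rng: np.random.Generator,
    universe: list[str],
    m: int,
    target_indicator: dict[str, np.ndarray],
    B: int,
) -> dict[str, np.ndarray]:
    """Overlap counts of B uniform size-m draws with each target set.

    One set of permutation draws is shared across all target sets.
    """
    N = len(universe)
    names = list(target_indicator)
    ind = np.stack([target_indicator[n] for n in names]).astype(np.int64)  # sets x N
    counts = {n: np.empty(B, dtype=int) for n in names}
    if m == 0:
        return {n: np.zeros(B, dtype=int) for n in names}
    # uniform size-m subsets as the top-m of per-draw random keys, chunked
    chunk = max(1, min(B, 4_000_000 // max(N, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]  # b x m
        for j, n in enumerate(names):
            counts[n][done:done + b] = ind[j][idx].sum(axis=1)
        done += b
    return counts


def permutation_enrichment(
    de_genes: set[str],
    target_set: set[str],
    universe: set[str] | list[str],
    B: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test of one target set; see the module docstring."""
    results = enrich_all(
        de_genes, GeneSetCollection({"target": set(target_set)}), universe, B=B, seed=seed
    )
    r = results[0]
    r.set_name = "target"
    return r


def enrich_all(
    de_genes: set[str],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
    B: int = 10000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Permutation enrichment of every set in a collection, sorted by p.

    The same B permutation draws are reused across sets, which both saves
    time and makes the per-set p-values comparable draws-for-draws.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    universe_list = sorted(set(universe))
    N = len(universe_list)
    de = set(de_genes)
    if not de <= set(universe_list):
        raise ValueError("de_genes must be a subset of the universe")
    m = len(de)
    if m > N:
        raise ValueError("DE list larger than the universe")
    if B < 100:
        warnings.warn(f"B={B} permutations is very low; p-values will be coarse")

    pos = {g: i for i, g in enumerate(universe_list)}
    indicators: dict[str, np.ndarray] = {}
    restricted: dict[str, set[str]] = {}
    for name, members in collection.items():
        inside = set(members) & set(universe_list)
        if not inside:
            raise ValueError(f"target set {name!r} does not intersect the universe")
        ind = np.zeros(N, dtype=bool)
        ind[[pos[g] for g in inside]] = True
        indicators[name] = ind
        restricted[name] = inside

    rng = np.random.default_rng(seed)
    null_overlaps = _draw_null_overlaps(rng, universe_list, m, indicators, B)

    results = []
    for name, inside in restricted.items():
        k = len(de & inside)
        K = len(inside)
        p = (1 + int((null_overlaps[name] >= k).sum())) / (B + 1)
        results.append(EnrichmentResult(
            set_name=name,
            universe_size=N,
            de_size=m,
            target_size=K,
            overlap=k,
            expected_overlap=m * K / N,
            p=p,
            n_permutations=B,
            seed=seed,
        ))
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def write_enrichment(results: list[EnrichmentResult], tsv_path, json_path=None) -> None:
    df = results_frame(results)
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        df.to_json(json_path, orient="records", indent=2)


__all__ = [
    "EnrichmentResult",
    "enrich_all",
    "hypergeom_tail",
    "permutation_enrichment",
    "results_frame",
    "write_enrichment",
]
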