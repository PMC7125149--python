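"""Permutation gene-set enrichment against a background universe, with an
exact hypergeometric tail as analytic counterpart.

The empirical null for one (input set, target set) pair is built by drawing
|input| genes from the background without replacement ``n_permutations``
times; the p-value is the fraction of draws whose overlap with the target
is at least the observed overlap. This literal rule can return p = 0, so
results carry the raw exceedance count and render −log10 p against the
1/n_permutations resolution floor.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Collection, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import GeneSetCollection

DEFAULT_N_PERMUTATIONS = 10_000

#: Cap on the random-key matrix used for vectorised sampling (floats).
_CHUNK_BUDGET = 4_000_000


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one input-set x target-set permutation test."""

    input_set: str
    target_set: str
    n_input: int
    n_target: int
    n_background: int
    overlap: int
    n_permutations: int
    exceedance_count: int
    p_perm: float
    seed: int | None

    @property
    def p_is_zero(self) -> bool:
        return self.exceedance_count == 0

    @property
    def neg_log10_p(self) -> float:
        """−log10 of the permutation p; a zero p is reported at the
        resolution floor −log10(1/n_permutations) (a lower bound)."""
        p = self.p_perm if not self.p_is_zero else 1.0 / self.n_permutations
        return -math.log10(p)

    def display_p(self) -> str:
        if self.p_is_zero:
            return f"<{1.0 / self.n_permutations:g}"
        return f"{self.p_perm:g}"


def _check_membership(name: str, members: frozenset[str], universe: frozenset[str],
                      clip_to_universe: bool) -> frozenset[str]:
    outside = members - universe
    if not outside:
        return members
    if clip_to_universe:
        return members & universe
    raise ValidationError(
        f"{name} has {len(outside)} members outside the universe "
        f"(e.g. {sorted(outside)[:5]}); pass clip_to_universe=True to intersect"
    )


def permutation_enrichment(input_set: Collection[str], target_set: Collection[str],
                           universe: Collection[str],
                           n_permutations: int = DEFAULT_N_PERMUTATIONS,
                           seed: int | None = None,
                           clip_to_universe: bool = False,
                           pseudocount: bool = False,
                           input_name: str = "input",
                           target_name: str = "target") -> EnrichmentResult:
    """Permutation test of the overlap between an input and a target set.

    Draws ``n_permutations`` same-size gene lists from the universe without
    replacement and counts those whose overlap with the target is >= the
    observed overlap. p = count / n_permutations; with ``pseudocount=True``
    the (count + 1)/(n_permutations + 1) variant is reported instead, which
    cannot be zero. Identical seeds reproduce identical counts.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    universe_list = sorted(set(universe))
    uni = frozenset(universe_list)
    inp = _check_membership(f"input set {input_name!r}", frozenset(input_set), uni,
                            clip_to_universe)
    tgt = _check_membership(f"target set {target_name!r}", frozenset(target_set), uni,
                            clip_to_universe)
    n_bg, n_in, n_tg = len(universe_list), len(inp), len(tgt)
    k_obs = len(inp & tgt)

    if n_in == 0:
        count = n_permutations  # empty input: every draw trivially reaches k = 0
    else:
        index = {g: i for i, g in enumerate(universe_list)}
        target_mask = np.zeros(n_bg, dtype=bool)
        target_mask[[index[g] for g in tgt]] = True
        rng = np.random.default_rng(seed)
        count = 0
        remaining = n_permutations
        rows_per_chunk = max(1, _CHUNK_BUDGET // n_bg)
        while remaining > 0:
            rows = min(rows_per_chunk, remaining)
            keys = rng.random((rows, n_bg))
            draws = np.argpartition(keys, n_in - 1, axis=1)[:, :n_in]
            overlaps = target_mask[draws].sum(axis=1)
            count += int((overlaps >= k_obs).sum())
            remaining -= rows
    p = (count + 1) / (n_permutations + 1) if pseudocount else count / n_permutations
    return EnrichmentResult(
        input_set=input_name, target_set=target_name,
        n_input=n_in, n_target=n_tg, n_background=n_bg,
        overlap=k_obs, n_permutations=n_permutations,
        exceedance_count=count, p_perm=p, seed=seed,
    )


def hypergeometric_tail(k: int, n_input: int, n_target: int, n_background: int) -> float:
    """Exact P(overlap >= k) for an |input|-sized draw from the background.

    Sum over j = k .. min(n_input, n_target) of
    C(n_target, j) C(n_background − n_target, n_input − j) / C(n_background, n_input),
    evaluated stably via the survival function of the hypergeometric
    distribution. The analytic counterpart of the permutation null.
    """
    if not (0 <= k <= min(n_input, n_target) <= n_background):
        raise ValidationError(
            f"infeasible arguments: k={k}, n_input={n_input}, "
            f"n_target={n_target}, n_background={n_background}"
        )
    if n_input > n_background or n_target > n_background:
        raise ValidationError("set sizes cannot exceed n_background")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_background, n_target, n_input))


def pair_seed(master_seed: int | None, input_name: str, target_name: str) -> int:
    """Deterministic per-pair sub-seed, independent of grid traversal order."""
    entropy = [
        0 if master_seed is None else int(master_seed),
        zlib.crc32(input_name.encode()),
        zlib.crc32(target_name.encode()),
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def enrichment_grid(input_collections: GeneSetCollection | dict,
                    target_collections: GeneSetCollection | dict,
                    universe: Collection[str],
                    n_permutations: int = DEFAULT_N_PERMUTATIONS,
                    seed: int | None = None,
                    clip_to_universe: bool = False,
                    pseudocount: bool = False) -> list[EnrichmentResult]:
    """Run the permutation test for every (input, target) pair.

    Each pair gets an independent sub-seed derived deterministically from
    the master seed and the pair's set names, so the grid is invariant to
    the order in which pairs are computed.
    """
    inputs = dict(input_collections.sets) if isinstance(input_collections, GeneSetCollection) \
        else dict(input_collections)
    targets = dict(target_collections.sets) if isinstance(target_collections, GeneSetCollection) \
        else dict(target_collections)
    results = []
    for in_name, in_members in inputs.items():
        for t_name, t_members in targets.items():
            results.append(permutation_enrichment(
                in_members, t_members, universe,
                n_permutations=n_permutations,
                seed=pair_seed(seed, in_name, t_name),
                clip_to_universe=clip_to_universe,
                pseudocount=pseudocount,
                input_name=in_name, target_name=t_name,
            ))
    return results


def grid_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Flatten grid results to a TSV-ready table sorted by (input_set, target_set)."""
    rows = [
        {
            "input_set": r.input_set, "target_set": r.target_set,
            "n_input": r.n_input, "n_target": r.n_target,
            "n_background": r.n_background, "overlap": r.overlap,
            "n_permutations": r.n_permutations,
            "exceedance_count": r.exceedance_count,
            "p_perm": r.p_perm, "neg_log10_p": r.neg_log10_p,
            "p_display": r.display_p(), "seed": r.seed,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values(
        ["input_set", "target_set"], kind="mergesort"
    ).reset_index(drop=True)
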