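"""Analytic rarefaction and Good's coverage.

The expected number of species seen in a uniform random subsample of
``n`` sequences drawn without replacement from a group with species
abundances N_1..N_S (N = sum N_i) is the hypergeometric expectation

    E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n)),

with C(a, b) = 0 when a < b.  Binomial coefficients are evaluated in
log space (gammaln) so the computation never overflows.  A seeded
Monte-Carlo subsampler is provided as an independent cross-check of the
closed form; production output always uses the analytic curve because
it is deterministic.

Good's coverage 1 - F1/N estimates the fraction of a group's
individuals whose species is represented more than once (F1 = number of
singleton species).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import ValidationError


def _validated(abundances: Sequence[int]) -> np.ndarray:
    arr = np.asarray(abundances, dtype=np.int64)
    if arr.size == 0:
        raise ValidationError("abundance vector is empty")
    if (arr < 1).any():
        raise ValidationError("abundances must all be >= 1")
    return arr


def _log_choose(a: np.ndarray | int, b: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def expected_richness(abundances: Sequence[int], n: int) -> float:
    """Hypergeometric expected species richness at subsample size n."""
    arr = _validated(abundances)
    N = int(arr.sum())
    if not 1 <= n <= N:
        raise ValidationError(f"subsample size {n} outside [1, {N}]")
    rest = N - arr
    terms = np.zeros(arr.size, dtype=float)
    feasible = rest >= n  # C(N - N_i, n) > 0 only when N - N_i >= n
    if feasible.any():
        terms[feasible] = np.exp(_log_choose(rest[feasible], n) - _log_choose(N, n))
    return float(np.sum(1.0 - terms))


def goods_coverage(abundances: Sequence[int]) -> float:
    """Good's coverage estimate 1 - F1/N."""
    arr = _validated(abundances)
    f1 = int(np.count_nonzero(arr == 1))
    return 1.0 - f1 / int(arr.sum())


def simulated_richness(
    abundances: Sequence[int],
    n: int,
    n_iter: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo mean and standard error of subsampled richness.

    Serves as the independent resampling oracle for the analytic
    expectation; seeded and vectorised.
    """
    arr = _validated(abundances)
    N = int(arr.sum())
    if not 1 <= n <= N:
        raise ValidationError(f"subsample size {n} outside [1, {N}]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = np.repeat(np.arange(arr.size), arr)
    richness = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        pick = rng.choice(N, size=n, replace=False)
        richness[it] = np.unique(labels[pick]).size
    mean = float(richness.mean())
    se = float(richness.std(ddof=1) / np.sqrt(n_iter)) if n_iter > 1 else float("nan")
    return mean, se


def curve_family(
    groups: Mapping[str, Sequence[int]], depths: Iterable[int]
) -> pd.DataFrame:
    """Rarefaction curves for several groups over a shared depth grid.

    The grid is clipped per group to its total sequence count N.
    Returns a long-format table (group, n, expected_richness).
    """
    depth_list = sorted(set(int(d) for d in depths))
    if any(d < 1 for d in depth_list):
        raise ValidationError("depths must be >= 1")
    rows = []
    for group, abundances in groups.items():
        arr = _validated(abundances)
        N = int(arr.sum())
        for n in depth_list:
            if n > N:
                continue
            rows.append(
                {
                    "group": group,
                    "n": n,
                    "expected_richness": expected_richness(arr, n),
                }
            )
    return pd.DataFrame(rows, columns=["group", "n", "expected_richness"])


def coverage_table(groups: Mapping[str, Sequence[int]]) -> pd.DataFrame:
    """Per-group N, observed richness S, singletons F1 and coverage."""
    rows = []
    for group, abundances in groups.items():
        arr = _validated(abundances)
        rows.append(
            {
                "group": group,
                "N": int(arr.sum()),
                "S": int(arr.size),
                "F1": int(np.count_nonzero(arr == 1)),
                "coverage": goods_coverage(arr),
            }
        )
    return pd.DataFrame(rows, columns=["group", "N", "S", "F1", "coverage"])


def group_abundances(
    assignment, records, *, by: str = "suborder", labels: Sequence[str] | None = None
) -> dict[str, list[int]]:
    """Species-abundance vectors per group for rarefaction input.

    ``by`` is either a rank name (group sequences by that taxon) or
    ``"env"`` (group by environmental category); species membership is
    always the assignment's own species partition.
    """
    from .core import ENV_CATEGORIES, RANKS

    species_of = {s: assignment.label(s, "species") for s in assignment.paths}
    if by == "env":
        by_id = {rec.id: rec for rec in records}
        group_of = {s: by_id[s].env_category for s in assignment.paths}
    elif by in RANKS:
        group_of = {
            s: assignment.name_of(assignment.label(s, by)) for s in assignment.paths
        }
    else:
        raise ValidationError(f"unknown grouping {by!r}")
    out: dict[str, dict[tuple, int]] = {}
    for seq_id, group in group_of.items():
        out.setdefault(group, {})
        sp = species_of[seq_id]
        out[group][sp] = out[group].get(sp, 0) + 1
    if labels is not None:
        out = {g: v for g, v in out.items() if g in set(labels)}
    return {g: sorted(v.values(), reverse=True) for g, v in sorted(out.items())}
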