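"""Validation of predicted profiles against literature co-occurrence.

Each disease's NAAS vector is compared with its literature sampling
frequencies over the shared cytokine subset using Spearman's rank
correlation.  P-values come from the exact permutation distribution for
short vectors (full enumeration, n <= 10), from a seeded Monte-Carlo
permutation null, or from the asymptotic t approximation (the default for
realistic vector lengths).  A Bonferroni-corrected cutoff controls the
family-wise error over diseases, and a disease counts as validated when its
correlation is positive and significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .profiles import CytokineProfile

EXACT_MAX_N = 10


@dataclass
class ValidationResult:
    """Spearman comparison of one disease's profile with literature data."""

    disease_id: str
    rho: float  # NaN when degenerate
    p_value: float
    n_cytokines_compared: int
    degenerate: bool = False  # a constant input vector: rho undefined


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_validate(
    naas_vec: Sequence[float],
    lit_freq_vec: Sequence[float],
    mode: Literal["exact", "permutation", "asymptotic"] = "asymptotic",
    n_perm: int = 100_000,
    seed: int | None = None,
    disease_id: str = "",
    alternative: Literal["two-sided", "greater"] = "two-sided",
) -> ValidationResult:
    """Spearman rho (average-rank ties) with a permutation or asymptotic p.

    ``exact`` enumerates all n! permutations (only for n <= 10);
    ``permutation`` draws ``n_perm`` seeded Monte-Carlo permutations and
    applies the add-one estimator; ``asymptotic`` uses the t approximation.
    """
    x = np.asarray(naas_vec, dtype=float)
    y = np.asarray(lit_freq_vec, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("vectors must be 1-D and aligned")
    n = len(x)
    if n < 3:
        raise InvalidParameterError(f"need >= 3 paired observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ValidationResult(disease_id, float("nan"), 1.0, n, degenerate=True)

    rx = stats.rankdata(x)  # average ranks
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    eps = 1e-12

    if mode == "asymptotic":
        p = stats.spearmanr(x, y, alternative=alternative).pvalue
    elif mode == "exact":
        if n > EXACT_MAX_N:
            raise InvalidParameterError(f"exact enumeration limited to n <= {EXACT_MAX_N}")
        count = total = 0
        for perm in permutations(ry):
            r = _spearman_rho(rx, np.asarray(perm))
            total += 1
            if alternative == "greater":
                count += r >= rho - eps
            else:
                count += abs(r) >= abs(rho) - eps
        p = count / total
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        rx0 = rx - rx.mean()
        rx0 /= np.linalg.norm(rx0)
        ry0 = ry - ry.mean()
        ry0 /= np.linalg.norm(ry0)
        perms = np.empty((n_perm, n))
        for i in range(n_perm):
            perms[i] = rng.permutation(ry0)
        r_null = perms @ rx0
        if alternative == "greater":
            exceed = int(np.sum(r_null >= rho - eps))
        else:
            exceed = int(np.sum(np.abs(r_null) >= abs(rho) - eps))
        p = (1 + exceed) / (1 + n_perm)
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    return ValidationResult(disease_id, rho, float(p), n)


def corrected_cutoff(alpha: float = 0.05, n_tests: int = 171, round_1sf: bool = False) -> float:
    """Bonferroni cutoff alpha / n_tests, optionally rounded to one
    significant digit for reporting."""
    if n_tests < 1:
        raise InvalidParameterError("n_tests must be >= 1")
    cut = alpha / n_tests
    if round_1sf and cut > 0:
        exp = int(np.floor(np.log10(cut)))
        cut = round(cut, -exp)
    return cut


def count_validated(results: Sequence[ValidationResult], cutoff: float) -> int:
    """Diseases with p below the cutoff and positive correlation."""
    return sum(1 for r in results if (not r.degenerate) and r.p_value < cutoff and r.rho > 0)


@dataclass
class RecallResult:
    hits: int
    known: int
    recall: float | None  # None when no known associations


def recall_at_cutoff(
    naas_vec: Mapping[str, float],
    known_flags: Mapping[str, bool],
    naas_cutoff: float = 0.8,
) -> RecallResult:
    """Recall of literature-known cytokines at a strict NAAS cutoff.

    ``known_flags`` marks cytokines whose literature frequency reaches the
    chosen frequency cutoff; a hit is a known cytokine with NAAS strictly
    above ``naas_cutoff``.
    """
    known = [c for c, f in known_flags.items() if f]
    if not known:
        return RecallResult(0, 0, None)
    hits = sum(1 for c in known if naas_vec.get(c, 0.0) > naas_cutoff)
    return RecallResult(hits, len(known), hits / len(known))


def validate_profiles(
    profiles: Sequence[CytokineProfile],
    literature: pd.DataFrame,
    mode: Literal["exact", "permutation", "asymptotic"] = "asymptotic",
    n_perm: int = 100_000,
    seed: int | None = None,
    alpha: float = 0.05,
    min_shared: int = 3,
) -> tuple[list[ValidationResult], float]:
    """Per-disease Spearman validation against a long-format frequency table.

    Returns the per-disease results (diseases sharing fewer than
    ``min_shared`` sampled cytokines are skipped) and the Bonferroni cutoff
    for the number of tests actually performed.
    """
    by_disease = {d: g.set_index("cytokine")["frequency"] for d, g in literature.groupby("disease_id")}
    results = []
    for i, prof in enumerate(profiles):
        freqs = by_disease.get(prof.disease_id)
        if freqs is None:
            continue
        shared = [c for c in prof.naas.index if c in freqs.index]
        if len(shared) < min_shared:
            continue
        sub_seed = None if seed is None else (seed + i) % (2**31)
        results.append(
            spearman_validate(
                prof.naas.loc[shared].to_numpy(),
                freqs.loc[shared].to_numpy(),
                mode=mode,
                n_perm=n_perm,
                seed=sub_seed,
                disease_id=prof.disease_id,
            )
        )
    cutoff = corrected_cutoff(alpha, max(1, len(results)))
    return results, cutoff
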