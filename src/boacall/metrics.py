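"""Scoring of breed-origin calls against truth, FST, and PCA.

Percentages share one denominator -- every haplotype x locus cell of the
stratum -- so %correct + %incorrect + %unassigned is exactly 100.
Assignment *yield* is the assigned fraction, and *accuracy* is correct
calls over all assigned calls (undefined, reported as NaN, when nothing
was assigned).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .haplo import EXOTIC, LOCAL, MISSING


def score(
    calls: np.ndarray,
    truth: np.ndarray,
    strata: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Score calls against the true origin matrix.

    ``calls`` and ``truth`` are aligned ``(n_haplotypes, n_loci)``
    matrices; ``truth`` contains only LOCAL/EXOTIC.  ``strata`` optionally
    maps label names to per-haplotype-row label arrays; scoring is then
    grouped over distinct label combinations.  Returns one row per
    stratum with counts, percentages, yield and accuracy.
    """
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError(f"calls {calls.shape} and truth {truth.shape} misaligned")
    if np.any(truth == MISSING):
        raise ValueError("truth matrix cannot contain missing codes")

    if strata:
        labels = pd.DataFrame(strata)
        if len(labels) != calls.shape[0]:
            raise ValueError("stratum label arrays must have one entry per haplotype row")
        groups = labels.groupby(list(strata), sort=True, observed=True).indices
        rows = []
        for key, rows_idx in groups.items():
            key = key if isinstance(key, tuple) else (key,)
            rec = _score_block(calls[rows_idx], truth[rows_idx])
            rows.append(dict(zip(strata, key)) | rec)
        return pd.DataFrame(rows)
    return pd.DataFrame([_score_block(calls, truth)])


def _score_block(calls: np.ndarray, truth: np.ndarray) -> dict:
    total = calls.size
    n_correct = int(np.count_nonzero(calls == truth))
    n_unassigned = int(np.count_nonzero(calls == MISSING))
    n_incorrect = total - n_correct - n_unassigned
    n_local = int(np.count_nonzero(calls == LOCAL))
    n_exotic = int(np.count_nonzero(calls == EXOTIC))
    pct_correct = 100.0 * n_correct / total
    pct_incorrect = 100.0 * n_incorrect / total
    # computed as the complement so the three percentages sum to 100 exactly
    pct_unassigned = 100.0 - pct_correct - pct_incorrect
    assigned = n_correct + n_incorrect
    return {
        "n_cells": total,
        "n_correct": n_correct,
        "n_incorrect": n_incorrect,
        "n_unassigned": n_unassigned,
        "n_local_calls": n_local,
        "n_exotic_calls": n_exotic,
        "pct_correct": pct_correct,
        "pct_incorrect": pct_incorrect,
        "pct_unassigned": pct_unassigned,
        "yield": assigned / total,
        "accuracy": n_correct / assigned if assigned else np.nan,
    }


def fst(
    haplotypes_a: np.ndarray, haplotypes_b: np.ndarray, estimator: str = "hudson"
) -> float:
    """Multi-locus global FST between two haplotype panels.

    ``hudson`` (default) is the ratio-of-averages Hudson estimator on
    allele frequencies; ``weir-cockerham`` is the ANOVA estimator applied
    to allele indicators.  Loci monomorphic in the pooled sample are
    excluded; an entirely monomorphic input raises.
    """
    a = np.asarray(haplotypes_a, dtype=float)
    b = np.asarray(haplotypes_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("panels must share the locus set")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two haplotypes per panel")
    n1, n2 = a.shape[0], b.shape[0]
    p1, p2 = a.mean(axis=0), b.mean(axis=0)

    if estimator == "hudson":
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    elif estimator == "weir-cockerham":
        n = n1 + n2
        nc = (n - (n1**2 + n2**2) / n)  # r - 1 = 1
        pbar = (n1 * p1 + n2 * p2) / n
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (r - 1)
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - 2)
        num = msp - msg
        den = msp + (nc - 1) * msg
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    keep = den > 0
    if not np.any(keep):
        raise ValueError("all loci are monomorphic; FST is undefined")
    return float(num[keep].sum() / den[keep].sum())


def pca(dosage: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Principal-component coordinates of a genotype dosage matrix.

    Columns (loci) are mean-centered and the matrix decomposed by SVD;
    returns the top ``n_components`` coordinates per individual.
    """
    x = np.asarray(dosage, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2-D dosage matrix with at least 3 individuals")
    centered = x - x.mean(axis=0)
    if not np.any(centered):
        raise ValueError("dosage matrix has zero variance at every locus")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    return u[:, :k] * s[:k]
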