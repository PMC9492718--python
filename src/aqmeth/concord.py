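"""Concordance between paired samples and the low-input titration curve.

Agreement between two methylation profiles is quantified as r^2, the
square of the Pearson correlation over pairwise-complete probes (the
smooth-scatter convention for array data, not a regression R^2 through
the origin). Declared tumor-AH pairs are validated by checking that each
AH sample's best-correlated tumor is its declared pair, and the
input-mass titration is emulated by resampling a clean profile at a grid
of noise precisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import BetaMatrix
from .simulate import sample_around

__all__ = ["pairwise_r2", "best_match_report", "titration_curve",
           "ConcordanceResult"]


@dataclass
class ConcordanceResult:
    """All-pairs concordance between two sample groups.

    ``r2``/``r``/``n`` are DataFrames indexed by group-A samples with
    group-B samples as columns: squared Pearson correlation, its sign-
    carrying value, and the pairwise-complete probe count. A pair with a
    constant vector has undefined correlation and is NaN (flagged in
    ``undefined``), never 0.
    """

    r2: pd.DataFrame
    r: pd.DataFrame
    n: pd.DataFrame
    undefined: pd.DataFrame


def pairwise_r2(betas: BetaMatrix, samples_a: Sequence[str],
                samples_b: Sequence[str],
                min_probes: int = 100) -> ConcordanceResult:
    """r^2 between every sample of group A and every sample of group B."""
    samples_a, samples_b = list(samples_a), list(samples_b)
    A = betas.beta[samples_a].to_numpy()
    B = betas.beta[samples_b].to_numpy()
    r = np.full((len(samples_a), len(samples_b)), np.nan)
    n = np.zeros_like(r, dtype=int)
    undef = np.zeros_like(r, dtype=bool)
    for i in range(len(samples_a)):
        for j in range(len(samples_b)):
            ok = ~(np.isnan(A[:, i]) | np.isnan(B[:, j]))
            m = int(ok.sum())
            n[i, j] = m
            if m < min_probes:
                raise ValueError(
                    f"pair ({samples_a[i]}, {samples_b[j]}) shares only "
                    f"{m} unmasked probes (minimum {min_probes})")
            x, y = A[ok, i], B[ok, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                undef[i, j] = True
                continue
            r[i, j] = np.corrcoef(x, y)[0, 1]
    idx, cols = pd.Index(samples_a), pd.Index(samples_b)
    return ConcordanceResult(
        r2=pd.DataFrame(r ** 2, index=idx, columns=cols),
        r=pd.DataFrame(r, index=idx, columns=cols),
        n=pd.DataFrame(n, index=idx, columns=cols),
        undefined=pd.DataFrame(undef, index=idx, columns=cols))


def best_match_report(result: ConcordanceResult,
                      pairing: Mapping[str, str]) -> pd.DataFrame:
    """Check that each group-A sample's best r^2 match is its declared pair.

    ``pairing`` maps each group-A sample (e.g. an AH id) to its declared
    group-B sample (its tumor). The report has one row per group-A sample
    with the best match, the declared pair, a tie flag (a tie at the
    maximum counts as a failure) and the boolean verdict; the summary
    fraction is stored in ``report.attrs["fraction_best"]``.
    """
    missing = [s for s in result.r2.index if s not in pairing]
    if missing:
        raise ValueError(f"pairing does not cover samples: {missing}")
    rows = []
    for s in result.r2.index:
        row = result.r2.loc[s]
        best_val = row.max()
        best = row.idxmax()
        tie = (row == best_val).sum() > 1
        ok = (not tie) and best == pairing[s]
        rows.append({"sample": s, "best_match": best,
                     "declared_pair": pairing[s], "tie": tie,
                     "r2_best": best_val, "r2_declared": row[pairing[s]],
                     "is_best": ok})
    report = pd.DataFrame(rows).set_index("sample")
    report.attrs["fraction_best"] = float(report["is_best"].mean())
    return report


def titration_curve(truth: Sequence[float], kappa_levels: Sequence[float],
                    replicates: int = 3, seed: int = 0) -> pd.DataFrame:
    """Mean r^2 to a clean profile across a grid of noise precisions.

    Emulates the input-DNA titration: each level resamples the clean
    profile at precision kappa (larger kappa = more input mass) and
    records the mean squared Pearson correlation back to the truth over
    ``replicates`` draws. Output is sorted by kappa.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(k <= 0 for k in kappa_levels):
        raise ValueError("kappa levels must be positive")
    truth = np.asarray(truth, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for kappa in sorted(kappa_levels):
        r2s = []
        for _ in range(replicates):
            noisy = sample_around(truth, kappa, rng)
            r = np.corrcoef(truth, noisy)[0, 1]
            r2s.append(r ** 2)
        rows.append({"kappa": kappa, "mean_r2": float(np.mean(r2s)),
                     "replicates": replicates})
    return pd.DataFrame(rows).set_index("kappa")
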