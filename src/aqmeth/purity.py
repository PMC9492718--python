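"""Leukocyte-unmethylation tumor-purity (LUMP) scoring and sample gating.

The LUMP score of a sample is the mean beta over a designated set of
probes that are unmethylated in leukocytes but methylated in the tumor
compartment, divided by a scale constant (0.85 by convention) and capped
at 1. Samples scoring below a purity threshold (default 0.5, i.e. <50%
tumor fraction) are removed from group contrasts.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_is_fitted

from .containers import BetaMatrix


def lump_score(betas: BetaMatrix, lump_probes: Sequence[str],
               scale: float = 0.85, threshold: float = 0.5) -> pd.DataFrame:
    """Per-sample LUMP purity scores.

    Returns a DataFrame indexed by sample id with columns ``lump_score``
    (min(1, mean unmasked beta over the LUMP probes / scale)),
    ``n_probes`` (unmasked LUMP probes used) and ``retained``
    (score >= ``threshold``). A sample with no unmasked LUMP probe gets a
    NaN score, ``retained`` False, and a warning; the pipeline continues.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    lump_probes = list(lump_probes)
    missing = [p for p in lump_probes if p not in betas.probe_ids]
    if missing:
        raise ValueError(f"LUMP probes absent from the matrix: {missing[:5]}")
    sub = betas.beta.loc[lump_probes]
    n = sub.notna().sum(axis=0)
    score = np.minimum(1.0, sub.mean(axis=0, skipna=True) / scale)
    score[n == 0] = np.nan
    if (n == 0).any():
        bad = list(betas.sample_ids[(n == 0).to_numpy()])
        warnings.warn(f"no unmasked LUMP probes for samples: {bad}")
    out = pd.DataFrame({"lump_score": score, "n_probes": n})
    out["retained"] = out["lump_score"] >= threshold
    out.index.name = "sample_id"
    return out


def filter_by_purity(results: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Sample ids surviving the purity gate.

    Follows the strict-less rule: samples with score < ``threshold`` are
    removed; a score exactly at the threshold is retained. Samples with an
    undefined (NaN) score are removed with a warning.
    """
    score = results["lump_score"]
    if score.isna().any():
        warnings.warn("samples with undefined LUMP score removed: "
                      f"{list(results.index[score.isna()])}")
    keep = score >= threshold
    return list(results.index[keep.fillna(False)])


class LUMPPurity(BaseEstimator, OutlierMixin):
    """Purity gate with the scikit-learn outlier-detector interface.

    ``X`` is samples x probes. :meth:`score_samples` returns the LUMP
    score; :meth:`predict` returns +1 for samples at or above the purity
    threshold and -1 for low-purity samples.

    Parameters
    ----------
    lump_probes : sequence of str
        Designated leukocyte-unmethylated probe ids (columns of X).
    scale : float, default 0.85
        Scale constant of the assay.
    threshold : float, default 0.5
        Minimum retained purity.
    """

    def __init__(self, lump_probes: Sequence[str] | None = None,
                 scale: float = 0.85, threshold: float = 0.5):
        self.lump_probes = lump_probes
        self.scale = scale
        self.threshold = threshold

    def _scores(self, X: pd.DataFrame) -> pd.Series:
        if self.lump_probes is None:
            raise ValueError("lump_probes must be provided")
        betas = BetaMatrix(X.T, validate=False)
        res = lump_score(betas, self.lump_probes, scale=self.scale,
                         threshold=self.threshold)
        return res["lump_score"]

    def fit(self, X: pd.DataFrame, y=None) -> "LUMPPurity":
        self.scores_ = self._scores(X)
        self.retained_ = (self.scores_ >= self.threshold).to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "scores_")
        return self._scores(X).to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.score_samples(X)
        return np.where(scores >= self.threshold, 1, -1)
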