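"""Two-group differential methylation.

Per-probe Welch's t-test with the Welch-Satterthwaite degrees of freedom,
group-mean difference (delta-beta), strict-threshold probe selection,
hyper/hypo direction fractions, and genic-region classification and
enrichment. Delta-beta is oriented contrast arm minus reference arm, so
"hyper" means elevated in arm A.

No multiple-testing correction is applied by default (selection combines a
raw p cutoff with an effect-size cutoff); Benjamini-Hochberg adjustment is
available via ``adjust="bh"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, ProbeAnnotation, classify_region  # noqa: F401

__all__ = [
    "welch_t", "dm_table", "select_dm", "direction_fractions",
    "classify_region", "region_enrichment", "DMTable", "WelchDMSelector",
]


def _welch_arrays(xa: np.ndarray, xb: np.ndarray):
    """Vectorized Welch statistics over rows; NaN-aware.

    Returns (mean_a, mean_b, t, df, p, degenerate) where ``degenerate``
    flags rows with zero variance in both arms but unequal means (p is 0
    there by convention).
    """
    na = np.sum(~np.isnan(xa), axis=1)
    nb = np.sum(~np.isnan(xb), axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(xa, axis=1)
        mb = np.nanmean(xb, axis=1)
        va = np.nanvar(xa, axis=1, ddof=1)
        vb = np.nanvar(xb, axis=1, ddof=1)
    sa = va / na
    sb = vb / nb
    se2 = sa + sb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
    zerovar = se2 == 0
    degenerate = zerovar & (diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(zerovar,
                     np.where(degenerate, np.sign(diff) * np.inf, 0.0), t)
    df = np.where(zerovar, na + nb - 2.0, df)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zerovar, np.where(degenerate, 0.0, 1.0), p)
    return ma, mb, t, df, p, degenerate


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test (two-sided), NaN values dropped.

    Returns ``(t, df, p)`` with t = (mean x - mean y) / sqrt(s2x/nx + s2y/ny)
    and df from the Welch-Satterthwaite approximation. Both groups constant
    with equal means gives (0, nx+ny-2, 1); constant with unequal means
    gives a signed infinite t and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    _, _, t, df, p, _ = _welch_arrays(x[None, :], y[None, :])
    return float(t[0]), float(df[0]), float(p[0])


@dataclass
class DMTable:
    """Differential-methylation result for one two-group contrast.

    ``records`` is indexed by probe id with columns mean_a, mean_b,
    delta_beta, t_stat, df, p_value (plus q_value under BH adjustment),
    direction (hyper/hypo/none) and region_class. ``skipped`` lists probes
    excluded from testing with a reason.
    """

    label: str
    records: pd.DataFrame
    delta_thresh: float
    p_thresh: float
    skipped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["reason"]))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# contrast={self.label}\n")
            fh.write(f"# delta_thresh={self.delta_thresh}\n")
            fh.write(f"# p_thresh={self.p_thresh}\n")
            self.records.to_csv(fh, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path) -> "DMTable":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            records = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(label=meta.get("contrast", ""),
                   records=records,
                   delta_thresh=float(meta.get("delta_thresh", 0.3)),
                   p_thresh=float(meta.get("p_thresh", 0.05)))


def _directions(delta: pd.Series, p: pd.Series,
                delta_thresh: float, p_thresh: float) -> pd.Series:
    direction = pd.Series("none", index=delta.index)
    sig = p < p_thresh
    direction[(delta > delta_thresh) & sig] = "hyper"
    direction[(delta < -delta_thresh) & sig] = "hypo"
    return direction


def dm_table(betas: BetaMatrix, arm_a: Sequence[str], arm_b: Sequence[str],
             probes: Sequence[str] | None = None,
             annotation: ProbeAnnotation | None = None,
             delta_thresh: float = 0.3, p_thresh: float = 0.05,
             min_per_arm: int = 3, adjust: str = "none",
             label: str = "contrast") -> DMTable:
    """Per-probe Welch differential methylation between two sample arms.

    Delta-beta is oriented ``arm_a - arm_b``. Probes with fewer than
    ``min_per_arm`` unmasked values in either arm are skipped with a
    reason rather than tested.
    """
    arm_a, arm_b = list(arm_a), list(arm_b)
    if set(arm_a) & set(arm_b):
        raise ValueError("contrast arms overlap")
    if len(arm_a) < 2 or len(arm_b) < 2:
        raise ValueError("each arm needs at least 2 samples")
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    sub = betas if probes is None else betas.select(probes=probes)
    xa = sub.values_for(arm_a)
    xb = sub.values_for(arm_b)
    na = np.sum(~np.isnan(xa), axis=1)
    nb = np.sum(~np.isnan(xb), axis=1)
    ok = (na >= min_per_arm) & (nb >= min_per_arm)

    reason = np.where(na < min_per_arm,
                      f"fewer than {min_per_arm} unmasked values in arm A",
                      f"fewer than {min_per_arm} unmasked values in arm B")
    skipped = pd.DataFrame({"reason": reason[~ok]},
                           index=sub.probe_ids[~ok])
    skipped.index.name = "probe_id"

    ma, mb, t, df, p, degen = _welch_arrays(xa[ok], xb[ok])
    records = pd.DataFrame({
        "mean_a": ma, "mean_b": mb, "delta_beta": ma - mb,
        "t_stat": t, "df": df, "p_value": p, "degenerate": degen,
    }, index=sub.probe_ids[ok])
    records.index.name = "probe_id"
    p_for_calls = records["p_value"]
    if adjust == "bh":
        records["q_value"] = multipletests(records["p_value"].to_numpy(),
                                           method="fdr_bh")[1]
        p_for_calls = records["q_value"]
    records["direction"] = _directions(records["delta_beta"], p_for_calls,
                                       delta_thresh, p_thresh)
    if annotation is not None:
        records["region_class"] = annotation.region_class.reindex(records.index)
    else:
        records["region_class"] = "other"
    return DMTable(label=label, records=records, skipped=skipped,
                   delta_thresh=delta_thresh, p_thresh=p_thresh)


def select_dm(table: DMTable, delta_thresh: float | None = None,
              p_thresh: float | None = None) -> tuple[set[str], set[str]]:
    """Hyper/hypo probe sets at strict thresholds (> delta, < p).

    Thresholds default to those recorded in the table. The two sets are
    disjoint for any positive delta threshold.
    """
    d = table.delta_thresh if delta_thresh is None else delta_thresh
    p = table.p_thresh if p_thresh is None else p_thresh
    rec = table.records
    pcol = rec["q_value"] if "q_value" in rec.columns else rec["p_value"]
    sig = pcol < p
    hyper = set(rec.index[(rec["delta_beta"] > d) & sig])
    hypo = set(rec.index[(rec["delta_beta"] < -d) & sig])
    return hyper, hypo


def direction_fractions(hyper: set[str], hypo: set[str]) -> tuple[float, float]:
    """Fractions of hyper- and hypomethylated probes over their union."""
    total = len(hyper) + len(hypo)
    if total == 0:
        raise ValueError("no selected probes")
    return len(hyper) / total, len(hypo) / total


def region_enrichment(hyper: set[str], hypo: set[str], universe: set[str],
                      annotation: ProbeAnnotation) -> pd.DataFrame:
    """Genomic-location distribution of hyper, hypo and all probes.

    Rows hyper/hypo/total; columns promoter/body/other (exclusive classes,
    fractions summing to 1 within a row) plus ``enhancer``, the fraction of
    probes overlapping an enhancer (a non-exclusive flag).
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    if not (hyper <= universe and hypo <= universe):
        raise ValueError("hyper/hypo sets must be subsets of the universe")
    cls = annotation.region_class
    enh = annotation.df["enhancer"].astype(bool)
    rows = {}
    for name, probe_set in (("hyper", hyper), ("hypo", hypo),
                            ("total", universe)):
        ids = list(probe_set)
        n = len(ids)
        if n == 0:
            rows[name] = {c: np.nan for c in
                          ("promoter", "body", "other", "enhancer")}
            continue
        sub = cls.loc[ids]
        counts = sub.value_counts()
        rows[name] = {c: counts.get(c, 0) / n for c in ("promoter", "body", "other")}
        rows[name]["enhancer"] = enh.loc[ids].mean()
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["promoter", "body", "other", "enhancer"])


class WelchDMSelector(BaseEstimator, TransformerMixin):
    """Differential-methylation probe selector (scikit-learn interface).

    ``X`` is samples x probes, ``y`` a two-level group label per sample.
    ``fit`` runs the per-probe Welch test; ``transform`` keeps the probes
    passing the strict |delta-beta| and p thresholds in either direction.

    Parameters
    ----------
    delta_thresh, p_thresh : float
        Strict selection thresholds (> delta, < p).
    positive_class : optional
        Label treated as the contrast arm (arm A); defaults to the
        lexicographically larger of the two labels.
    min_per_group, adjust : see :func:`dm_table`.

    Attributes
    ----------
    dm_ : DMTable
    hyper_ids_, hypo_ids_ : list of probe ids per direction
    support_ : boolean mask over the input probes
    """

    def __init__(self, delta_thresh: float = 0.3, p_thresh: float = 0.05,
                 positive_class=None, min_per_group: int = 3,
                 adjust: str = "none"):
        self.delta_thresh = delta_thresh
        self.p_thresh = p_thresh
        self.positive_class = positive_class
        self.min_per_group = min_per_group
        self.adjust = adjust

    def fit(self, X, y) -> "WelchDMSelector":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("y must contain exactly two classes")
        pos = self.positive_class if self.positive_class is not None else classes[-1]
        if pos not in classes:
            raise ValueError(f"positive_class {pos!r} not present in y")
        neg = classes[classes != pos][0]
        betas = BetaMatrix(X.T, validate=False)
        self.dm_ = dm_table(
            betas,
            arm_a=list(X.index[y == pos]), arm_b=list(X.index[y == neg]),
            delta_thresh=self.delta_thresh, p_thresh=self.p_thresh,
            min_per_arm=self.min_per_group, adjust=self.adjust,
            label=f"{pos}_vs_{neg}")
        hyper, hypo = select_dm(self.dm_)
        self.hyper_ids_ = sorted(hyper)
        self.hypo_ids_ = sorted(hypo)
        selected = hyper | hypo
        self.feature_names_in_ = np.asarray(X.columns)
        self.support_ = np.array([c in selected for c in X.columns])
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        return X.loc[:, self.support_]
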