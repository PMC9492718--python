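"""From raw signal matrices to the filtered analysis-ready probe universe.

Covers the standard array-preprocessing steps downstream of normalization:
beta computation from methylated/unmethylated intensities, detection-p
masking, exclusion-flag probe filtering (polymorphism-linked, sex-chromosome
and aging-related probes), and cross-platform probe intersection.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (BetaMatrix, EXCLUSION_FLAGS, IntensityMatrix,
                         PLATFORMS, ProbeAnnotation)


def beta_from_intensities(intensities: IntensityMatrix,
                          offset: float = 0.0) -> BetaMatrix:
    """Compute beta = M / (M + U + offset) per cell.

    Cells where the denominator is zero are masked. ``offset`` defaults to
    0 (the plain ratio); a positive value can be supplied for numerical
    stability with near-zero total signal.
    """
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    M = intensities.M.to_numpy(dtype=float)
    U = intensities.U.to_numpy(dtype=float)
    denom = M + U + offset
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(denom > 0, M / denom, np.nan)
    out = pd.DataFrame(beta, index=intensities.M.index,
                       columns=intensities.M.columns)
    return BetaMatrix(out)


def mask_by_detection(betas: BetaMatrix, detp: pd.DataFrame,
                      alpha: float = 0.05) -> BetaMatrix:
    """Mask cells whose detection p-value exceeds ``alpha``.

    A detection p above the cutoff means the fluorescence was not
    significantly above background, so the measurement is discarded.
    """
    if not (detp.index.equals(betas.probe_ids)
            and detp.columns.equals(betas.sample_ids)):
        raise ValueError("detection-p matrix is not aligned with the beta matrix")
    masked = betas.beta.where(~(detp > alpha))
    return BetaMatrix(masked, validate=False)


def filter_probes(annotation: ProbeAnnotation,
                  drop_flags: Sequence[str] = EXCLUSION_FLAGS) -> pd.Index:
    """Return probe ids carrying none of the exclusion flags, order preserved.

    Default drops the three standard classes: polymorphism-linked (``snp``),
    X/Y-chromosome (``sexchrom``) and aging-related (``age``) probes. The
    aging list is whatever the annotation's ``age`` column flags; no
    built-in clock list is assumed.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    unknown = set(drop_flags) - set(EXCLUSION_FLAGS)
    if unknown:
        raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
    keep = pd.Series(True, index=annotation.probe_ids)
    for flag in drop_flags:
        keep &= ~annotation.df[flag].astype(bool)
    return annotation.probe_ids[keep]


def intersect_platforms(annotation: ProbeAnnotation,
                        platforms: Sequence[str]) -> pd.Index:
    """Probes present on *all* requested platforms (e.g. EPIC and HM450)."""
    if len(platforms) == 0:
        raise ValueError("at least one platform must be requested")
    unknown = set(platforms) - set(PLATFORMS)
    if unknown:
        raise ValueError(f"unknown platforms: {sorted(unknown)}")
    wanted = frozenset(platforms)
    keep = annotation.platform_sets.map(lambda s: wanted <= s)
    return annotation.probe_ids[keep.to_numpy()]
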