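"""Core data containers shared across the pipeline.

The universal currency is the :class:`BetaMatrix`: a probes x samples matrix
of methylation fractions (beta values) in [0, 1], with missing measurements
stored as NaN. Probe metadata travels in a :class:`ProbeAnnotation`, sample
metadata in a plain sample-sheet DataFrame (see :mod:`aqmeth.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Transcript-region tokens counted as promoter: transcription start site
#: windows, 5' UTR and first exon.
PROMOTER_TOKENS = frozenset({"TSS200", "TSS1500", "5'UTR", "1stExon"})
#: Tokens counted as gene body (body proper plus 3' UTR).
BODY_TOKENS = frozenset({"Body", "3'UTR"})
#: Full token vocabulary of the manifest-style annotation.
KNOWN_TOKENS = PROMOTER_TOKENS | BODY_TOKENS | frozenset({"ExonBnd"})

REGION_CLASSES = ("promoter", "body", "other")
EXCLUSION_FLAGS = ("snp", "sexchrom", "age")
PLATFORMS = ("EPIC", "HM450")
SEX_CHROMS = frozenset({"chrX", "chrY"})


def classify_region(tokens: Iterable[str]) -> str:
    """Collapse transcript-region tokens into one region class.

    Promoter takes precedence over body, body over other, so a probe
    annotated to several transcripts gets the most regulatory reading.
    Unknown tokens are ignored with a warning.

    Parameters
    ----------
    tokens : iterable of str
        Manifest tokens such as ``TSS200`` or ``Body``.

    Returns
    -------
    str
        One of ``promoter``, ``body``, ``other``.
    """
    toks = {t for t in tokens if t}
    unknown = toks - KNOWN_TOKENS
    if unknown:
        warnings.warn(f"ignoring unknown region tokens: {sorted(unknown)}",
                      stacklevel=2)
        toks -= unknown
    if toks & PROMOTER_TOKENS:
        return "promoter"
    if toks & BODY_TOKENS:
        return "body"
    return "other"


def _split_cell(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return str(cell).split(";")


class BetaMatrix:
    """Probes x samples matrix of beta values with a missingness mask.

    Parameters
    ----------
    beta : pandas.DataFrame
        Rows indexed by probe id, columns by sample id. NaN marks a masked
        (missing) measurement; every unmasked value must lie in [0, 1].
    validate : bool
        Skip validation for internal construction when False.
    """

    def __init__(self, beta: pd.DataFrame, validate: bool = True):
        beta = beta.astype(float)
        if validate:
            if not beta.index.is_unique:
                raise ValueError("probe ids must be unique")
            if not beta.columns.is_unique:
                raise ValueError("sample ids must be unique")
            vals = beta.to_numpy()
            with np.errstate(invalid="ignore"):
                bad = np.nansum((vals < 0) | (vals > 1))
            if bad:
                raise ValueError(f"{int(bad)} beta values outside [0, 1]")
        self.beta = beta

    # -- basic views -----------------------------------------------------
    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame: True where the measurement is missing."""
        return self.beta.isna()

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def select(self, probes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "BetaMatrix":
        """Subset by probe and/or sample ids (order preserved as given)."""
        beta = self.beta
        if probes is not None:
            beta = beta.loc[list(probes)]
        if samples is not None:
            beta = beta[list(samples)]
        return BetaMatrix(beta, validate=False)

    def values_for(self, samples: Sequence[str]) -> np.ndarray:
        return self.beta[list(samples)].to_numpy()

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV with probe ids as the row key, 6-decimal values,
        masked cells as ``NA``."""
        self.beta.to_csv(path, sep="\t", float_format="%.6f", na_rep="NA",
                         index_label="probe_id")

    @classmethod
    def from_tsv(cls, path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df)

    def __repr__(self) -> str:  # pragma: no cover
        p, s = self.shape
        return f"BetaMatrix({p} probes x {s} samples)"


@dataclass
class IntensityMatrix:
    """Paired methylated (M) / unmethylated (U) signal intensities."""

    M: pd.DataFrame
    U: pd.DataFrame

    def __post_init__(self):
        if not (self.M.index.equals(self.U.index)
                and self.M.columns.equals(self.U.columns)):
            raise ValueError("M and U must share identical probe and sample indexing")
        for name, df in (("M", self.M), ("U", self.U)):
            if (df.to_numpy() < 0).any():
                raise ValueError(f"negative intensities in {name}")


class ProbeAnnotation:
    """Manifest-style probe annotation table.

    Wraps a DataFrame indexed by probe id with columns:

    - ``chrom`` (``chr1`` ... ``chrX``), ``pos`` (1-based int)
    - ``genes``: semicolon-delimited gene symbols
    - ``regions``: semicolon-delimited transcript-region tokens
    - ``enhancer``: bool overlap flag
    - ``snp`` / ``sexchrom`` / ``age``: exclusion flags (bool)
    - ``platforms``: semicolon-delimited subset of {EPIC, HM450}

    The derived ``region_class`` column collapses tokens with promoter >
    body > other precedence (see :func:`classify_region`).
    """

    REQUIRED = ("chrom", "pos", "genes", "regions", "enhancer",
                "snp", "sexchrom", "age", "platforms")

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            missing = [c for c in self.REQUIRED if c not in df.columns]
            if missing:
                raise ValueError(f"annotation missing columns: {missing}")
            if not df.index.is_unique:
                raise ValueError("probe ids must be unique")
            is_sex = df["chrom"].isin(SEX_CHROMS)
            if not (df["sexchrom"].astype(bool) == is_sex).all():
                raise ValueError(
                    "sexchrom flag must be set exactly for chrX/chrY probes")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def token_sets(self) -> pd.Series:
        return self.df["regions"].map(_split_cell).map(frozenset)

    @property
    def region_class(self) -> pd.Series:
        """Region class per probe (promoter/body/other), promoter-first."""
        toks = self.token_sets
        cls = pd.Series("other", index=self.df.index, name="region_class")
        cls[toks.map(lambda s: bool(s & BODY_TOKENS))] = "body"
        cls[toks.map(lambda s: bool(s & PROMOTER_TOKENS))] = "promoter"
        return cls

    @property
    def gene_lists(self) -> pd.Series:
        return self.df["genes"].map(_split_cell)

    @property
    def platform_sets(self) -> pd.Series:
        return self.df["platforms"].map(_split_cell).map(frozenset)

    def subset(self, probes: Sequence[str]) -> "ProbeAnnotation":
        return ProbeAnnotation(self.df.loc[list(probes)], validate=False)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="probe_id")

    @classmethod
    def from_csv(cls, path) -> "ProbeAnnotation":
        df = pd.read_csv(path, index_col=0,
                         dtype={"genes": str, "regions": str, "platforms": str},
                         keep_default_na=False, na_values=[])
        for col in ("enhancer", "snp", "sexchrom", "age"):
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
        df["pos"] = df["pos"].astype(int)
        return cls(df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ProbeAnnotation({len(self)} probes)"
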