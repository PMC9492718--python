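"""Readers and writers for the plain-text formats the pipeline exchanges.

Beta/intensity/detection-p matrices are TSV with probe ids as the row key
and sample ids as columns; annotations and sample sheets are CSV.
"""

from __future__ import annotations

import json

import pandas as pd

from .containers import BetaMatrix, IntensityMatrix, ProbeAnnotation

SAMPLE_ROLES = ("retina", "tumor", "AH", "blood", "leukocyte")
OUTCOMES = ("SV", "PE", "SE")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a numeric probes x samples TSV (detection-p, M or U signal)."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_betas(path) -> BetaMatrix:
    return BetaMatrix.from_tsv(path)


def write_betas(betas: BetaMatrix, path) -> None:
    betas.to_tsv(path)


def read_intensities(m_path, u_path) -> IntensityMatrix:
    return IntensityMatrix(M=read_matrix_tsv(m_path), U=read_matrix_tsv(u_path))


def read_annotation(path) -> ProbeAnnotation:
    return ProbeAnnotation.from_csv(path)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet CSV indexed by sample id.

    Expected columns: ``role`` (retina/tumor/AH/blood/leukocyte) and,
    where applicable, ``pair_id``, ``outcome`` (SV/PE/SE), ``subtype``,
    ``cohort``. Missing optional columns are added empty.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    if "role" not in df.columns:
        raise ValueError("sample sheet must contain a 'role' column")
    bad = set(df["role"]) - set(SAMPLE_ROLES)
    if bad:
        raise ValueError(f"unknown sample roles: {sorted(bad)}")
    for col in ("pair_id", "outcome", "subtype", "cohort"):
        if col not in df.columns:
            df[col] = pd.NA
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample_id")


def read_probe_list(path) -> list[str]:
    """One probe id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
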