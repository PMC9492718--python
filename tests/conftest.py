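import numpy as np
import pandas as pd
import pytest

import aqmeth as aq


def toy_annotation(rows: dict) -> aq.ProbeAnnotation:
    """Build a small annotation by hand.

    ``rows`` maps probe id -> dict of column overrides; unspecified columns
    get neutral defaults (autosomal, unflagged, both platforms).
    """
    records = {}
    for pid, over in rows.items():
        rec = {"chrom": "chr1", "pos": 1000, "genes": "", "regions": "",
               "enhancer": False, "snp": False, "sexchrom": False,
               "age": False, "platforms": "EPIC;HM450"}
        rec.update(over)
        if rec["chrom"] in ("chrX", "chrY"):
            rec["sexchrom"] = True
        records[pid] = rec
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "probe_id"
    return aq.ProbeAnnotation(df)


def make_betas(values, probes=None, samples=None) -> aq.BetaMatrix:
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:03d}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return aq.BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


@pytest.fixture(scope="session")
def annotation_small():
    return aq.make_annotation(4000, 1200, seed=7)


@pytest.fixture(scope="session")
def cohort_small(annotation_small):
    """Default-parameter cohort: 12 retina, 8+8 tumors, 4 paired AH."""
    design = {"retina": 12, "tumor_subtype1": 8, "tumor_subtype2": 8,
              "AH_paired": 4, "leukocyte": 2}
    return aq.make_cohort(annotation_small, design, seed=7)


@pytest.fixture(scope="session")
def dm_small(cohort_small, annotation_small):
    betas, sheet, _ = cohort_small
    tumors = list(sheet.index[sheet["role"] == "tumor"])
    retina = list(sheet.index[sheet["role"] == "retina"])
    return aq.dm_table(betas, tumors, retina, annotation=annotation_small,
                       label="tumor_vs_retina")
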