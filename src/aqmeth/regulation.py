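"""Integration of differential methylation with differential expression.

A gene is called "regulated by methylation" when a concordantly
differential probe and a reproducible expression change point the same
way: promoter hypomethylation or gene-body hypermethylation with
upregulation, promoter hypermethylation or gene-body hypomethylation with
downregulation. Expression calls must replicate in two independent
datasets (fold change beyond the threshold in both); the integration is
conjunctive, so either data type alone calls nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ProbeAnnotation
from .diffmeth import DMTable

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter_hypo_up", "body_hyper_up",
              "promoter_hyper_down", "body_hypo_down")

#: (region class, probe direction, expression direction) per category.
_CATEGORY_RULES = {
    "promoter_hypo_up": ("promoter", "hypo", "up"),
    "body_hyper_up": ("body", "hyper", "up"),
    "promoter_hyper_down": ("promoter", "hyper", "down"),
    "body_hypo_down": ("body", "hypo", "down"),
}


def de_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame,
               fold_thresh: float = 2.0) -> tuple[set[str], set[str]]:
    """Genes consistently up/down beyond a fold change in both datasets.

    Tables need columns ``gene`` and ``log2FC`` (one row per gene). The
    raw-scale fold threshold (default 2) is applied as a strict cutoff on
    the log2 scale: up means log2FC > log2(fold_thresh) in *both* tables,
    down means log2FC < -log2(fold_thresh) in both. Genes present in only
    one table are excluded (logged).
    """
    if fold_thresh <= 1:
        raise ValueError("fold_thresh must exceed 1")
    cut = np.log2(fold_thresh)
    fa = table_a.set_index("gene")["log2FC"]
    fb = table_b.set_index("gene")["log2FC"]
    only = set(fa.index) ^ set(fb.index)
    if only:
        logger.info("excluding %d genes present in one table only", len(only))
    shared = fa.index.intersection(fb.index)
    fa, fb = fa.loc[shared], fb.loc[shared]
    up = set(shared[(fa > cut) & (fb > cut)])
    down = set(shared[(fa < -cut) & (fb < -cut)])
    return up, down


@dataclass
class RegulatedGene:
    """One methylation-regulated gene call."""

    gene: str
    category: str            # primary category (largest |delta-beta| probe)
    categories: list[str]    # all matching categories
    probe_ids: list[str]     # supporting probes of the primary category
    max_abs_delta: float
    log2fc: float


def call_regulated_genes(dm: DMTable, annotation: ProbeAnnotation,
                         up: set[str], down: set[str],
                         delta_thresh: float = 0.3,
                         p_thresh: float | None = 0.05,
                         expr_tables: Sequence[pd.DataFrame] = (),
                         ) -> list[RegulatedGene]:
    """Call genes whose expression change matches a DM probe pattern.

    A gene enters a category when at least one of its probes passes the
    strict delta-beta cutoff (and p cutoff unless ``p_thresh`` is None,
    which reproduces a delta-only selection) in the category's region
    class and direction, and the gene sits in the matching expression set.
    A gene matching several categories is reported in all of them, with
    the primary category taken from its largest-|delta-beta| probe.

    ``log2fc`` in the output is the gene's mean log2 fold change across
    the given ``expr_tables`` (NaN when none are supplied).
    """
    rec = dm.records
    fc_of: dict[str, float] = {}
    if expr_tables:
        stacked = pd.concat([t.set_index("gene")["log2FC"] for t in expr_tables],
                            axis=1)
        fc_of = stacked.mean(axis=1).to_dict()
    region = annotation.region_class.reindex(rec.index)
    genes = annotation.gene_lists.reindex(rec.index)
    passing = rec["p_value"] < p_thresh if p_thresh is not None \
        else pd.Series(True, index=rec.index)

    # probe-level qualification per (region, direction)
    qual = {}
    for direction, sign in (("hyper", 1.0), ("hypo", -1.0)):
        ok = passing & (sign * rec["delta_beta"] > delta_thresh)
        for cls in ("promoter", "body"):
            qual[(cls, direction)] = ok & (region == cls)

    # gene -> category -> supporting probes
    support: dict[str, dict[str, list[str]]] = {}
    for cat, (cls, direction, expr_dir) in _CATEGORY_RULES.items():
        expr_set = up if expr_dir == "up" else down
        mask = qual[(cls, direction)]
        for probe in rec.index[mask]:
            for g in genes[probe]:
                if g in expr_set:
                    support.setdefault(g, {}).setdefault(cat, []).append(probe)

    calls = []
    for g in sorted(support):
        cats = support[g]
        best_cat, best_probe, best_delta = None, None, -1.0
        for cat, probe_list in cats.items():
            for probe in probe_list:
                d = abs(rec.loc[probe, "delta_beta"])
                if d > best_delta:
                    best_cat, best_probe, best_delta = cat, probe, d
        calls.append(RegulatedGene(
            gene=g, category=best_cat,
            categories=sorted(cats),
            probe_ids=sorted(cats[best_cat]),
            max_abs_delta=float(best_delta),
            log2fc=float(fc_of.get(g, float("nan")))))
    return calls


def regulated_table(calls: Sequence[RegulatedGene]) -> pd.DataFrame:
    """Flatten regulated-gene calls to a DataFrame (one row per gene)."""
    return pd.DataFrame([{
        "gene": c.gene, "category": c.category,
        "categories": ";".join(c.categories),
        "probes": ";".join(c.probe_ids),
        "max_abs_delta": c.max_abs_delta,
    } for c in calls]).set_index("gene") if calls else pd.DataFrame(
        columns=["category", "categories", "probes", "max_abs_delta"])
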