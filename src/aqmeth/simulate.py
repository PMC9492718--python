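"""Synthetic methylation cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable without any external
download:

- genome-wide bimodal beta baselines (modes near 0.1 and 0.9), as seen in
  array data from differentiated tissue;
- tumors carrying a planted retina-vs-tumor differential panel (signed
  delta-beta shifts) and two latent subtypes carrying a second, disjoint
  panel;
- per-tumor individual mean profiles, so paired aqueous-humor (AH) samples
  are recognizably *their* tumor and not just their subtype;
- AH samples as noisy re-reads of the paired tumor's mean profile;
- leukocyte profiles and convex purity mixtures (the simulated counterpart
  of the LUMP purity assay);
- input-mass-dependent beta noise via a mean-preserving Beta(mu, kappa)
  resampling model, where larger kappa corresponds to more input DNA;
- expression fold changes coupled to promoter/body methylation for a set
  of planted "regulated" genes.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` child streams, so identical seeds give
byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ProbeAnnotation

TUMOR_VS_RETINA = "tumor_vs_retina"
SUBTYPE_CONTRAST = "subtype2_vs_subtype1"

#: Sign of the planted log2 fold change per regulated-gene category:
#: promoter hypomethylation and gene-body hypermethylation activate, the
#: mirror patterns repress.
COUPLING_SIGNS = {
    "promoter_hypo_up": +1.0,
    "body_hyper_up": +1.0,
    "promoter_hyper_down": -1.0,
    "body_hypo_down": -1.0,
}

_DESIGN_ROLES = ("retina", "tumor_subtype1", "tumor_subtype2",
                 "AH_paired", "leukocyte")
_STREAMS = ("annotation", "baseline", "panels", "effects", "individual",
            "observe", "leukocyte", "expression", "noise")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def sample_around(mean, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-preserving Beta resampling of beta values.

    Each value mu is replaced by a draw from Beta(mu*kappa, (1-mu)*kappa),
    which has mean mu and variance mu(1-mu)/(kappa+1); kappa plays the role
    of a precision and maps monotonically to input DNA mass. Exact 0 and 1
    are fixed points; NaN propagates.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    mu = np.asarray(mean, dtype=float)
    out = np.array(mu, copy=True)
    mid = np.isfinite(mu) & (mu > 0.0) & (mu < 1.0)
    m = mu[mid]
    out[mid] = rng.beta(m * kappa, (1.0 - m) * kappa)
    return out


def bimodal_baseline(n: int, rng: np.random.Generator,
                     weight_high: float = 0.5) -> np.ndarray:
    """Per-probe baseline means: mixture of Beta(3,19) and Beta(19,3).

    The two components have modes near 0.1 and 0.9, matching the
    genome-wide bimodality of array beta values.
    """
    high = rng.random(n) < weight_high
    lo = rng.beta(3.0, 19.0, size=n)
    hi = rng.beta(19.0, 3.0, size=n)
    return np.where(high, hi, lo)


def mix_purity(tumor_profile, leukocyte_profile, alpha: float):
    """Convex mixture alpha*tumor + (1-alpha)*leukocyte, elementwise."""
    t = np.asarray(tumor_profile, dtype=float)
    l = np.asarray(leukocyte_profile, dtype=float)
    if t.shape != l.shape:
        raise ValueError("tumor and leukocyte profiles differ in length")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    mixed = alpha * t + (1.0 - alpha) * l
    if isinstance(tumor_profile, pd.Series):
        return pd.Series(mixed, index=tumor_profile.index)
    return mixed


def apply_low_input_noise(betas: BetaMatrix, kappa: float,
                          seed: int = 0) -> BetaMatrix:
    """Re-sample every unmasked beta at precision kappa (low-input model).

    The output equals the input in expectation; masked cells stay masked.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = np.random.default_rng(seed)
    noisy = sample_around(betas.beta.to_numpy(), kappa, rng)
    df = pd.DataFrame(noisy, index=betas.probe_ids, columns=betas.sample_ids)
    return BetaMatrix(df, validate=False)


# ---------------------------------------------------------------------------
# annotation


def make_annotation(n_probes: int, n_genes: int,
                    region_mix: Mapping[str, float] | None = None,
                    flag_rates: Mapping[str, float] | None = None,
                    enhancer_rate: float = 0.10,
                    platform_mix: Mapping[str, float] | None = None,
                    seed: int = 0) -> ProbeAnnotation:
    """Generate a manifest-style probe annotation.

    Parameters
    ----------
    n_probes, n_genes : int
        Table size and size of the gene-symbol pool.
    region_mix : mapping, optional
        Proportions over {promoter, body, other}; default (0.35, 0.35, 0.30),
        roughly the genic-region split of genome-scale arrays.
    flag_rates : mapping, optional
        Independent Bernoulli rates for the {snp, sexchrom, age} exclusion
        flags; default (0.05, 0.03, 0.02).
    enhancer_rate : float
        Rate of the (non-exclusive) enhancer overlap flag.
    platform_mix : mapping, optional
        Proportions for platform membership over {"both", "EPIC", "HM450"};
        default (0.80, 0.15, 0.05).
    """
    if n_probes <= 0 or n_genes <= 0:
        raise ValueError("n_probes and n_genes must be positive")
    region_mix = dict(region_mix or {"promoter": 0.35, "body": 0.35, "other": 0.30})
    flag_rates = dict(flag_rates or {"snp": 0.05, "sexchrom": 0.03, "age": 0.02})
    platform_mix = dict(platform_mix or {"both": 0.80, "EPIC": 0.15, "HM450": 0.05})
    probs = np.array([region_mix.get(c, 0.0) for c in ("promoter", "body", "other")])
    if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("region_mix must be proportions summing to 1")
    for name in ("snp", "sexchrom", "age"):
        r = flag_rates.get(name, 0.0)
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"flag rate {name} outside [0, 1]")

    rng = _rngs(seed)["annotation"]
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id")
    classes = rng.choice(np.array(["promoter", "body", "other"]),
                         size=n_probes, p=probs)

    promoter_tokens = np.array(["TSS200", "TSS1500", "5'UTR", "1stExon"])
    body_tokens = np.array(["Body", "3'UTR"])
    regions = np.empty(n_probes, dtype=object)
    for i, cls in enumerate(classes):
        if cls == "promoter":
            regions[i] = rng.choice(promoter_tokens)
        elif cls == "body":
            regions[i] = rng.choice(body_tokens)
        else:
            regions[i] = "ExonBnd" if rng.random() < 0.2 else ""

    genes = np.array([f"G{i:06d}" for i in rng.integers(0, n_genes, size=n_probes)])
    snp = rng.random(n_probes) < flag_rates.get("snp", 0.0)
    sexchrom = rng.random(n_probes) < flag_rates.get("sexchrom", 0.0)
    age = rng.random(n_probes) < flag_rates.get("age", 0.0)
    enhancer = rng.random(n_probes) < enhancer_rate

    autosomes = np.array([f"chr{i}" for i in rng.integers(1, 23, size=n_probes)])
    sexchr = np.where(rng.random(n_probes) < 0.5, "chrX", "chrY")
    chrom = np.where(sexchrom, sexchr, autosomes)
    pos = rng.integers(1, 2**27, size=n_probes)

    plat_choices = np.array(["EPIC;HM450", "EPIC", "HM450"])
    plat_p = np.array([platform_mix.get("both", 0.0),
                       platform_mix.get("EPIC", 0.0),
                       platform_mix.get("HM450", 0.0)])
    if abs(plat_p.sum() - 1.0) > 1e-9:
        raise ValueError("platform_mix must sum to 1")
    platforms = rng.choice(plat_choices, size=n_probes, p=plat_p)

    df = pd.DataFrame({
        "chrom": chrom, "pos": pos, "genes": genes, "regions": regions,
        "enhancer": enhancer, "snp": snp, "sexchrom": sexchrom, "age": age,
        "platforms": platforms,
    }, index=probe_ids)
    return ProbeAnnotation(df)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class PlantedEffects:
    """Planted effect sizes and panel sizes for :func:`make_cohort`.

    Attributes
    ----------
    tumor_delta, tumor_panel_size : float, int
        Signed magnitude and size of the retina-vs-tumor panel; a
        ``tumor_hyper_fraction`` share of the panel is shifted up in tumors
        (default 0.19, the hyper/hypo split characteristic of this tumor
        type), the rest down.
    subtype_delta, subtype_panel_size : float, int
        Panel separating latent tumor subtype 2 from subtype 1 (half up,
        half down in subtype 2), disjoint from the tumor panel by default.
    n_regulated_per_category : int
        Planted methylation-regulated genes per coupling category (see
        :data:`COUPLING_SIGNS`); their probes are embedded in the tumor
        panel with the matching region class and direction.
    n_lump_probes, lump_beta : int, float
        Designated purity (LUMP) probe set: methylated at ``lump_beta`` in
        retina/tumor/AH, unmethylated (0) in leukocytes.
    kappa_individual : float
        Precision of the per-tumor individual mean-profile layer
        (inter-tumor biological variability).
    subtype_overlap : bool
        Allow the subtype panel to overlap the tumor panel.
    """

    tumor_delta: float = 0.4
    tumor_panel_size: int = 500
    tumor_hyper_fraction: float = 0.19
    subtype_delta: float = 0.5
    subtype_panel_size: int = 500
    n_regulated_per_category: int = 10
    n_lump_probes: int = 40
    lump_beta: float = 0.85
    kappa_individual: float = 1000.0
    subtype_overlap: bool = False


@dataclass
class TruthRecord:
    """Ground truth for one simulated cohort.

    ``dm_probes`` maps contrast name -> probe id -> signed planted
    delta-beta (arm A minus arm B). ``regulated_genes`` maps gene symbol ->
    coupling category. ``noise_precision`` holds the per-sample kappa used
    for the observation layer.
    """

    dm_probes: dict[str, dict[str, float]] = field(default_factory=dict)
    subtype_labels: dict[str, int] = field(default_factory=dict)
    pairing: dict[str, str] = field(default_factory=dict)
    purity: dict[str, float] = field(default_factory=dict)
    regulated_genes: dict[str, str] = field(default_factory=dict)
    noise_precision: dict[str, float] = field(default_factory=dict)
    lump_probes: list[str] = field(default_factory=list)

    def planted(self, contrast: str) -> dict[str, float]:
        return self.dm_probes.get(contrast, {})

    def hyper_probes(self, contrast: str) -> list[str]:
        return [p for p, d in self.planted(contrast).items() if d > 0]

    def hypo_probes(self, contrast: str) -> list[str]:
        return [p for p, d in self.planted(contrast).items() if d < 0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def _pick_regulated(annotation, pool, region_class, effects, rng, used_genes):
    """Pick planted regulated-gene probes of one (region, direction) kind."""
    gene_of = annotation.df["genes"]
    cls = annotation.region_class
    candidates = [p for p in pool if cls[p] == region_class]
    rng.shuffle(candidates)
    chosen = []
    for p in candidates:
        g = gene_of[p]
        if g and g not in used_genes:
            used_genes.add(g)
            chosen.append(p)
            if len(chosen) == effects.n_regulated_per_category:
                return chosen
    raise ValueError(
        f"not enough {region_class} probes with unused genes to plant "
        f"{effects.n_regulated_per_category} regulated genes")


def make_cohort(annotation: ProbeAnnotation,
                design: Mapping[str, object],
                effects: PlantedEffects | None = None,
                noise_precision: Mapping[str, float] | None = None,
                seed: int = 0,
                purity: Mapping[str, float] | None = None,
                ) -> tuple[BetaMatrix, pd.DataFrame, TruthRecord]:
    """Simulate a cohort of retina, tumor, paired-AH and leukocyte samples.

    Parameters
    ----------
    annotation : ProbeAnnotation
        Probe table (typically from :func:`make_annotation`).
    design : mapping
        Group sizes keyed by ``retina``, ``tumor_subtype1``,
        ``tumor_subtype2``, ``AH_paired`` and ``leukocyte``. ``AH_paired``
        is either an int (paired to the first tumors, subtype 1 first) or a
        mapping ``{"tumor_subtype1": a, "tumor_subtype2": b}``.
    effects : PlantedEffects, optional
    noise_precision : mapping, optional
        Observation-layer kappa per role; default 200 for every role
        (retina, tumor, AH, leukocyte).
    purity : mapping, optional
        Per-sample tumor fraction alpha in [0, 1] keyed by generated sample
        id (``Tumor_01``, ``AH_01``, ...); samples not listed are pure
        (alpha = 1). Impure samples are convex mixtures with the leukocyte
        mean profile, mirroring what the LUMP assay estimates.

    Returns
    -------
    (BetaMatrix, sample sheet DataFrame, TruthRecord)
    """
    effects = effects or PlantedEffects()
    kappas = {"retina": 200.0, "tumor": 200.0, "AH": 200.0, "leukocyte": 200.0}
    if noise_precision:
        kappas.update(noise_precision)
    if any(k <= 0 for k in kappas.values()):
        raise ValueError("noise precisions must be positive")
    unknown = set(design) - set(_DESIGN_ROLES)
    if unknown:
        raise ValueError(f"unknown design roles: {sorted(unknown)}")

    n_retina = int(design.get("retina", 0))
    n_s1 = int(design.get("tumor_subtype1", 0))
    n_s2 = int(design.get("tumor_subtype2", 0))
    n_leuk = int(design.get("leukocyte", 0))
    ah_spec = design.get("AH_paired", 0)

    probes = annotation.probe_ids
    n_probes = len(probes)
    needed = (effects.n_lump_probes + effects.tumor_panel_size
              + (0 if effects.subtype_overlap else effects.subtype_panel_size))
    if needed > n_probes:
        raise ValueError("panel sizes exceed the number of probes")

    rng = _rngs(seed)
    pos_of = {p: i for i, p in enumerate(probes)}

    # baseline (retina-like) per-probe means
    mu0 = bimodal_baseline(n_probes, rng["baseline"])

    shuffled = list(probes)
    rng["panels"].shuffle(shuffled)
    lump = shuffled[:effects.n_lump_probes]
    pool = shuffled[effects.n_lump_probes:]

    # ---- tumor-vs-retina panel, with embedded regulated-gene probes
    used_genes: set[str] = set()
    reg_probe_cat: dict[str, str] = {}
    hyper: list[str] = []
    hypo: list[str] = []
    if effects.tumor_panel_size > 0:
        if effects.n_regulated_per_category > 0:
            for cat, region_cls, direction in (
                    ("promoter_hyper_down", "promoter", "hyper"),
                    ("body_hyper_up", "body", "hyper"),
                    ("promoter_hypo_up", "promoter", "hypo"),
                    ("body_hypo_down", "body", "hypo")):
                picked = _pick_regulated(annotation, pool, region_cls,
                                         effects, rng["panels"], used_genes)
                for p in picked:
                    reg_probe_cat[p] = cat
                (hyper if direction == "hyper" else hypo).extend(picked)
        n_hyper = int(round(effects.tumor_hyper_fraction * effects.tumor_panel_size))
        n_hyper = max(n_hyper, len(hyper))
        n_hypo = effects.tumor_panel_size - n_hyper
        if n_hypo < len(hypo):
            raise ValueError("tumor panel too small for the planted regulated genes")
        gene_of = annotation.df["genes"]
        taken = set(hyper) | set(hypo)
        filler = [p for p in pool
                  if p not in taken and gene_of[p] not in used_genes]
        need_hyper = n_hyper - len(hyper)
        need_hypo = n_hypo - len(hypo)
        if need_hyper + need_hypo > len(filler):
            raise ValueError("not enough free probes for the tumor panel")
        hyper += filler[:need_hyper]
        hypo += filler[need_hyper:need_hyper + need_hypo]

    # ---- subtype panel (disjoint from tumor panel unless overlap allowed;
    # probes of planted regulated genes are always avoided so recovery is
    # unconfounded)
    taken = set(lump) | set(hyper) | set(hypo)
    gene_of = annotation.df["genes"]
    if effects.subtype_overlap:
        sub_pool = [p for p in pool if gene_of[p] not in used_genes]
    else:
        sub_pool = [p for p in pool
                    if p not in taken and gene_of[p] not in used_genes]
    if effects.subtype_panel_size > len(sub_pool):
        raise ValueError("not enough free probes for the subtype panel")
    sub_panel = sub_pool[:effects.subtype_panel_size]
    n_sub_hyper = effects.subtype_panel_size // 2
    sub_hyper = sub_panel[:n_sub_hyper]
    sub_hypo = sub_panel[n_sub_hyper:]

    # ---- planted means: resample baselines so the full shift stays in [0,1]
    eff_rng = rng["effects"]
    tumor_shift = np.zeros(n_probes)
    d = effects.tumor_delta
    for p in hyper:
        i = pos_of[p]
        mu0[i] = eff_rng.uniform(0.05, 0.95 - d)
        tumor_shift[i] = +d
    for p in hypo:
        i = pos_of[p]
        mu0[i] = eff_rng.uniform(0.05 + d, 0.95)
        tumor_shift[i] = -d
    d2 = effects.subtype_delta
    sub_shift = np.zeros(n_probes)
    for p in sub_hyper:
        i = pos_of[p]
        mu0[i] = eff_rng.uniform(0.05, 0.95 - d2)
        sub_shift[i] = +d2
    for p in sub_hypo:
        i = pos_of[p]
        mu0[i] = eff_rng.uniform(0.05 + d2, 0.95)
        sub_shift[i] = -d2

    lump_idx = np.array([pos_of[p] for p in lump], dtype=int)
    retina_mean = mu0.copy()
    if len(lump_idx):
        retina_mean[lump_idx] = effects.lump_beta
    tumor_base = np.clip(retina_mean + tumor_shift, 0.0, 1.0)
    s_mean = {1: tumor_base,
              2: np.clip(tumor_base + sub_shift, 0.0, 1.0)}
    leuk_mean = bimodal_baseline(n_probes, rng["leukocyte"])
    if len(lump_idx):
        leuk_mean[lump_idx] = 0.0

    # ---- sample bookkeeping
    tumor_ids = ([f"Tumor_{i+1:02d}" for i in range(n_s1)]
                 + [f"Tumor_{n_s1 + i + 1:02d}" for i in range(n_s2)])
    tumor_subtype = {t: (1 if i < n_s1 else 2) for i, t in enumerate(tumor_ids)}
    if isinstance(ah_spec, Mapping):
        bad = set(ah_spec) - {"tumor_subtype1", "tumor_subtype2"}
        if bad:
            raise ValueError(f"unknown AH_paired keys: {sorted(bad)}")
        a = int(ah_spec.get("tumor_subtype1", 0))
        b = int(ah_spec.get("tumor_subtype2", 0))
        if a > n_s1 or b > n_s2:
            raise ValueError("more paired AH samples requested than tumors")
        paired_tumors = tumor_ids[:a] + tumor_ids[n_s1:n_s1 + b]
    else:
        n_ah = int(ah_spec)
        if n_ah > len(tumor_ids):
            raise ValueError("more paired AH samples requested than tumors")
        paired_tumors = tumor_ids[:n_ah]
    ah_ids = [f"AH_{i+1:02d}" for i in range(len(paired_tumors))]
    pairing = dict(zip(ah_ids, paired_tumors))
    retina_ids = [f"Retina_{i+1:02d}" for i in range(n_retina)]
    leuk_ids = [f"Leukocyte_{i+1:02d}" for i in range(n_leuk)]

    alpha_of = {s: 1.0 for s in tumor_ids + ah_ids}
    if purity:
        unknown = set(purity) - set(alpha_of)
        if unknown:
            raise ValueError(f"purity given for unknown samples: {sorted(unknown)}")
        for s, a in purity.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError("purity values must lie in [0, 1]")
            alpha_of[s] = float(a)

    ind_rng, obs_rng = rng["individual"], rng["observe"]
    columns: dict[str, np.ndarray] = {}
    for s in retina_ids:
        ind = sample_around(retina_mean, effects.kappa_individual, ind_rng)
        columns[s] = sample_around(ind, kappas["retina"], obs_rng)
    tumor_ind: dict[str, np.ndarray] = {}
    for t in tumor_ids:
        ind = sample_around(s_mean[tumor_subtype[t]],
                            effects.kappa_individual, ind_rng)
        tumor_ind[t] = ind
        mean = mix_purity(ind, leuk_mean, alpha_of[t])
        columns[t] = sample_around(mean, kappas["tumor"], obs_rng)
    for a_id, t_id in pairing.items():
        mean = mix_purity(tumor_ind[t_id], leuk_mean, alpha_of[a_id])
        columns[a_id] = sample_around(mean, kappas["AH"], obs_rng)
    for s in leuk_ids:
        columns[s] = sample_around(leuk_mean, kappas["leukocyte"], obs_rng)

    order = retina_ids + tumor_ids + ah_ids + leuk_ids
    beta = BetaMatrix(
        pd.DataFrame({s: columns[s] for s in order}, index=probes),
        validate=False)

    # ---- sample sheet
    def outcome_of(t: str) -> str:
        if tumor_subtype[t] == 1:
            return "SV"
        k = tumor_ids.index(t) - n_s1
        return "PE" if k % 2 == 0 else "SE"

    rows = []
    for s in retina_ids:
        rows.append((s, "retina", None, None, None))
    for t in tumor_ids:
        rows.append((t, "tumor", None, outcome_of(t), tumor_subtype[t]))
    for a_id, t_id in pairing.items():
        rows.append((a_id, "AH", t_id, outcome_of(t_id), tumor_subtype[t_id]))
    for s in leuk_ids:
        rows.append((s, "leukocyte", None, None, None))
    sheet = pd.DataFrame(rows, columns=["sample_id", "role", "pair_id",
                                        "outcome", "subtype"]).set_index("sample_id")
    sheet["cohort"] = "sim"

    kappa_of = {}
    for s in retina_ids:
        kappa_of[s] = kappas["retina"]
    for s in tumor_ids:
        kappa_of[s] = kappas["tumor"]
    for s in ah_ids:
        kappa_of[s] = kappas["AH"]
    for s in leuk_ids:
        kappa_of[s] = kappas["leukocyte"]

    gene_of = annotation.df["genes"]
    truth = TruthRecord(
        dm_probes={
            TUMOR_VS_RETINA: {p: +d for p in hyper} | {p: -d for p in hypo},
            SUBTYPE_CONTRAST: ({p: +d2 for p in sub_hyper}
                               | {p: -d2 for p in sub_hypo}),
        },
        subtype_labels={s: tumor_subtype.get(s) or tumor_subtype[pairing[s]]
                        for s in tumor_ids + ah_ids},
        pairing=pairing,
        purity=alpha_of,
        regulated_genes={gene_of[p]: cat for p, cat in reg_probe_cat.items()},
        noise_precision=kappa_of,
        lump_probes=list(lump),
    )
    return beta, sheet, truth


# ---------------------------------------------------------------------------
# expression


def make_expression(truth: TruthRecord, annotation: ProbeAnnotation,
                    coupling: Mapping[str, float] | None = None,
                    noise_sd: float = 0.25,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two independent noisy expression replicates coupled to the truth.

    Planted regulated genes get log2FC = sign * (2 + |noise|), where the
    sign follows the coupling rule (promoter-hypo and body-hyper activate,
    the mirror patterns repress); every other gene is centered at 0 with
    standard deviation ``noise_sd``. Two tables emulate two independent
    expression datasets whose fold-change calls are later intersected.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    coupling = dict(coupling or COUPLING_SIGNS)
    unknown = set(truth.regulated_genes.values()) - set(coupling)
    if unknown:
        raise ValueError(f"unknown regulated-gene categories: {sorted(unknown)}")
    genes = sorted({g for lst in annotation.gene_lists for g in lst if g})
    rng = _rngs(seed)["expression"]
    tables = []
    for source in ("sim_expr_A", "sim_expr_B"):
        fc = rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd > 0 \
            else np.zeros(len(genes))
        fc = pd.Series(fc, index=genes)
        for g, cat in truth.regulated_genes.items():
            sign = 1.0 if coupling[cat] > 0 else -1.0
            eps = abs(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            fc[g] = sign * (2.0 + eps)
        tables.append(pd.DataFrame({"gene": genes,
                                    "log2FC": fc.to_numpy(),
                                    "source": source}))
    return tables[0], tables[1]
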