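# aqmeth

Methylation-array analysis for aqueous-humor (AH) liquid biopsies in
retinoblastoma — and, more generally, for any beta-value cohort that needs
probe filtering, purity gating, differential methylation, expression
integration and prognostic signature derivation.

## The problem

Retinoblastoma is a childhood eye cancer for which direct tumor biopsy is
contraindicated, so molecular tumor profiles are normally available only
after the eye is removed. The aqueous humor — the clear fluid of the eye's
anterior chamber — carries tumor-derived cell-free DNA (cfDNA) and can be
sampled safely during therapy. Genome-scale DNA methylation arrays applied
to AH cfDNA make it possible to (i) verify that the AH methylation profile
faithfully represents the tumor, (ii) find tumor-specific methylation
changes and the genes they regulate, and (iii) derive methylation
signatures that separate eyes salvaged by therapy from eyes that required
enucleation.

`aqmeth` implements that analysis chain as a tested library with a thin
CLI, plus a synthetic-cohort generator with planted ground truth so every
stage is verifiable without any external download.

## What it computes

- **Beta values and masking.** β = M/(M+U) per probe and sample, with
  measurements masked when the detection p-value exceeds 0.05; probes
  linked to polymorphisms, on chrX/chrY, or aging-related are removed, and
  cohorts on different platforms (EPIC / HM450) are intersected.
- **Purity gating (LUMP).** Per-sample purity = min(1, mean β over a
  leukocyte-unmethylated probe set / 0.85); samples under 50% tumor
  fraction are dropped.
- **Differential methylation.** Per-probe two-sided Welch's *t*
  (Welch–Satterthwaite df) with effect-size selection
  Δβ = mean(arm A) − mean(arm B); probes pass with |Δβ| > δ and p < α
  (strict inequalities). Hyper/hypo fractions and genic-region enrichment
  (promoter = TSS200/TSS1500/5'UTR/1st exon; body = gene body/3'UTR)
  summarize the selection.
- **Methylation-regulated genes.** Genes with a promoter-hypo / body-hyper
  probe and replicated up-regulation (log2FC > 1 in two expression
  datasets), or the mirror pattern with down-regulation.
- **Signatures and clusters.** Top-k most variable probes, agglomerative
  clustering (Euclidean, complete linkage by default), classical
  (Torgerson) MDS, outcome-linked panel derivation (Δβ > 0.4, p < 0.01),
  two-group cluster assignment (Cluster A = salvage-enriched), and an
  exact 2×2 cluster-vs-outcome test (doubled hypergeometric tail).
- **Concordance.** Paired tumor–AH agreement as r² (squared Pearson), a
  best-match report against declared pairs, and the input-mass titration
  curve under the Beta(μ, κ) noise model.

The statistical core is also exposed as scikit-learn-style estimators
(`WelchDMSelector`, `TopVariableProbeSelector`, `ClassicalMDS`,
`SignatureClusterer`, `LUMPPurity`) that compose with sklearn pipelines.

## Worked example

```python
import aqmeth as aq

ann = aq.make_annotation(n_probes=20000, n_genes=6000, seed=0)
betas, sheet, truth = aq.make_cohort(
    ann,
    design={"retina": 12, "tumor_subtype1": 8, "tumor_subtype2": 8,
            "AH_paired": 4, "leukocyte": 2},
    seed=0)

tumors = list(sheet.index[sheet.role == "tumor"])
retina = list(sheet.index[sheet.role == "retina"])

# tumor-vs-retina differential methylation
dm = aq.dm_table(betas, tumors, retina, annotation=ann,
                 label="tumor_vs_retina")
hyper, hypo = aq.select_dm(dm)
fh, fl = aq.direction_fractions(hyper, hypo)
print(f"differential probes: {len(hyper) + len(hypo)} "
      f"({fh:.0%} hyper / {fl:.0%} hypo)")

# purity gate
purity = aq.lump_score(betas, truth.lump_probes)
print(f"median LUMP purity: {purity['lump_score'].loc[tumors].median():.3f}")

# paired AH concordance
ah = list(sheet.index[sheet.role == "AH"])
r2 = aq.pairwise_r2(betas, ah, tumors)
report = aq.best_match_report(r2, truth.pairing)
print(f"AH/tumor best-match fraction: {report.attrs['fraction_best']:.2f} "
      f"(median paired r2 = {report['r2_declared'].median():.3f})")

# outcome signature and cluster assignment
sv = [s for s in ah if sheet.loc[s, "outcome"] == "SV"]
enuc = [s for s in tumors if sheet.loc[s, "outcome"] != "SV"]
panel = aq.derive_panel(betas, sv, enuc, delta_thresh=0.4, p_thresh=0.01,
                        label="salvage_vs_enucleated")
asg = aq.assign_clusters(betas, panel, samples=tumors + ah,
                         outcomes=sheet["outcome"])
test = aq.cluster_outcome_test(asg.labels, sheet["outcome"])
print(f"signature panel: {len(panel)} probes; "
      f"cluster A n={len(asg.members('A'))}, B n={len(asg.members('B'))}; "
      f"exact p = {test.p_value:.2e}")
```

Output:

```
differential probes: 500 (19% hyper / 81% hypo)
median LUMP purity: 0.998
AH/tumor best-match fraction: 1.00 (median paired r2 = 0.991)
signature panel: 500 probes; cluster A n=12, B n=8; exact p = 1.59e-05
```

The generator planted a 500-probe tumor panel with the characteristic
19/81 hyper/hypo split, pure tumors, and an outcome-linked subtype panel;
the pipeline recovers all of it: every planted probe is selected, each AH
sample's best-correlated tumor is its declared pair, and the two clusters
separate salvaged from enucleated samples perfectly (the p-value is the
doubled exact hypergeometric tail of the 12-vs-8 table).

The same chain is available from a shell via the `aqmeth` CLI
(`simulate`, `preprocess`, `purity`, `dm`, `regulate`,
`signature derive|assign|concord`, `concord`).

## Applying it to real cohorts

The package starts from matrices, not raw IDATs: export normalized
β values (or M/U intensities and detection p-values) to TSV, the probe
manifest and sample sheet to CSV, and run the same chain
(`preprocess` → `purity` → `dm` → `regulate` / `signature`). IDAT
decoding, background/dye-bias correction, copy-number calling and pathway
analysis are deliberately out of scope.
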