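# mthet

Replicate-based detection of low-level mitochondrial point heteroplasmy
(PHP) and the downstream "PHP landscape" statistics.

## The problem

A point heteroplasmy is the coexistence of two single-base mtDNA alleles at
one rCRS position within a person and tissue, quantified by the minor allele
fraction (MAF).  Below ~1% MAF, genuine heteroplasmies overlap with the
substitution-error noise of deep sequencing, so single-library calls are
unreliable.  The approach implemented here suppresses that noise
experimentally rather than statistically: a minor allele is accepted only if
it is **completely reproducible** — present, with reads on both strands, in
*every* biological, PCR and library replicate of a donor/tissue, above a
genotype-quality gate, and concordant across two sequencing platforms and
two independent analysis pipelines.  The package is aimed at forensic and
medical mtDNA groups who run replicated deep-coverage (~7,700x) whole-mtDNA
panels and want tested, scriptable building blocks for that cascade.

## What is in the box

| module | role |
|---|---|
| `mthet.reference` | packaged rCRS (NC_012920.1) + locus map; region / HVS / codon annotation, synonymous vs non-synonymous classification under the vertebrate mito code, `m.<pos><maj>><IUPAC>` naming |
| `mthet.simulate` | synthetic strand-resolved replicate count tables with known truth: 11 donors x 2 tissues, 159 libraries, two platforms with distinct error profiles, negative-binomial ~7,746x coverage, CR-hotspot-enriched PHPs down to 0.1% MAF |
| `mthet.calling` | per-library minor-allele caller: AT/IT = 0.1%, minimum minor count 10 (fall-back 2), binomial likelihood-ratio GQ, Fisher-exact strand bias |
| `mthet.concordance` | the confirmation cascade: all-replicate reproducibility, both-strand rule, GQ > 41 gate, platform-B and pipeline-P2 concordance, read-count-only rescue |
| `mthet.landscape` | event/position counts per tissue, region distributions, MAF cut-off profiles, multi-person hotspot tables, tissue specificity, co-occurrence (linkage) permutation test, longitudinal stability, blood:buccal ratios |
| `mthet.io` / `mthet.cli` | strict TSV readers/writers, minimal VCF export, YAML run configs; `mthet simulate | call | confirm | annotate | summarize` |

Thresholds live in one dataclass (`calling.Thresholds`): analysis and
interpretation thresholds both default to 0.1% MAF, minimum minor-read count
10 with a fall-back of 2 for depth-limited replicates, GQ gate 41.

## Worked example

Annotate three heteroplasmies against the packaged rCRS gene map:

```python
from mthet import reference as R

for pos, major, minor in [(3586, "C", "T"), (16093, "T", "C"), (14539, "A", "G")]:
    ann = R.classify_substitution(pos, major, minor)
    print(ann.hgvs_name, ann.region.locus_name, ann.region.region_class,
          ann.change_class, ann.coding_effect, ann.aa_change)
```

prints

```
m.3586C>Y MT-ND1 protein_coding transition non_synonymous p.P94S
m.16093T>Y MT-HV1 control_region transition non_coding None
m.14539A>R MT-ND6 protein_coding transition synonymous None
```

`m.3586C>Y` substitutes the first base of MT-ND1 codon 94 and changes
proline to serine (p.P94S); `m.16093T>Y` sits in hypervariable segment I of
the control region; `m.14539A>R` is a third-codon-position transition in the
light-strand gene MT-ND6 (reverse-complemented before translation), hence
synonymous.  The IUPAC code after `>` names the observed base mixture
(Y = C/T, R = A/G).

The same cascade end-to-end on synthetic data:

```python
from mthet import simulate, calling, concordance

cfg = simulate.StudyConfig(n_donors=2, n_technical_donors=0,
                           n_timepoints=1, replicates_per_timepoint=3)
study = simulate.simulate_study(cfg, seed=1)
th = calling.Thresholds()
calls = {lib: calling.call_library(df, th, library_id=lib)
         for lib, df in study.counts.items()}
confirmed = concordance.confirmed_only(
    concordance.confirm(calls, study.manifest, th,
                        counts_by_library=study.counts))
print(len(study.truth), sum(len(v) for v in calls.values()), len(confirmed))
```

prints `29 390 23`: the 16 libraries produce 390 raw per-library
minor-allele calls (mostly sequencing noise), the cascade confirms 23 —
every one of them a planted truth record, including all 20 with true
MAF >= 0.5%.

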