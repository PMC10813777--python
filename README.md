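# neutralstab

Community-assembly and community-stability analysis for 16S amplicon count
tables, built around the study design of microalgae-inoculated shrimp-rearing
water: four treatment groups (control **C**, *Nannochloropsis oculata* **N**,
*Thalassiosira weissflogii* **T**, mixed **M**), three replicate tanks, eight
sampling days, and two bacterial lifestyles (particle-attached **PA**,
free-living **FL**) — 192 samples in a full factorial cross.

It is aimed at microbial ecologists who want the full chain — neutral-model
fitting, stability indexing, and the standard distance-based test battery —
as one tested, scriptable toolkit, plus a synthetic-data generator so every
stage can be exercised (and its statistical behaviour verified) without any
sequencing data.

## What it computes

**Sloan neutral community model (NCM).** For a taxon with metacommunity
relative abundance *p*, the expected occurrence frequency across local
communities of size *N* (reads) with detection limit *d* reads is

    F(p) = 1 − I_{d/N}(Nm·p, Nm·(1−p))

where *I* is the regularised incomplete beta function and *Nm* = *N·m* is
community size times immigration rate. `fit_ncm` estimates *Nm* by nonlinear
least squares of observed occurrence frequencies on *F(p)*, reports
R², *m* = *Nm/N*, and partitions taxa into `above` / `neutral` / `below` a
95% binomial prediction band around the fitted curve. Partition summaries
(taxon counts, cumulative relative abundance, per-family breakdown) follow.

**AVD stability index.** The average variation degree of a sample group with
*k* samples and *n* taxa,

    AVD = Σᵢ Σⱼ |xᵢⱼ − x̄ᵢ| / δᵢ / (k·n),

where x̄ᵢ and δᵢ are the mean and standard deviation of taxon *i*'s rarefied
abundance within the group. Lower AVD = more stable community. Computed per
group × lifestyle stratum with replicate-level values for ANOVA + Tukey HSD
comparisons and a compact letter display.

**Distance-based statistics**, all implemented here and cross-checked
against independent references in the test suite: Bray–Curtis dissimilarity,
PCoA, RDA and distance-based RDA (CPCoA), PERMANOVA with sequential Type-I
sums of squares and interaction terms, ANOSIM, MRPP, the Spearman Mantel
test, one-way ANOVA + Tukey, UPGMA clustering with Newick output, and the
usual alpha-diversity panel (observed, Shannon, Simpson, Chao1, Pielou).

**Synthetic data.** `simulate_study` generates the full 4 × 3 × 8 × 2 design
from the model's own sampling process — per-taxon local abundances
x ~ Beta(Nm·p, Nm·(1−p)), reads ~ Binomial(N, x) — with per-group Nm,
injected taxa that occur more/less often than neutrality predicts (with
sample totals conserved exactly), and group-structured nutrient covariates
(NH₄⁺-N, NO₂⁻-N, NO₃⁻-N, PO₄³⁻-P plus day-0-baseline change columns).

## Worked example

```python
from neutralstab.simulate import StudyDesignConfig, simulate_study
from neutralstab.ncm import fit_ncm, partition_abundance
from neutralstab.avd import avd_by_stratum
from neutralstab.datamodel import rarefy

cfg = StudyDesignConfig(seed=11)          # 4 groups x 3 reps x 8 days x PA/FL
table, frame, truth = simulate_study(cfg)  # 1000 ZOTUs x 192 samples

for group in ("C", "N", "T", "M"):
    ids = frame.data.index[frame.data["group"] == group]
    fit = fit_ncm(table.subset_samples(ids))
    neutral = partition_abundance(fit).cumulative_abundance("neutral")
    print(f"{group}: Nm={fit.nm:7.1f}  R2={fit.r_squared:.3f}  "
          f"neutral abundance={100 * neutral:.1f}%")

rare = rarefy(table, int(table.sample_totals().min()), seed=11)
results, _ = avd_by_stratum(rare, frame)
for r in results[:4]:
    print(f"AVD {r.group}: {r.avd:.4f} (k={r.k}, n={r.n})")
```

prints

```
C: Nm= 2646.2  R2=0.689  neutral abundance=78.7%
N: Nm= 1652.3  R2=0.648  neutral abundance=79.5%
T: Nm=  874.6  R2=0.568  neutral abundance=79.4%
M: Nm= 1320.5  R2=0.619  neutral abundance=77.1%
AVD C_PA: 0.6555 (k=24, n=891)
AVD C_FL: 0.6555 (k=24, n=879)
AVD N_PA: 0.6260 (k=24, n=866)
AVD N_FL: 0.6268 (k=24, n=868)
```

The simulated groups were assembled at Nm = 1500 (C), 1000 (N), 600 (T),
800 (M): the fitted values rank the groups correctly (the absolute level
carries a known upward bias from the binomial read layer; see
`docs/methods.md`), R² falls in the 0.55–0.70 range typical of rearing-water
communities, and the fitted m = Nm/N is the per-generation immigration
probability. Lower AVD in the N strata than C says those simulated
communities deviate less, in per-taxon SD units, around their mean profile.

The same analyses run from the shell:

```bash
neutralstab simulate --seed 11 --out-dir data/
neutralstab ncm --counts data/counts.tsv --metadata data/metadata.tsv --out ncm_out/
neutralstab avd --counts data/counts.tsv --metadata data/metadata.tsv --out avd_out/
neutralstab run --config config.yaml --seed 42 --out results/
neutralstab figures --out results/
```

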