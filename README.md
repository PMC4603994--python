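# ordimap

Covariate-adjusted Kendall correlation and SVD-based multidimensional
scaling (MDS) of joint miRNA/mRNA expression profiles.

## The problem

Studies that correlate miRNA and mRNA expression across tissue samples
routinely find both negative correlations (consistent with miRNAs
destabilizing their target mRNAs) and positive ones (feed-forward loops in
which a transcription factor drives a miRNA and its targets together).
Summarizing the tens of thousands of pairwise correlations among even a
few hundred differentially expressed genes calls for a robust multivariate
map. In diseased human tissue there is an extra trap: the histological
composition of each sample — e.g. the degree of hepatocellular necrosis in
acute liver failure, where hepatocyte transcripts fall and
immune-infiltrate transcripts rise with the lesion grade — acts as a
confounder that manufactures large spurious correlations of both signs.

`ordimap` implements the full analysis for that setting, aimed at
computational biologists working with bulk expression matrices of a
diseased and a control group:

1. **Differential expression** — a multivariate permutation F-test
   controlling the false-discovery proportion at a target rate with a
   stated confidence, plus a signed geometric-mean fold-change filter.
2. **Association** — pairwise Kendall tau-b over all miRNA–mRNA,
   miRNA–miRNA and mRNA–mRNA pairs; for the diseased group, the
   first-order *partial* tau with the tissue-damage covariate removed:

   τ<sub>xy·z</sub> = (τ<sub>xy</sub> − τ<sub>xz</sub>τ<sub>yz</sub>) / √((1 − τ<sub>xz</sub>²)(1 − τ<sub>yz</sub>²))

3. **Ordination** — correlations become zero-centered nonmetric distances
   d = (−1)·τ and are embedded by classical scaling computed through the
   SVD: B = J(−d)J with J = I − (1/n)𝟙𝟙ᵀ, B = UΣVᵀ, coordinates UΣ^{1/2}.
   Sammon's mapping and Kruskal's nonmetric MDS are available as
   robustness comparators, with a Procrustes statistic to quantify
   configuration agreement.
4. **Thematic maps** — 1.6-SD dispersion ellipses around functional gene
   classes, kernel density fields with a miRNA/mRNA complementarity
   score, per-miRNA median-correlation shifts between conditions
   (±0.15 τ threshold), target-pair distances with a sign-flip control
   ordination, a multiple regression of mirSVR target scores on
   per-dimension map distances (first 50 dimensions), and grouping of
   miRNAs by identical seed sequence.
5. **Synthetic studies** — a generator that emulates the study design
   (13 diseased + 17 control samples, 109 miRNAs + 531 mRNAs, an ordinal
   necrosis covariate, functional co-expression blocks, inhibitory and
   feed-forward miRNA–mRNA couplings) with full ground truth, so every
   stage is testable offline. All randomness flows from a single integer
   seed through one numpy `Generator` (PCG64 bit generator), so runs are
   bit-reproducible.

## Worked example

```python
import ordimap as om

cfg = om.StudyConfig(rng_seed=1)            # the default study shape
bundle = om.generate_study(cfg)
cov = bundle.necrosis_covariate()

simple  = om.pairwise_matrix(bundle.case_matrix)
partial = om.pairwise_matrix(bundle.case_matrix, covariate=cov,
                             covariate_name="necrosis")
for name, assoc in [("simple", simple), ("partial", partial)]:
    prof = om.distribution_profile(assoc)
    print(f"{name:8s} tau bimodality coefficient: "
          f"{prof.bimodality_coefficient:.3f}  bimodal: {prof.is_bimodal}")

ordn = om.classical_scaling_svd(om.to_distance(partial), k=3)
screen = om.covariate_screen(bundle.case_matrix, cov, threshold=0.9)
rep = om.target_pair_analysis(ordn, partial, bundle.targets, n_dims=3)
print(f"|R| > 0.9 screen: {len(screen.flagged_ids)}/{len(screen.r)} genes flagged")
print(f"mean target-pair distance: {rep.observed_mean:.3f}  "
      f"background: {rep.background_mean:.3f}  sign-flip: {rep.signflip_mean:.3f}")
```

prints

```
simple   tau bimodality coefficient: 0.664  bimodal: True
partial  tau bimodality coefficient: 0.320  bimodal: False
|R| > 0.9 screen: 106/640 genes flagged
mean target-pair distance: 0.583  background: 0.656  sign-flip: 0.576
```

Reading the numbers: the raw correlations of the diseased matrix are
bimodal (Sarle's coefficient above the 5/9 benchmark) because necrosis
pushes hepatocyte and infiltrate genes in opposite directions; removing
the covariate by partial correlation restores a unimodal distribution.
One sixth of the genes track the covariate at |R| > 0.9. Because this
bundle plants inhibitory and feed-forward couplings in balance, inverting
the sign of all miRNA–mRNA correlations barely changes the mean
target-pair distance on the recomputed map (0.583 vs 0.576) — target
pairs are *not* uniformly far apart, the signature of a bidirectional
regulatory network.

## Command line

```bash
ordimap simulate --config cfg.yaml --out study/ --seed 1
ordimap correlate --matrix study/case_matrix.tsv --samples study/samples.tsv \
    --annotations study/annotations.tsv --covariate necrosis --out assoc.tsv
ordimap ordinate --assoc assoc.tsv --annotations study/annotations.tsv \
    --method svd -k 3 --out coords.tsv
ordimap run --config run.yaml --out results/   # full pipeline + manifest
```

All on-disk formats are plain TSV (see `ordimap.matrix_io`); a full run
writes a `manifest.json` with a content hash per output.

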