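# paleodiet

Multi-isotope paleodietary inference for Bronze Age bioarchaeology: a
tested, reusable implementation of the full analysis chain that links
charred crop remains, animal bone collagen and human bone, dentine and
enamel into quantitative statements about farming practice and diet.

## Who this is for

Bioarchaeologists and isotope ecologists working with small per-site
assemblages of δ13C / δ15N / δ34S measurements who want the standard
analysis steps — collagen preservation screening, charring corrections,
trophic-offset arithmetic, Bayesian diet mixing, apatite-based C4
quantification and exact small-sample statistics — as auditable,
configurable code rather than spreadsheet arithmetic.  The package ships
the per-specimen tables of a western-Switzerland Bronze Age assemblage
(30 charred seeds/chaff, 22 animals, 41 humans from three cemeteries
spanning the Early to Final Bronze Age) as reference data, and a synthetic
generator that emulates the same statistical structure.

## The models

**Collagen QC.** Preserved collagen satisfies %C ≥ 30, %N ≥ 10,
%S ≥ 0.15, 2.9 < C:N < 3.6, C:S = 600 ± 300, N:S = 200 ± 100, yield ≥ 1 %.
Values breaching a bound within a configurable proportional margin are
retained *with caution*; worse breaches fail.  Screening is per tissue.

**Plant corrections and discrimination.** Charred grain: δ13C − 0.11 ‰,
δ15N − 0.31 ‰; wheat chaff: δ13C + 1.9 ‰, δ15N + 2.4 ‰.  Crop water
status uses carbon discrimination against the contemporaneous atmosphere,

    Δ13C = (δ13C_air − δ13C_plant) / (1 + δ13C_plant/1000),

and manuring intensity is banded on δ15N (cereals 3/6 ‰, pulses 0/3 ‰).

**Trophic offsets.** Plant → consumer collagen +4.8 ‰ δ13C; prey collagen
→ consumer collagen +0.8 ‰ δ13C; diet → consumer +4.0 ‰ δ15N.  These give
forage estimates, "100 % of diet from X" endmembers, and the
Δ13C/Δ15N humans−animals and humans−plants spacings.

**Bayesian diet mixing.** For contributions `p` on the simplex with a
Dirichlet prior, each proxy j of the consumer group mean is modelled as

    y_j ~ Normal( Σ_i p_i (μ_ij + Δ_ij),
                  sqrt(σ_j² + Σ_i p_i² (σ_ij² + σΔ_ij²)) )

sampled by an adaptive Metropolis walk on a stick-breaking
reparameterisation (4 chains × 20 000 draws by default), with split-chain
R-hat and effective-sample-size diagnostics.

**Apatite.** Δ13C_ap-coll = enamel δ13C − dentine collagen δ13C (≈ 8.4 ‰
for a monoisotopic diet); the whole-diet C4 share interpolates the
bone-apatite-scale diet value between a −25 ‰ C3 pole and a 15 ‰ C3–C4
span: %C4 = (δ13C_enamel + 1.8 − 9.4 + 25) / 15 × 100.

**Statistics.** Exact (full-enumeration) rank-sum, signed-rank with Pratt
zero handling, and Spearman tests with mid-rank ties; Monte-Carlo
permutation Kruskal–Wallis.  Two-sided p-values are the doubled smaller
tail.

## Worked example

```python
from paleodiet import apatite, mixing, pipeline

study = pipeline.load_study()          # packaged tables + QC
print(len(study.fauna_retained))       # 19   (of 22 animals)
print(pipeline.offsets_table(study).to_string(index=False))
```

```
      site  d13C_humans_animals  d15N_humans_animals  d13C_humans_plants  d15N_humans_plants
  LaBarmaz                  0.5                  3.7                 5.2                 5.0
  Vufflens                  0.7                  3.7                 4.2                 5.9
Tolochenaz                  3.0                  2.5                 5.8                 4.1
```

The Early Bronze Age humans sit one full trophic level (+0.5 ‰ δ13C,
+3.7 ‰ δ15N) above their coeval animals — a mixed C3-plant/animal diet —
while the Final Bronze Age group's +3.0 ‰ carbon spacing signals a
13C-enriched (millet-bearing) diet.  Quantifying that:

```python
he = study.human_enamel()
tol = he[he.site == "Tolochenaz"]
print(apatite.percent_c4(tol.d13C.mean())["percent_c4"])   # 47.2
est = mixing.fit(pipeline.site_scenario(study, "LaBarmaz"), seed=1)
for name, m in zip(est.source_names, est.mean):
    print(f"{name}: {100*m:.1f}%")
```

```
C3 cereals: 44.9%
C4 cereals: 5.1%
herbivore/pig meat: 35.7%
freshwater fish: 14.3%
```

So roughly half the Final Bronze Age childhood diet drew on C4 plants
(47 % of whole-diet carbon), while at the Early Bronze Age cemetery C3
cereals dominate the posterior diet composition, with animal products
second and freshwater fish poorly constrained but minor in the
best-supported region.

The same pipeline is scriptable from the shell:

```sh
paleodiet run-all --seed 1 --out-dir report/
```

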