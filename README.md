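# urbanbees

Analysis pipeline linking urbanization metrics — % impervious surface and
human population density within a 500 m radius — to wild-bee community
structure: local species richness (α), taxonomic dissimilarity (β), and
functional-trait occurrence along the urbanization gradient.  A seeded
synthetic survey generator with known ecological-filter structure makes
every stage testable without external data.

## Pipeline stages

| stage | module | what it does |
| --- | --- | --- |
| load/validate | `urbanbees.core` | schema-checked CSV/TSV input, taxon filters (honeybee, parasitic species), sites × species community table, result (de)serialization |
| aggregate | `urbanbees.preprocess` | complete-linkage merge of sites < 500 m apart (barycenters, collated effort), consensus k-means × hierarchical sampling-scheme categories |
| diversity | `urbanbees.diversity` | richness, Sorensen pairwise dissimilarity, abundance-based sample coverage with Chao1 asymptotic richness |
| alpha | `urbanbees.alpha` | zero-truncated negative-binomial richness regression (Laplace-approximated random intercepts, optional exponential-correlation spatial effect), per-term likelihood-ratio tests, Moran's I residual diagnostics, VIF collinearity screen |
| beta | `urbanbees.beta` | fixed-width gradient binning, mean within-interval pairwise dissimilarity, OLS homogenization trend with normality and confounder diagnostics |
| traits | `urbanbees.traits` | global-pool occurrence expansion, binomial GLMM with trait × metric interactions (site-in-category plus crossed species random intercepts), Benjamini–Hochberg adjustment, prediction curves |
| simulate | `urbanbees.synthetic` | scenario presets (`tiny`, `null`, `filter_paper_like`) writing the three standard CSVs |

## Input schemas (CSV by default, TSV via format options)

```
records.csv  site_id,species,count[,year]
sites.csv    site_id,x,y,pop_density,impervious_pct,region,active_days,passive_hours,kick_net
traits.csv   species,nesting,sociality,diet,size,itd_mm,parasitic
```

Coordinates are planar meters in any projected CRS (e.g. a national
grid); geographic lon/lat can be converted at load time with
`format_options={"coords": "lonlat"}`.  Trait modalities use
`above/below`, `social/solitary`, `generalist/specialist`,
`small/large`, each with a `no_information` third category; the
small/large split is at ITD = 2 mm.

## CLI

```bash
urbanbees simulate --scenario tiny --seed 7 --out data/
urbanbees validate  data/records.csv data/sites.csv data/traits.csv
urbanbees aggregate data/records.csv data/sites.csv data/traits.csv --out out/
urbanbees diversity data/records.csv data/sites.csv data/traits.csv --out out/
urbanbees alpha     data/records.csv data/sites.csv data/traits.csv --no-spatial --out out/alpha.csv
urbanbees beta      data/records.csv data/sites.csv data/traits.csv --metric impervious_pct --out out/beta/
urbanbees traits    data/records.csv data/sites.csv data/traits.csv --metric impervious_pct --out out/traits.csv
```

## Notes on statistical choices

* Continuous predictors enter models standardized; population density is
  `log(x+1)`-transformed first.
* The spatial random effect uses an exponential correlation
  `exp(-d/rho)` with the range profiled over a log-spaced grid.
* Mixed models use a Laplace approximation at the joint random-effect
  mode (penalized IRLS/Newton inner loop); the crossed-design trait
  GLMM exploits the complete sites × species layout for dense-block
  normal equations.
* The BH adjustment family is the eight informative trait tests (four
  main effects, four interactions) per metric model; `no_information`
  contrasts are estimated but not part of the family.
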