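# mireomics

Computational pipeline for genome-resolved multi-omic studies of
polyphenol-driven methane inhibition in peat microcosms.

Catechin amendment of anoxic peat can suppress methanogenesis: the microbes
that degrade catechin and its phenolic products consume molecular hydrogen,
starving hydrogenotrophic and H2-dependent methylotrophic methanogens.
`mireomics` implements the bespoke analysis stages needed to test this
hypothesis from metatranscriptome, annotation and metabolome data, plus a
synthetic-data generator with planted ground truth so the whole pipeline is
verifiable end-to-end without any external download.

## What is in the box

| Module | Purpose |
| --- | --- |
| `mireomics.normalize` | Low-count filtering (counts < 5 → 0), geTMM normalization (RPK × trimmed-mean-of-M-values scaling, per million), and the per-sample MAG activity filter (a genome needs ≥ 22 genes "on" to count as transcriptionally active in a sample) |
| `mireomics.response` | Six-way MAG response classification from cross-treatment expression presence: *resistant, responsive, sensitive, stimulated, lost_function, gained_function* |
| `mireomics.methanogens` | Rule-based methanogen substrate-potential and active-pathway calling (Mcr/Hdr confirmation; Wood-Ljungdahl + Mtr + hydrogenases; Methanosarcinia ACS/CODH + acetate genes; mtxB methyltransferases; Methanotrichales obligate-acetoclast override), built on a generic boolean rule engine usable for carbon-cycle role tables |
| `mireomics.hydrogenases` | HydDB-style directionality classes (H2-uptake / H2-evolving / bidirectional / bifurcating) for hydrogenase groups, per-class expression totals and ANOVA + Benjamini-Hochberg treatment contrasts |
| `mireomics.ledger` | Exact stoichiometric hydrogen ledger: element/charge balancing, route netting, cofactor recycling (PntAB, Rnf, [FeFe]-A3, [NiFe]-4e) and net H2 per substrate |
| `mireomics.msfilter` | LC-MS in-source fragment removal (RT binning at 0.005 s, Pearson r > 0.98, 5 ppm MS2 confirmation) and halogen-composition rejection |
| `mireomics.stats` | Gene / MAG / annotation-level abundance summaries, Bray-Curtis distances, cross-treatment distance sets, Kruskal-Wallis + Dunn + BH, and a sequential-term PERMANOVA (adonis2-equivalent, re-implemented) |
| `mireomics.simulate` | Synthetic counts, methanogen fixtures and LC-MS feature tables with planted truth |

## The hydrogen ledger in one paragraph

Anaerobic catechin (C15H14O6) degradation starts with oxidation to taxifolin
and then branches: dehydroxylations (2-electron reductions releasing H2O) and
the flavanone/flavanonol-cleaving reductase (FCR) consume NADH; chalcone
isomerase and hydrolytic cleavages are redox-neutral; the common A-ring
product phloroglucinol is fermented to acetate + butyrate at the cost of one
NADPH and two NADH while reducing one ferredoxin. Closing the books with the
NAD(P) transhydrogenase (PntAB), the Rnf complex (Fd_red + NAD+ → Fd_ox +
NADH), an electron-bifurcating [FeFe]-A3 hydrogenase (2 H2 + NAD+ + Fd_ox →
NADH + Fd_red) and a Fd-driven [NiFe]-4e hydrogenase (Fd_red → Fd_ox + H2)
yields the net hydrogen demand of each route. Every reaction is exactly
element- and charge-balanced (cofactor couples are tracked as balanced
moieties) and all arithmetic is rational, so these numbers are exact:

```
$ mireomics ledger --route all
naringenin	net H2 consumed per catechin: 3
eriodictyol	net H2 consumed per catechin: 2
dihydrokaempferol	net H2 consumed per catechin: 1
phloroglucinol	net H2 consumed per phloroglucinol: 2
methanogenesis_reference	net H2 consumed per co2: 4
```

Reading: a mole of catechin routed through naringenin soaks up 3 moles of H2
(2 via the eriodictyol route, 1 via dihydrokaempferol), versus the 4 H2
needed to make one CH4 hydrogenotrophically — catechin degradation is a
stoichiometrically competitive hydrogen sink.

## Worked example: plant categories, recover them

```
$ mireomics simulate --seed 7 --out demo/
wrote 9457 genes x 30 samples to demo
```

```python
from mireomics import io as mio, normalize as norm, response as resp

counts = mio.read_matrix("demo/counts.tsv")
catalog = mio.read_table("demo/catalog.tsv")
samples = mio.read_table("demo/samples.tsv")

expr = norm.getmm(counts, catalog)              # filter <5, RPK, TMM, per-million
expr, _ = norm.mag_on_filter(expr, catalog, 22) # silence inactive MAG-sample blocks
table, props = resp.classify_all(expr, catalog, samples)
print(table.head(3).to_string(index=False))
```

```
mag_id  day  n_both  n_unamended_only  n_catechin_only  pct_both  delta_unique   category
MAG000    0     142                30               24 72.448980      3.061224  resistant
MAG001    0      16                54               52 13.114754      1.639344 responsive
MAG002    0      19                84               37 13.571429     33.571429  sensitive
```

`MAG000` expresses 72% of its genes in both treatments with a 3-point
treatment asymmetry — *resistant*. `MAG002` shares only 14% and expresses a
34-point excess of genes only in unamended microcosms — *sensitive* (its
transcriptional repertoire collapses under catechin). Merging against the
generator's truth table shows 100% of planted categories recovered
(`recovered: 1.0`), and the per-day category proportions (`props`) are the
input for a stacked-bar view of community restructuring over time.

The other stages follow the same pattern; see `mireomics --help` for the
`methanogens`, `hydrogenases`, `msfilter`, `stats` and `ledger` subcommands.

## Limitations

Upstream steps (read QC, assembly, binning, annotation, read mapping,
hydrogenase HMM screening and phylogenetic placement, metabolite annotation)
are out of scope: the pipeline starts from count tables, annotation catalogs,
hydrogenase group labels and feature tables. See `docs/methods.md` for the
models, defaults and known limitations.
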