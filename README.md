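# spindex — spatial price indexes for medical services

`spindex` estimates how the price level of medical services differs across
regions that each publish their own fee schedule, as the four provincial
regions of China's Yangtze River Delta (Shanghai, Jiangsu, Zhejiang, Anhui)
do. It is a library for health economists and price statisticians: it
matches service items across regional schedules, estimates purchasing power
parities (PPPs) within basic headings, aggregates them with expenditure
weights into bilateral indexes, and produces transitive multilateral
price-level matrices, with CPI-based back-casting to earlier years and a
synthetic price-system generator for testing.

## The method

Services are partitioned into basic headings (here the four national
categories: general medical, medical diagnosis, clinical treatment,
traditional medicine). Within a heading, the PPP of region *j* with region
*k* as base is the Jevons index — the geometric mean of the matched
services' price ratios:

    PPP_jk = prod_i (P_ij / P_ik)^(1/N)

(equivalently, on a complete tableau, the exponentiated region effect of a
country-product-dummy regression of log prices on region and service
dummies). Heading PPPs are aggregated with expenditure weights W (shares of
medical-services spending per heading) into

* Laspeyres: arithmetic mean under the base region's weights,
* Paasche: harmonic mean under the compared region's weights,
* Fisher: their geometric mean, `F = sqrt(L * P)`.

The bilateral Fisher matrix is not transitive, so two multilateral methods
make it so:

* **GEKS** — `GEKS_jk = prod_i (F_ji * F_ik)^(1/M)`, the geometric mean over
  all bridge regions; the log-least-squares-closest transitive matrix.
* **MST** (Hill) — build the minimum spanning tree over regions weighted by
  the Paasche–Laspeyres spread `PLS = |log(L/P)|`, then chain Fisher links
  along tree paths; transitive because tree paths are unique.

All matrices follow the published-table convention: entry (row *j*,
column *k*) is region *j*'s price level with region *k* as base (×100).

## Worked example

`examples/01_published_comparison.py` re-derives the published Yangtze
River Delta comparison from the packaged bilateral Fisher matrix:

```
GEKS multilateral price levels (x100):
          Shanghai  Jiangsu  Zhejiang   Anhui
Shanghai    100.00   137.58    127.55  123.30
Jiangsu      72.68   100.00     92.71   89.62
Zhejiang     78.40   107.87    100.00   96.67
Anhui        81.10   111.59    103.45  100.00
```

Reading the Zhejiang column: medical services in Shanghai cost 127.55% of
the Zhejiang price level, Anhui 103.45%, while Jiangsu sits at 92.71%. The
MST method (tree Jiangsu–Shanghai, Shanghai–Zhejiang, Zhejiang–Anhui;
inferred, since the spread values behind the published tree are not printed)
gives 128.11, 102.20 and 93.80 — similar, but keeping tree-adjacent
bilateral Fisher links exact.

The other examples generate a synthetic four-region system with known true
multipliers and recover them through the full pipeline
(`02_synthetic_pipeline.py`), demonstrate the CPD/Jevons identity and its
breakdown on incomplete tableaus (`03_cpd_vs_jevons.py`), and back-cast a
2020 comparison to 2015 with CPI series (`04_backcast.py`).

A thin CLI wraps the same pipeline: `spindex simulate`, `spindex match`,
`spindex bilateral`, `spindex multilateral`, `spindex backcast` (all driven
by a YAML config), and `spindex benchmark`, which re-derives the published
tables from packaged fixtures alone.

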