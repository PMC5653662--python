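# gametecnv

Copy-number and parental-origin analysis for low-depth single-gamete and
single-kernel sequencing, built for studying chromosome fragmentation and
uniparental genome elimination in maize haploid-induction (HI) lines.

Pollen of Stock6-derived inducer lines triggers maternal haploids when
crossed onto regular maize. The mechanistic signal sits in single nuclei:
sperm and trophic (vegetative) nuclei of individual pollen grains,
microspores of tetrads, and the embryo/endosperm pair of individual
kernels, each sequenced at very low depth after whole-genome amplification
(WGA). This package provides the complete analysis chain for such data,
plus a simulator that plants known copy-number truths so every step can be
validated against an exact oracle.

## What it computes

**Uniform-depth variable bins.** WGA coverage bias is strong but largely
shared across samples. The genome is first cut into *n* fixed bins
(default 4000) to set a target pooled depth, then re-partitioned into
variable-length bins that each hold the same number of *pooled* reads
(MapQ ≥ 10) across all samples of a batch. Per sample and bin *b*, the
copy-number ratio is

    CNR_b = count_b / median_b'(count_b'),      log2(CNR_b) ≈ 0 when euploid,

so a bin at half the baseline copy number sits near log2(CNR) = −1 and a
doubled bin near +1.

**Ploidy segmentation.** Each bin is assigned the integer copy state *c*
minimizing |log2(CNR) − log2(c/baseline)| (copy 0 uses the zero-count
pseudocount floor); runs of equal states become segments; segments shorter
than a minimum span (10 Mb at full genome scale, scaled by genome size)
or with mean log2(CNR) inside a ±0.35 no-call band are absorbed.

**Sperm-pair CNV types.** Joint states of the two sperm of one pollen on
an interval: loss with complementary gain (0/2) = type I, loss in one only
(0/1) = type II, loss in both (0/0) = type III — interpreted as
fragmentation around, after the 2nd, and after the 1st pollen mitosis
respectively. Cohort tables count pollens with one (AP1S) or two (AP2S)
aneuploid sperm, total aneuploid pollens (TP) and sperm (ASS/TS), and
compare groups with a Pearson chi-square (no continuity correction).

**SNP ratio and RGR.** For hybrid embryo (1 maternal : 1 paternal genome)
and endosperm (2 : 1), parent-informative SNPs are pooled into bins of 700
adjacent SNPs and the maternal-allele read fraction computed per bin
(≈ 0.5 euploid embryo, ≈ 2/3 endosperm). The relative genotype ratio

    RGR_{b,s} = ratio_{b,s} / mean_s'(ratio_{b,s'}),   log2-transformed,

cancels shared artifacts: log2(RGR) > 0 marks paternal loss, < 0 maternal
loss. Combined with CNV segmentation this yields kernel classes: class I
(genome-wide paternal elimination, complete or with retained fragments)
and class II (local fragment loss from either parent).

## Worked example

```python
import gametecnv as g

# simulate a small inducer-line cohort: 4 pollens (3 nuclei each),
# one with a single aneuploid sperm, one with two
cfg = {"lines": [{"name": "CAU5", "group": "inducer", "n_pollen": 4,
                  "nuclei_per_pollen": 3,
                  "one_aneuploid": 1, "two_aneuploid": 1}],
       "reads_per_nucleus": 100_000}
genome, samples, placements, truths = g.simulate_pollen_cohort(cfg, seed=5)

res = g.run_pollen_pipeline(genome, samples, placements, n_fixed_bins=400)
for pc in res.pollen_calls:
    print(pc.pollen_id, pc.category,
          [(e.chrom, e.state1, e.state2, e.cnv_type)
           for e in pc.typed_events])
print(res.summary.to_string(index=False))
```

prints

```
CAU5_pollen001 euploid []
CAU5_pollen002 euploid []
CAU5_pollen003 two_aneuploid_sperm [('chr5', 0, 0, 'III')]
CAU5_pollen004 one_aneuploid_sperm [('chr3', 0, 1, 'II')]
          line   group  ap1s_n  ap2s_n  tp_n  pollens  ass_n  sperms
          CAU5 inducer       1       1     2        4      3       8
pooled_inducer inducer       1       1     2        4      3       8
```

The planted type III event (a loss in both sperm of pollen 3, joint state
0/0) and the type II event (a loss in one sperm of pollen 4, joint state
0/1) are recovered, and the cohort table counts 1 pollen with one
aneuploid sperm and 1 with two among the 4 sequenced (3 aneuploid sperm
of 8).

A chi-square on two aneuploidy rates (e.g. 3/50 vs 14/52 aneuploid sperm):

```bash
$ gametecnv test 3 50 14 52
{"statistic": 8.0345, "p": 0.004589565160436365, "df": 1}
```

## Command-line interface

`gametecnv` exposes thin subcommands over the library: `simulate`
(write a synthetic cohort), `validate` (check a dataset directory),
`bins`, `cnr`, `segment`, `pollen`, `test` and `kernel`. All file formats
are plain text (BED5 placements, BED3 bins + TSV sidecars, minimal VCF or
TSV SNP panels, TSV reports); every interval is 0-based half-open.

See `docs/methods.md` for the model, parameter defaults and limitations.
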