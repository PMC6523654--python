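# centrotime

Replication-timing inference from sorted-fraction (G1/S) whole-genome
sequencing, built to keep **centromeres** in the analysis.

## The problem

DNA replication timing (RT) can be measured without synchronization or label
incorporation by flow-sorting an asynchronous culture into a G1 (pre-replicative)
and an S (replicating) fraction and sequencing both: early-replicating loci are
over-represented in the S fraction (approaching 2x copies), late ones stay near
1x, and the G1 fraction provides a uniform-copy baseline that absorbs
mappability and copy-number bias. Centromeres — megabase-scale α-satellite
repeat arrays — are usually discarded by this kind of analysis: their
repetitiveness collapses alignments onto shared coordinates, so standard
single-end duplicate marking throws away the genuine reads and coverage filters
finish the job. With paired-end data, a mate coordinate distinguishes a true
repeat-derived fragment from a PCR/optical duplicate, which makes centromeric
RT measurable.

`centrotime` implements the full inference recipe plus the centromere-specific
analyses, and ships a ground-truth read simulator so every stage is testable
without any sequencing data.

## The method

For usable fragments (duplicates marked in paired or single-end mode; MAPQ
filter; 100 Kb bins above the 99th coverage percentile and 500 Kb bins below
the 0.5th percentile excluded):

1. **Windows** — G1 reads define sliding windows of equal read depth
   (200 reads, advancing by 100, so 10 consecutive windows span 1100 distinct
   reads). Window width adapts to mappability.
2. **Raw profile** — per window, the S/G1 read-count ratio, scaled to mean 1.
3. **Outlier filter** — a penalized piecewise-constant changepoint fit per
   contiguous segment (noise variance fixed at 0.04); windows deviating more
   than 3σ from their piece mean are dropped.
4. **Smoothing** — a cubic smoothing spline per segment, minimizing
   `p·Σ(yᵢ−f(xᵢ))² + (1−p)·∫f″(x)²dx` with fidelity weight `p = 1e-16` and
   x in bp.
5. **Normalization** — z-scored so autosomal windows have mean 0, SD 1.

Downstream: centromere inclusion (≥ 10 G1 windows/Mb on average), 100-bin
centromere aggregation with a cross-centromere mean and min/max envelope,
pericentromere-anchored overlays, cross-sample Pearson correlations per
chromosome and per centromere, and two matched null controls (size-matched
random regions; window-count-matched runs) with a two-sample KS test.

## Worked example

```bash
python examples/01_simulate_and_profile.py
```

```
windows built:        8904
normalized windows:   8904
autosomal mean:       +9.26e-16   (target 0)
autosomal SD:         1.000000     (target 1)
recovery vs truth r = 0.9959
```

The simulator draws a smooth timing landscape on a 2 × 10 Mb toy genome
(repeat-array centromeres, 85% of centromeric reads at low MAPQ, injected
PCR/optical duplicates) and 1M fragments per fraction; the pipeline rebuilds
the landscape from read depth alone. `r` is the Pearson correlation between
the inferred normalized profile and the standardized ground-truth replicated
fraction — 0.996 here means essentially complete recovery. The other examples
show the single- vs paired-end duplicate contrast on a synthetic centromere
(`02`), inclusion/aggregation/overlays (`03`), and cross-sample correlation
statistics with a matched null (`04`).

A thin CLI wraps the same library:

```bash
centrotime simulate --seed 1 --out sim/
centrotime profile --g1 sim/g1.bedpe --s sim/s.bedpe \
    --chrom-sizes sim/genome.chrom.sizes --centromeres sim/centromeres.bed \
    --out prof/
centrotime centromeres --profile prof/profile.stages.tsv \
    --windows prof/windows.tsv --chrom-sizes sim/genome.chrom.sizes \
    --centromeres sim/centromeres.bed --out cen/
```

Formats are plain text throughout: BEDPE/BED6 for reads, BED and chrom.sizes
for the genome, bedGraph and TSV for profiles, JSON manifests for provenance.

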