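# rtprofiler

Replication-timing (RT) profiling from S/G1 whole-genome sequencing, plus the
downstream statistics used to characterize replication dynamics in repetitive
and centromeric regions:

- **Uniform-G1-coverage binning** — variable-size genomic bins each holding
  exactly 200 G1-phase read starts (configurable), so mappability, GC and
  copy-number variation cancel out of the S/G1 ratio.
- **Cubic smoothing spline** (csaps convention, smoothing parameter `1e-16`
  with x in bp) applied per gap-free segment, then z-normalization to an
  autosomal mean of 0 and SD of 1 (chrX scaled with autosomal parameters,
  chrY dropped).
- **Replication dynamics** — peak/valley calling with prominence filtering,
  inter-peak distances (inter-origin distance proxy) and averaged
  ascending/descending peak slopes (fork-speed proxy), overall and within
  region sets such as centromeres or HOR arrays.
- **Satellite family RT bias** — assignment of profile bins to cenSat-dialect
  annotation families (hor, dhor, mon, hsat1-3, bsat, ct, ...), per-family
  median/IQR/early-fraction statistics, and early-bin composition of newly
  resolved regions.
- **Cross-assembly comparison** — UCSC chain parsing, fixed-window coordinate
  mapping with a best-chain/min-match rule, and Pearson correlation of RT
  profiles between genome builds.
- **Centromere comparison across samples** — relative-position profiles
  (100 interior bins per region + fixed-width flanks) and per-chromosome
  earliest-to-latest sample rankings.
- **Synthetic data generator** — G1/S read sets drawn from an explicit
  replication-kinetics landscape (origin positions, firing times, constant
  fork speed; S cells sampled uniformly through S phase so expected copy
  number is `c(x) = 2 − τ(x)`), with optional bias curves and assembly gaps.
  Every downstream stage is validated against this ground truth.

## CLI

All coordinates are 0-based half-open (BED-native); profiles interchange as
bedGraph.

```bash
# simulate ground-truth G1/S reads (writes g1.bed, s.bed, chrom.sizes,
# tau/copy-number bedGraphs and a landscape JSON sidecar)
rtprofiler simulate --config sim.yaml --out simdir --seed 1

# reads -> uniform-G1-coverage bins with S/G1 ratios
rtprofiler bin --g1 g1.bed --s s.bed --genome chrom.sizes \
    --reads-per-bin 200 --out bins.tsv

# smooth + normalize -> RT bedGraph
rtprofiler profile --bins bins.tsv --p 1e-16 --max-gap 100000 \
    --out profile.bedGraph

# or both stages at once
rtprofiler pipeline --g1 g1.bed --s s.bed --genome chrom.sizes \
    --out profile.bedGraph

# peaks, inter-peak distances, slopes (optionally split by a region BED)
rtprofiler dynamics --profile profile.bedGraph --regions cen.bed --out dyn.json

# per-satellite-family RT statistics
rtprofiler satstats --profile profile.bedGraph --censat censat.bed \
    --baseline noncen.bed --out satstats.json

# cross-assembly window mapping + profile correlation
rtprofiler liftcompare --profile-a a.bedGraph --profile-b b.bedGraph \
    --chain x.over.chain --genome a.chrom.sizes --out compare.json

# relative centromere profiles + per-chromosome sample ranking
rtprofiler cenrank --profiles a.bedGraph --profiles b.bedGraph \
    --regions cen.bed --out cen.json
```

A minimal `sim.yaml`:

```yaml
n_chromosomes: 2
chrom_length: 5000000
n_origins: 4
n_reads_g1: 100000
n_reads_s: 100000
```

or with explicit landscapes:

```yaml
chromosomes:
  chr1:
    chrom_length: 5000000
    fork_speed: 4000000
    origins: [[1000000, 0.1], [3500000, 0.25]]
    gaps: [[2000000, 2100000]]
n_reads_g1: 100000
n_reads_s: 100000
```

## Package layout

| module | contents |
| --- | --- |
| `rtprofiler.synthetic` | landscapes, timing/copy-number curves, read sampling |
| `rtprofiler.io` | BED/bedGraph/chrom.sizes/cenSat readers and writers |
| `rtprofiler.binning` | uniform-G1-coverage bins, S counting, S/G1 ratios |
| `rtprofiler.profile` | segmentation, smoothing spline, normalization |
| `rtprofiler.dynamics` | extrema calling, inter-peak distances, slopes |
| `rtprofiler.satellite` | family assignment and RT-bias statistics |
| `rtprofiler.chains` | chain parsing, window mapping, profile correlation |
| `rtprofiler.cenrank` | relative centromere profiles, sample rankings |
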