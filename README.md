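# readscrub

De novo "scrubbing" of long noisy sequencing reads: detecting and removing
low-quality segments *inside* reads (as opposed to trimming their ends) and
splitting the reads at the removals. Errors in nanopore-style long reads —
5–40% per read, dominated by indels — tend to cluster into junk segments and
artifactual chimeric junctions, which propagate into mis-assemblies and
large indel errors downstream. readscrub targets users preprocessing long
reads for de novo assembly or error correction, especially in metagenome
settings where reference genomes are unavailable.

## Method

1. **Overlap.** All-vs-all read overlaps are found from shared co-linear
   (w,k)-minimizers (defaults w=5, k=15): the minimum-order k-mer of every
   window of w consecutive k-mers. Two reads sharing w+k−1 identical bases
   are guaranteed to share a minimizer there, so shared minimizers compress
   how well reads support each other without base-level alignment.
2. **Encode.** Each read in turn is a *reference read*; its overlapping
   *matching reads* form a pile that is encoded as an RGB image with one
   column per reference-read minimizer and one row per read (row 0 = the
   reference; 24 rows total, sampling the pile when it is deeper). Per
   pixel: **red** 255 if that row's read shares the column's minimizer,
   70 if it is inside the matched span without it, 0 outside the match;
   **green** = 2 × the mean Phred+33 quality character over the pixel's
   base interval (range 66–254); **blue** = base distance to the next
   minimizer (clamped at 255) — disagreement between rows in blue marks
   likely indels.
3. **Regress.** Images are cut into 48-minimizer segments and a
   convolutional network (a VGG16-style 13-convolution regressor, or a
   small 3-convolution variant for CPU-scale runs) maps each segment to its
   *percent identity* — the fraction of its read bases that match the true
   sequence — trained with Adam on mean squared error.
4. **Scrub.** Segments predicted below a threshold (default 0.8) are
   removed, reads are split at the removals, and fragments shorter than
   500 bases are dropped; output is a new FASTQ.

Training labels come either from read-to-reference alignments (SAM/PAF,
identity = matched read bases / read bases per segment) or from the bundled
long-read simulator, which provides per-base ground truth for reads with
clustered junk segments, indel-dominant errors, and chimeras.

## Worked example

The whole pipeline runs file-to-file from the CLI:

```sh
readscrub simulate --genome-length 20000 --coverage 6 --seed 42 --outdir demo
readscrub overlap  --reads demo/reads.fastq --out demo/overlaps.tsv
readscrub pileup   --reads demo/reads.fastq --overlaps demo/overlaps.tsv --out demo/segments.h5
readscrub label    --segments demo/segments.h5 --truth demo/truth.tsv --out demo/labels.tsv
readscrub train    --segments demo/segments.h5 --labels demo/labels.tsv --epochs 5 --out demo/model.npz
readscrub predict  --segments demo/segments.h5 --model demo/model.npz --out demo/predictions.tsv
readscrub scrub    --reads demo/reads.fastq --predictions demo/predictions.tsv \
                   --out demo/scrubbed.fastq --stats demo/stats.json
readscrub evaluate --predictions demo/predictions.tsv --labels demo/labels.tsv --out demo/report.json
```

The stages log their record counts as they run; on this 20 kb / 6× toy run:

```
readscrub INFO simulate: 52 reads, 1 genomes
readscrub INFO overlap: 52 piles, 198 overlaps
readscrub INFO pileup: 872 segments from 52 reads
readscrub INFO train: loss history [0.00186, 0.00182, 0.00177, 0.00178, 0.00175]
readscrub INFO scrub: 50/52 reads kept, 805 bases removed
```

so 52 simulated reads yielded 872 pileup segments, the per-epoch training
loss fell over 5 epochs, and scrubbing removed 805 bases (reads are split
at removed segments; fragments under 500 bases are dropped).
`demo/report.json` holds the prediction quality on the same data — mean
squared error (here 0.0019), Pearson/Spearman correlation between predicted
and true segment identity, and sensitivity/specificity of retaining
truly-above-0.8 segments at the 0.8 cutoff. A 6× toy run is too shallow for
the correlations to be impressive (0.27/0.29 here); the held-out evaluation
in `tests/test_acceptance.py` runs the intended 30× depth, where Spearman
exceeds 0.5 and sensitivity 0.99. Library users can drive the same stages
in memory via `readscrub.pipeline`.

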