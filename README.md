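# gazesal

Gaze-contingent analysis of surveillance-style video: what visual content
do two groups of viewers place their gaze on, and can the groups be told
apart from it?

The package provides an end-to-end, fully synthetic-testable pipeline:

- **`gazesal.synth`** — synthetic stimulus clips (four action categories:
  fight / confrontation / playful / neutral; moving agent blobs plus
  colored distractors), two-group gaze traces with a controllable
  between-group strategy gap and within-group consistency, and
  signal-detection-model ratings on a 1–6 scale.
- **`gazesal.patches`** — gaze-centered square patch extraction
  (default 75×75 px; missing-gaze frames become zero patches) and
  frame downsampling (1-in-10 for the embedding stream).
- **`gazesal.saliency`** — a six-channel spatiotemporal saliency model:
  luminance / red–green / yellow–blue (cone-opponent space), orientation
  (Gabor bank), texture (LoG bank), optical-flow magnitude
  (structure-tensor dense flow); 4-level Gaussian pyramids, five passes
  of center-surround activation, per-channel normalization factors
  blended through a 3-frame 0.5-decay temporal buffer, and a logistic-
  squashed final saliency map with a gaze-region saliency index. The six
  blended normalization factors per frame are the exported channel
  features.
- **`gazesal.embed`** — pluggable patch embeddings (default: a
  deterministic seeded random projection, 4096-D; a CNN penultimate-layer
  backend hook raises a capability error when torch is absent).
- **`gazesal.decode`** — elastic-net-penalized logistic group decoding in
  a leave-one-participant-out loop over cumulative temporal windows
  (step 50 frames for saliency, 5 for embeddings), max-over-windows
  summarization, per-category t-tests vs chance with Bonferroni
  adjustment, a channel-shuffling permutation test, channel selection
  proportions, per-participant fight-vs-rest decoding in 4-s chunks,
  stream combination, and behavior correlations.
- **`gazesal.isc`** — within-group inter-subject correlation of
  time-concatenated feature vectors (pooled per-channel z-scoring),
  time-resolved 2-s-chunk ISC, and individual-vs-group-mean inter-group
  correlations (leave-self-out).
- **`gazesal.behavior`** — signal-detection scoring of ratings
  (hit = fight rated ≥ 4), d′ and criterion C with log-linear correction.

## CLI

```bash
# synthetic dataset: 36 clips, 11 + 10 participants, gaze + ratings
gazesal synth make --n-per-category 9 --operators 11 --novices 10 --seed 1 --out data/

# feature tensors per clip
gazesal features compute --stream saliency --in data/ --out feats/
gazesal features compute --stream embed --embed-dim 4096 --in data/ --out feats/

# leave-one-out group decoding with cumulative windows
gazesal decode group --stream saliency --step 50 --alpha 1.0 --seed 1 \
    --in feats/ --out results.json

# inter-subject correlation tables (per clip, per 2-s chunk, inter-group)
gazesal isc run --stream saliency --chunk-seconds 2 --in feats/ --out isc.csv

# signal-detection scores from ratings
gazesal behavior score --ratings data/ratings.csv --out sdt.csv
```

Note: at the full default geometry (576×480 px, 16 s, 25 fps, 36 clips,
21 participants) the dataset and saliency pass are large; for
experimentation pass `--width/--height/--duration/--fps` and a smaller
`--window`.

## Conventions

Coordinates are 0-based with `x` = column, `y` = row, origin top-left;
gaze is rounded to the nearest pixel, patches are half-open crops
`[c − w//2, c − w//2 + w)` zero-padded at frame borders. RGB is assumed
sRGB in [0, 1] and linearized before the cone-response matrix
(Hunt–Pointer–Estevez). Z-scoring for ISC uses the population-sd
convention. All generators and analyses are deterministic given their
seeds.
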