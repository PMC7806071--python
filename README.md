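# dyadsync

Unsupervised measurement of interpersonal synchrony in dyadic conversations
from frame-level speech features, with complementary lexical similarity
measures. Intended for researchers in computational paralinguistics and
behavioral signal processing who want a corpus-independent, annotation-free
estimate of whether two conversation partners' vocal behavior converges
over an interaction.

## The method

For each dyadic recording, the frame stream (10 ms frames of acoustic
low-level descriptors, optionally delta-augmented 65 → 130 dims, or
high-dimensional spectrogram-embedding vectors) is standardized per
recording, split into the two speakers' subsequences using the
time-stamped transcript, and each speaker's frames train a bottleneck
autoencoder (e.g. 130–64–32–12–32–64–130; MSE loss, Adagrad, lr 0.01,
batch 256, 512 epochs). Each trained model then reconstructs the
*partner's* frames in temporal order, giving a per-frame reconstruction
error trace

&nbsp;&nbsp;&nbsp;&nbsp;RMSE_i = sqrt( (1/d) · Σ_j (x_ij − x̂_ij)² )

The autoencoder acts as a one-class model of its speaker's feature
distribution, so the trace is a novelty score of the partner's behavior
over time. The synchrony statistic is the OLS slope of RMSE against
session-normalized time t ∈ [0, 1]: a negative slope means the partner's
frames become easier to reconstruct, i.e. the partners' acoustic
distributions converge. Per group (e.g. culture), results aggregate as the
mean slope *s* over all subjects and the Pearson correlation (PCC) of the
two partners' slopes across sessions — positive PCC: partners co-vary;
negative: one partner dominates the adaptation.

Lexical entrainment is measured on conversation halves: a shared-vocabulary
word-usage score S = Σ_{w used by both} (c_A(w)+c_B(w)) / ((N_A+N_B)/2),
ranging over [0, 2], and the cosine similarity of the speakers' mean
word2vec embeddings per half.

Because suitable dyadic corpora are access-restricted, the package includes
a first-class generator of synthetic dyads whose feature distributions
converge at a controllable rate κ and whose transcripts have controllable
per-half vocabulary overlap, so the whole pipeline is testable end to end.

## Worked example

```python
from dyadsync import (DyadGeneratorConfig, RunConfig, TrainingConfig,
                      generate_corpus, run_acoustic_pipeline, run_linguistic_pipeline)

cfgs = {"converging": DyadGeneratorConfig(convergence_rate=0.8),
        "static":     DyadGeneratorConfig(convergence_rate=0.0)}
generate_corpus(3, cfgs, seed=42, out_dir="demo_corpus")

cfg = RunConfig(manifest_path="demo_corpus/manifest.tsv", output_dir="demo_out",
                training=TrainingConfig(epochs=64), seed=42)
run_acoustic_pipeline(cfg)
print(open("demo_out/group_report.tsv").read())
```

```
feature_set	statistic	converging	static
synthetic	average_slope	-0.4865	0.0078
synthetic	pcc_of_pairs	0.0469	-0.8741
synthetic	n_sessions	3	3
```

The converging group's mean slope is clearly negative (−0.49 RMSE per unit
session time: partner frames reconstruct much better by session end), while
the static control group sits near zero (+0.01). Per-subject slopes are in
`demo_out/session_slopes.tsv`; in the converging group the drifting
speaker's slope is strongly negative (≈ −1.0) while the stationary
speaker's is near zero, which also drives the group PCCs. The linguistic
pipeline over the same corpus,

```python
run_linguistic_pipeline(RunConfig(manifest_path="demo_corpus/manifest.tsv",
                                  output_dir="demo_lg", seed=42))
```

```
group	usage_half1	usage_half2	embedding_half1	embedding_half2	n_sessions
converging	0.0185	0.8704	—	—	3
static	0.0185	0.4167	—	—	3
```

shows word-usage similarity rising from the first to the second half, as
generated (per-half shared-vocabulary rates 0.2 → 0.8); embedding columns
are em dashes because no lexicon was supplied (pass `lexicon_path=` with a
word2vec text-format file to fill them).

The same pipelines are available from the shell:

```
dyadsync generate --out-dir corpus --n-sessions 3 --group converging:0.8 --group static:0.0 --seed 42
dyadsync acoustic --manifest corpus/manifest.tsv --out-dir out --epochs 64 --seed 42
dyadsync linguistic --manifest corpus/manifest.tsv --out-dir lg
```

Every output directory contains the resolved `config.yaml` (all seeds
included) and a run log; a rerun with the same config and seed reproduces
the reports byte-identically.

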