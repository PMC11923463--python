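# drugpulse

Mine drug discourse from short-text social-media corpora. The pipeline
covers five stages over timestamped short texts (tweets or similar):

1. **Preprocessing** (`drugpulse.corpus_io`) — JSONL/CSV corpus reading
   with validation, URL-tweet exclusion, `@handle` masking (with a public-
   figure allowlist), and anchor-aligned 7-day weekly binning over a
   configurable study window (default 2020-02-01 through 2022-04-30).
2. **Entity extraction** (`drugpulse.entities`) — lexicon-based drug and
   symptom mention extraction with colloquial-variant normalization
   (case-insensitive, word-boundary, longest-match-first), a hook for
   external model taggers, per-class mention-frequency thresholds
   (drugs > 1000, symptoms > 250 by default), and a Yates-corrected
   chi-square harness for comparing extraction methods.
3. **Targeted sentiment** (`drugpulse.sentiment`) — pluggable scorers over
   the `"<tweet> [SEP] <entity>"` contract, a deterministic valence-lexicon
   baseline, per-entity sentiment distributions, and weekly mention /
   polarity-ratio time series.
4. **Topic modeling** (`drugpulse.lda`) — own collapsed-Gibbs LDA (numba-
   accelerated when available, identical results without it), collocation
   (bigram) merging, held-out perplexity via fold-in, UMass coherence, and
   topic-count selection combining both.
5. **Co-occurrence networks** (`drugpulse.network`) — binary entity×tweet
   incidence matrices, cosine-similarity edges with strict `tau`
   thresholding (defaults 0.005 drug–drug, 0.05 drug–symptom), own Louvain
   community detection with an independent modularity function, ATC
   annotation with ARI/NMI agreement, and GEXF/GraphML/CSV export loadable
   by Gephi.

A seeded synthetic-corpus generator (`drugpulse.synthetic`) plants entity
mentions, topic mixtures, sentiment cues, block-structured co-mention
probabilities, and weekly volume curves with full ground truth, so every
stage is testable without external data.

## CLI

Each stage runs standalone; `run` executes everything from one YAML config:

```bash
drugpulse simulate   --config sim.yaml --out corpus.jsonl --truth truth.json
drugpulse preprocess --in corpus.jsonl --out kept.jsonl --window 2020-02-01:2022-04-30
drugpulse extract    --in kept.jsonl --lexicon lex.csv --out mentions.jsonl \
                     --min-drug 1000 --min-symptom 250
drugpulse sentiment  --mentions mentions.jsonl --corpus kept.jsonl --out scored.jsonl
drugpulse trends     --mentions mentions.jsonl --corpus kept.jsonl --drug zinc --out zinc.csv
drugpulse topics     --in kept.jsonl --k-grid 5,10,15,20 --seed 13 --out topics/
drugpulse network    --mentions mentions.jsonl --corpus kept.jsonl \
                     --mode drug-drug --tau 0.005 --louvain --atc lex.csv --out net.gexf
drugpulse run        --config pipeline.yaml
```

The lexicon CSV has columns `surface,canonical,class,atc` (UTF-8, header
required). `run` writes a deterministic `report.json` auditing attrition at
every stage; two runs with the same config and seed are byte-identical.

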