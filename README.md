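# gsnamer

Toolkit for interpreting gene sets with large language models and for
evaluating how trustworthy those interpretations are.

Given a gene set, an LLM backend is prompted (seven-section engineered
prompt, one-shot example, deterministic decoding settings) to propose a
short biological-process name, a supporting analysis essay and a
self-confidence score in [0, 1] — with the sentinel *"System of unrelated
proteins"* at confidence 0.00 when no coherent function exists. The
toolkit then evaluates such proposals:

- **`gsnamer.ontology`** — OBO parsing, GAF/TSV annotation loading,
  per-term gene aggregation over `is_a`/`part_of` descendants, seeded
  sampling of terms by aggregated gene-set size (default band 3–100).
- **`gsnamer.geneset_io`** — GMT read/write, plain gene lists, score-table
  thresholding, size filtering.
- **`gsnamer.llm_interface`** — prompt assembly, pluggable LLM backends
  with disk caching and bounded retries, response parsing into
  name/confidence/paragraphs.
- **`gsnamer.similarity`** — embedding-based cosine similarity between
  names, percentile calibration against the full branch name corpus
  (percentile = % of corpus names strictly less similar), and
  classification of outcomes as recovered / generalized / other /
  not_named. A real biomedical embedder (`SapBertEmbedder`, optional
  `torch`+`transformers` extra) and a deterministic hash-bag mock are
  provided.
- **`gsnamer.enrichment`** — native over-representation baseline:
  upper-tail hypergeometric test, Benjamini–Hochberg correction, Jaccard
  effect size, and the annotation decision (adjusted p ≤ 0.05 and best
  JI ≥ 0.1 by default).
- **`gsnamer.benchmark`** — contaminated-set confidence probes: real /
  50-50 mix / fully random gene sets of matched size, confidence binning
  (high ≥ 0.87, medium 0.80–0.86, low 0.01–0.79, not assigned = 0),
  contingency tables, chi-squared and Mann–Whitney comparisons.
- **`gsnamer.citations`** — five-step citation pipeline: keyword
  extraction per essay paragraph, PubMed query assembly, relevance-sorted
  retrieval, re-ranking by gene mentions in abstracts, and LLM support
  verdicts; only verdict-supported publications are attached.
- **`gsnamer.fixtures`** — seeded toy ontologies, scripted LLM backends,
  a hash embedder and a canned PubMed client so the entire pipeline runs
  deterministically offline.

## CLI

```bash
# deterministic fixture files (toy OBO + annotation TSV)
gsnamer fixtures make --out fixtures/ --n-terms 12 --seed 7

# name gene sets from a GMT with a scripted (or live) backend
gsnamer annotate --gmt sets.gmt --script script.json --out records.jsonl

# sample ontology terms, name, calibrate and classify
gsnamer eval-go --obo go.obo --annotations goa.gaf --script script.json \
    --out-dir eval/ --n 100 --seed 42

# real / 50-50 mix / random confidence benchmark
gsnamer bench --obo go.obo --annotations goa.gaf --out-dir bench/ --n 100 --seed 42

# enrichment baseline
gsnamer enrich --query-gmt query.gmt --library-gmt library.gmt --out enrich.tsv

# citation pipeline on canned fixtures
gsnamer cite --essay essay.json --records records.json --rules rules.json --out cited.json
```

Live backends (`--backend openai`, `--embedder sapbert`, the Entrez
PubMed client) need the corresponding optional extras and credentials via
environment variables interpolated from a YAML config (`--config`,
`${ENV_VAR}` syntax). Defaults: temperature 0.0, seed 42, max_tokens
1000, alpha 0.05, min JI 0.1, percentile threshold 95, size band 3–100.

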