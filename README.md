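# metaret

Retrieval over two-field dataset metadata (title + description), built for
biomedical dataset search. The package combines:

- a native **two-field positional inverted index** with Dirichlet-smoothed
  language-model statistics (`metaret.indexer`),
- **TFIDF**, **query-likelihood**, **MRF** (term-dependence) and
  **POS-weighted MRF** ranking models (`metaret.ranking`) — the POS-MRF
  weights each query term's clique contributions by a per-POS-class
  constant (NN 0.5970, NNS 0.2265, VBN 0.3065, VBD 0.2260, JJ 0.3730,
  RB 0.1040, NNP 0.8930, 0.0 otherwise) with clique-type weights
  θ = (0.8, 0.1, 0.1) for unigram/ordered/unordered cliques,
- **skip-gram (SGNS) query expansion** trained locally on the corpus
  (dim 100; each extracted medical entity word contributes its five
  cosine-nearest neighbors at weight 0.1, originals at 0.9)
  (`metaret.expansion`),
- **dictionary-based medical entity extraction** with surface
  normalization ("bone morphogenetic protein-2" → "bone morphogenetic
  protein 2"), acronym detection, and priority-based merging with external
  annotation files (`metaret.entities`),
- **entity-overlap re-ranking** of the top 10 000 retrieved documents:
  s′ = s_max · n_D + s_D, returning the top 1000 (`metaret.rerank`),
- classical and **inferred evaluation metrics**: MAP, P@10(±partial),
  NDCG@10, infAP, infNDCG over plain or stratified-sampled qrels
  (`metaret.metrics`),
- a **synthetic collection generator** with planted topics, synonym
  families, entities and graded relevance so everything above is testable
  offline (`metaret.synthetic`), and
- a **pipeline** wiring the twelve standard system configurations
  (3 models × ±expansion × ±re-ranking) (`metaret.pipeline`).

## CLI

All commands are subcommands of `metaret`:

```bash
# generate an offline benchmark collection
metaret generate-synthetic --seed 7 --out corpus/

# build the two-field index from dataset metadata JSON
metaret index --input corpus/docs.jsonl --out idx/ \
    --fieldmap doc_id=_id,title=metadata.title,description=metadata.description

# retrieve (TREC run output)
metaret search --index-dir idx/ --queries corpus/queries.tsv \
    --model posmrf --k 10000 --mu 2500 --theta 0.8,0.1,0.1 --out base.run

# train expansion embeddings (word2vec text format)
metaret train-embeddings --input corpus/docs.jsonl --dim 100 --seed 1 \
    --out vectors.txt

# extract normalized entity mentions
metaret extract-entities --input corpus/docs.jsonl \
    --dict corpus/dictionary.tsv --out docs.mentions.tsv

# entity-overlap re-ranking
metaret rerank --run base.run --mentions docs.mentions.tsv \
    --query-mentions query.mentions.tsv --k 1000 --out final.run

# evaluation (six metrics, TSV per query + mean)
metaret evaluate --run final.run --qrels corpus/qrels.txt --stratified

# run configured end-to-end systems from YAML
metaret run --config system.yaml
```

`system.yaml` example:

```yaml
corpus_dir: corpus
out_dir: runs
embed_seed: 1
all: true            # or: systems: [{model: posmrf, use_expansion: true, use_rerank: true}]
```

## File formats

- dataset metadata: JSON lines (or JSON array / directory of JSON files)
  with configurable dot-delimited field paths;
- queries: `query_id<TAB>text`;
- qrels: TREC 4-column `qid stratum docid grade` with grades 0/1/2; a
  sampled-qrels sidecar `<qrels>.meta.json` records per-stratum pool and
  sample sizes for the inferred metrics;
- runs: TREC format `qid Q0 docid rank score tag` (ties broken by doc id,
  scores printed with 6 decimals);
- entity dictionaries: TSV `surface  entity_id  semantic_type  source`;
- annotations/mentions: TSV `unit_id  start  end  surface  entity_id
  semantic_type  source` (0-based half-open spans on raw text).

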