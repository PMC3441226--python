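# hgca — gene coexpression analysis

`hgca` builds coexpression neighborhoods of a driver probe set from a
probe-set × sample expression matrix and turns them into functional
hypotheses:

1. **preprocess** — intensity-range QC (0–65535), hash-signature duplicate
   removal (MD5+SHA-1+CRC32), tissue/series-balanced sample selection,
   AFFX control exclusion, and per-sample trimmed-mean scaling (2% per tail,
   target 500) with half-unit rounding.
2. **coexpression** — all-against-all Pearson correlation with the
   t-statistic significance chain (`t = r·√(n−2)/√(1−r²)`, two-sided
   Student-t p, Bonferroni-corrected e-value capped at 1).
3. **treecluster** — `D = 1 − r` distances, canonical Saitou–Nei
   neighbour joining (deterministic tie-breaking, trifurcating root,
   optional midpoint rooting), Phylip/Newick I/O, and height-adjustable
   clade neighborhoods around a query leaf.
4. **enrichment** — hypergeometric upper-tail over-representation of
   annotation terms (free text tokenized, structured vocabularies matched
   whole) with Benjamini–Hochberg correction and a 0.05 trim.
5. **pwm_scan** — promoter scanning with position weight matrices using
   information-weighted, min-max-normalized core/matrix similarity scores
   (defaults CSS ≥ 0.95, MSS ≥ 0.90; 500 bp upstream promoter windows).
6. **fixtures** — deterministic synthetic data with recorded ground truth:
   planted coexpression modules, planted enriched terms, planted duplicate
   samples, planted motif sites.

## CLI

Every stage is a subcommand of `hgca`; `hgca <cmd> --help` documents each.

```sh
# synthetic input with ground truth
hgca simulate expression --spec spec.yaml --out sim/

# individual stages
hgca qc GSM1.txt GSM2.txt
hgca dedupe GSM*.txt --report dupes.tsv
hgca select --manifest samples.tsv --n 600
hgca normalize sim/expression.tsv --out normalized.tsv
hgca correlate normalized.tsv --out pairs.tsv
hgca rank sim/expression.tsv --probe PS00001_at --top 50
hgca tree distances.phy --out tree.nwk
hgca neighborhood tree.nwk --probe PS00001_at --height 0.4
hgca enrich --list list.txt --annotations sim/annotations.tsv --category go_bp
hgca pwm-scan --fasta promoters.fasta --pwms pwms.txt --out hits.tsv

# the full chain from a YAML config
hgca run --config config.yaml
```

`config.yaml` schema (defaults shown):

```yaml
io: {matrix: expression.tsv, annotations: annotations.tsv, out: hgca_out}
normalization: {target: 500, trim: 0.02}
correlation: {n_tests: auto}          # auto = number of probe pairs
tree: {rooting: trifurcating}         # or: midpoint
neighborhood: {height: 0.5}           # path length climbed from the query leaf
queries: [PS00001_at]
enrichment: {alpha: 0.05, category: go_bp}
seed: 0
```

The pipeline writes a deterministic artifact directory: normalized matrix,
pair-statistics table, Phylip distances, Newick tree, per-query ranked
lists/neighborhoods/enrichment tables, and a `manifest.json` with the
config hash.

## File formats

- expression matrix: TSV, header row of sample IDs, optional `#tissue` /
  `#series` metadata rows, then `probe_id<TAB>value...`
- annotation catalog: `probe_id<TAB>category<TAB>term1|term2|...`
- distance matrix: relaxed Phylip (full-length names; `strict_names`
  truncates to 10 characters for classic tools)
- trees: Newick with branch lengths
- PWMs: `>name` header followed by L rows of 4 counts/frequencies (A C G T)
- hits: BED-like TSV (sequence, start, end, pwm, mss, strand, css)
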