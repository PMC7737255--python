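# fireladder

Cross-terminology IS-A pattern mining over UMLS-style RRF files.

`fireladder` builds one IS-A hierarchy per source vocabulary (SAB) from
MRCONSO/MRREL (PAR relationships carrying the `inverse_isa` attribute),
removes self-loops and short directed cycles, and searches every ordered
triple of terminologies for the *fire ladder* pattern: a target concept A1
shared with an upper source B, whose child B2 in B is shared with a lower
source C, whose child C3 in C is again a child of A1 in the target — with
each rung concept absent from exactly the terminology it could be imported
into. Detected patterns are turned into two candidate lists:

- **Data Set 1** — import B2 into the target as a child of A1 and parent of
  C3 (patterns sharing the same target and concept triple are merged across
  source permutations);
- **Data Set 2** — import C3 into the upper source as a child of B2
  (`anchored` mode also admits qualifying sibling children of B2; `strict`
  mode is the exact projection of the pattern set).

The package also ships a two-rater agreement module (Cohen's kappa,
Krippendorff's alpha for the binary/nominal two-rater case) for evaluating
expert review of the candidates, and a synthetic-fixture generator that
plants ladders, single-constraint decoys and cycles with known ground
truth.

## CLI

```bash
# generate the worked HPO/NCIt/SNOMED CT example fixture
fireladder fixture --out-dir demo --fig3

# run the full detection pipeline
cat > config.yaml <<EOF
sabs: [HPO, NCI, SNOMEDCT_US]
EOF
fireladder detect --config config.yaml \
    --mrconso demo/MRCONSO.RRF --mrrel demo/MRREL.RRF --out-dir out
# -> out/patterns.tsv, dataset1.tsv, dataset2.tsv, summary.tsv,
#    removed_edges.tsv, report.json

# agreement statistics from a 2x2 contingency or its marginals
fireladder agreement --cells 39 3 6 7
fireladder agreement --marginals 55 42 45 39

# synthetic fixture with planted structures
fireladder fixture --out-dir fx --sabs AAA,BBB,CCC \
    --concepts 30 --ladders 2 --decoys 9 --cycles 1 --seed 7
```

Without `--config`, `detect` uses the default ten-terminology
configuration (SNOMEDCT_US, NCI, MEDCIN, ATC, CPM, CPT, FMA, GO, HPO,
UMD; SNOMEDCT_VET and UWDA excluded). Config keys: `sabs`,
`excluded_sabs`, `language`, `drop_suppressed`, `max_cycle_depth`,
`dataset2_mode`, `seed`.

## Layout

- `src/fireladder/rrf_io.py` — RRF dialect parsing/serialization, config
- `src/fireladder/graph_core.py` — per-SAB graphs, cycle removal
- `src/fireladder/ladder_detect.py` — triple enumeration, detection, brute-force oracle
- `src/fireladder/candidates.py` — Data Set 1/2, per-triple summaries
- `src/fireladder/agreement.py` — kappa, alpha, contingency handling
- `src/fireladder/synth_fixtures.py` — ground-truth fixture generator
- `src/fireladder/cli.py` — `fireladder` command-line entry point
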