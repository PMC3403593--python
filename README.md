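# mrscreen

Identification of candidate transcriptional **master regulators (MRs)** —
transcription factors whose activity plausibly drives a case-vs-control
expression program, such as disease progression in a rat strain model —
by combining two independent routes from expression data to TF→gene pairs
and keeping only TFs that survive under both.

**Who it is for.** Systems-biology analysts with (a) a collection of known
regulatory networks (gene sets plus TF→target relations), (b) gene-level
expression matrices for two strains across growth periods, and (c) a TF
list — or nobody's data at all: the package ships a synthetic-data
generator that emulates all three inputs, so every stage runs without a
download.

## The method

Samples form six cells: strains {case, control} × periods {P1, P2, P3}.

1. **Network screening** (knowledge-based): each reference network G, a
   DAG of TF→target edges, is scored per cell by the Gaussian-network
   log-likelihood without intercepts,
   `l(G) = Σ_i −(m/2)(1 + ln 2π σ_i²)`, with σ_i² the ML residual variance
   of node i regressed on its graph parents (genes standardised per cell).
   The score is calibrated by the **graph consistency probability**:
   GCP = N_s/N_r, the fraction of N_r random same-size DAGs scoring
   strictly higher. GCP is an empirical p-value; a network is *active*
   when GCP < 0.05 (N_r = 2000 by default).
2. **Network inference** (data-driven): per cell, an undirected skeleton
   is inferred by a **modified path-consistency algorithm** — partial
   correlations of increasing order, Fisher z tests, and the modification
   that a numerically unevaluable test (multicollinear genes) *keeps* the
   edge flagged `kept-multicollinear` instead of aborting the run.
3. **Signatures**: per period, genes differing between strains at
   BH-FDR < 0.05 (Welch t). TF→gene pairs from both routes are kept only
   if the gene is in the period's signature.
4. **Selection**: per route, TFs pass by **specificity** (emerge in ≥ 1
   case cell, never in control) or **coverage** (outlyingly many regulated
   signature genes, by an iterated one-sided Smirnov–Grubbs test,
   p < 0.05; case selections minus control selections).
5. **Merge + hierarchy**: final candidates are TFs passing at least one
   criterion under *both* routes (a 2×2 overlap matrix is reported), with
   their case-cell regulated genes, placed by BFS level in the merged
   regulatory network.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

`examples/` holds one short script per capability. The five-variable
skeleton-inference demonstration (`examples/01_pc_worked_example.py`)
builds the population correlation of the DAG X1→X3←X2, X1→X4, X3→X5←X4
and prints:

```
removals (pair, order, separating set):
  X1-X2  order 0  sepset {}
  X2-X4  order 0  sepset {}
  X3-X4  order 1  sepset {X1}
  X1-X5  order 2  sepset {X3, X4}
  X2-X5  order 2  sepset {X3, X4}
final skeleton edges: [('X1', 'X3'), ('X1', 'X4'), ('X2', 'X3'), ('X3', 'X5'), ('X4', 'X5')]
```

Two pairs fall at order 0 (marginal independence), one at order 1, two at
order 2 — each removal's separating set certifies one conditional
independence of the model, and the surviving five edges are exactly the
true skeleton.

Replaying the bundled GK/WKY diabetic-rat selection tables
(`examples/03_published_replay.py`) prints:

```
criterion sizes:
  screening specificity: 21
  screening coverage:    3 ['EGR1', 'NRF1', 'TCFAP2A']
  inference specificity: 108
  inference coverage:    42
overlap matrix (rows: screening spec/cov; cols: inference spec/cov):
  [[4, 2], [0, 0]]
final MR candidates (5): Etv4, Fus, Nr2f1, Sp2, Tcfap2b
regulated-gene pairs: 54 (52 unique genes)
```

i.e. the 21 screening-specific TFs share 4 TFs with the inference
specificity list and 2 with the inference coverage list; merging yields 5
candidate MRs regulating 54 gene pairs.

End-to-end on synthetic data (`examples/04_recover_planted_mrs.py`): the
demo scenario plants 5 MRs among 25 TFs with case-specific regulons; the
full pipeline reports `['TF01', 'TF02', 'TF03', 'TF04', 'TF05']` — all
planted MRs, nothing else — and places all five in the top hierarchy band.

## Command line

```sh
mrscreen simulate --config scenario.yaml --seed 1 --out artifacts/
mrscreen run-all  --artifacts artifacts/ --seed 1 --out results/
# or stage by stage:
mrscreen screen    --networks artifacts/ --expr artifacts/expression.tsv \
                   --sheet artifacts/samples.tsv --n-random 2000 --out gcp/
mrscreen infer     --expr ... --sheet ... --alpha 0.05 --out skeletons/
mrscreen signature --expr ... --sheet ... --fdr 0.05 --out signatures/
mrscreen hierarchy --edges final_edges.tsv --tfs tfs.txt --out levels.tsv
```

All inputs and outputs are plain TSV/GMT/JSON; formats are documented in
`mrscreen/iodata.py`.

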