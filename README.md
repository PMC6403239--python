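# lopnet

Graph-centrality analysis of levels-of-processing (LOP) effects on
memory-encoding brain networks — as a tested, reusable pipeline with a
synthetic-cohort generator, so every stage runs and is verifiable without
access to real fMRI data.

## The scientific problem

Deep (semantic) processing during encoding produces more durable memories
than shallow processing. One mechanistic account is that deep processing
reorganizes *communication* within the network of encoding-relevant brain
regions: certain regions become more central — better connected to the rest
of the network — exactly when elaborative encoding succeeds, and people who
centralize these regions more strongly remember more. `lopnet` implements
the full analysis chain needed to test this on an incidental item–action
encoding study (~100 events, yes/no evaluations, a delayed three-question
source-memory test, event-related fMRI at TR 2.39 s), and a forward model
that plants such an effect with known ground truth.

## The method

1. **Stimulus classification.** Events ranked by total "yes" count across
   participants, quartile-split: middle two quartiles (high disagreement) =
   high *elaboration*; per-participant "yes" = high *congruity*.
2. **Memory scoring.** Full source memory = recognize the item, claim and
   correctly report the encoding action; corrected score subtracts wrong
   action reports; recognition d′ = Φ⁻¹(hit) − Φ⁻¹(FA). Exclusion rules:
   ≥ 10 trials per analysis cell, ≥ 10 % overall source memory.
3. **Connectivity (correlational PPI).** Per node: drift removal →
   deconvolution against the canonical two-gamma HRF → condition boxcar ×
   neural estimate → reconvolution. Fisher-z Pearson correlations between
   PPI terms give one node × node matrix per participant and condition.
4. **Graphs.** Matrices binarized at edge densities 20–30 % (step 2), the
   20 % floor validated by the 85/85 connectedness rule. Centralities from
   their definitions, e.g. closeness `CC(v) = 1 / Σᵢ d(v,i)`, plus degree,
   betweenness and eigenvector centrality.
5. **Inference.** Node-wise paired t-tests between conditions at every
   density; Benjamini–Hochberg FDR (q = 0.05) within density; only nodes
   significant with consistent direction at *all six* densities survive.
   Mean centrality change (remembered − forgotten) over the surviving set
   is correlated with source memory, and its specificity is quantified by
   recomputing that correlation for *every* same-size subset of the
   remaining nodes (C(38,4) = 73 815 constellations) — the empirical p is
   the fraction with an equal or higher r.

The synthetic generator (`lopnet.simulate`) draws yes-rates from a
calibrated agreement mixture, memory outcomes from a logistic LOP model,
and node time series as evoked event amplitudes plus stationary background
with a structured covariance; four planted "hub" nodes synchronize with the
network's common evoked signal during successfully encoded deep events.
See `docs/methods.md` for the model, its assumptions and its limits.

## Worked example

```bash
python examples/full_pipeline.py
```

prints (60-participant cohort, seed 7):

```
included participants: 52
source memory high vs low elaboration: 60.0% vs 35.1%
planted hubs:               [15, 20, 25, 32]
conjunction (increased CC): [15, 20, 25, 32]
centrality-change/memory r = 0.228 (p = 0.105); 5943/73815 random node subsets matched it (8.051%)
```

Reading: deep elaboration roughly doubles source memory; the FDR
conjunction across all six graph densities recovers exactly the four
planted hub nodes as the regions whose closeness centrality rises under
deep processing; and the correlation between hub-centrality change during
successful encoding and memory performance beats ~92 % of all alternative
four-node constellations. (At this reduced cohort size the memory
correlation is underpowered; at the full 113-participant study scale the
planted link gives r ≈ 0.15–0.30 depending on the cohort draw — r = 0.30,
p = 0.004, exhaustive-permutation p = 0.007 at the default seed; see
below.)

Other examples: `behavioral_classification.py` (ranking, quartile split,
memory scoring), `node_extraction_demo.py` (mesh clusters → nodes),
`cppi_connectivity.py` (the PPI chain on one participant),
`graph_centrality.py` (thresholding + the four measures). A thin CLI wraps
the pipeline (`lopnet run-all --seed 1 --out-dir runs/demo`, plus
stage-wise `simulate` / `classify` / `connect` / `graph` / `infer` /
`report` subcommands operating on the run directory).

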