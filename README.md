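# connectome-nbs

Construction of functional and structural brain connectomes from
region-level data, and detection of group-differing sub-networks with
network-based statistics (NBS) — edge-wise general linear models, connected
suprathreshold components, and permutation-based family-wise error (FWE)
control — plus the follow-up analyses a genotype-stratified imaging study
needs: iso-/anisocoupled link classification against a six-division atlas
partition, genotype × sex interaction tests, sex-matched re-tests, and
partial correlations with behavioral scores.

The package is aimed at imaging-genetics and systems-neuroscience analyses
where two groups (e.g. carriers of a low- vs high-expression genotype) are
compared edge-by-edge over node × node connectivity matrices, and where the
inferential unit is a *connected cluster of links* rather than a single
edge. A bundled synthetic-cohort generator with edge-level ground truth
makes every stage testable: it plants a covariance increase on a chosen
edge set in one group (functional), a multiplicative offset on streamline
counts (structural), motion spikes, unbalanced sex composition and
brain–behavior loadings.

## Method

For each subject, functional connectivity is the Pearson correlation matrix
of 116 regional fMRI time series after motion QC (frame-wise displacement
FD_t = Σ|Δd| + 50 mm·Σ|Δθ|; frames with FD > 0.5 mm are scrubbed and
B-spline interpolated; subjects with > 10 % flagged frames are excluded),
nuisance regression (white matter, CSF, task means for active tasks, six
motion parameters) and temporal filtering (0.008–0.1 Hz band-pass at rest,
128 s high-pass for tasks). Structural connectivity is the symmetrized
streamline-count matrix from deterministic tractography.

NBS then tests, at every edge (i, j),

    w_ij ~ β₀ + β₁·group + β₂·age + β₃·sex + β₄·site + β₅·protocol

reporting the partial F for the group term (functional weights Fisher
z-transformed first). Edges with p ≤ .005 are kept; connected components of
the surviving graph are the candidate sub-networks. Group labels are
permuted K times (5,000 by default; covariates stay attached to subjects),
the maximal component extent is recorded each time, and each observed
component receives

    p_FWE = (1 + #{null maxima ≥ extent}) / (K + 1).

Detected components are characterized by their iso-/anisocoupled link split
(same vs different supraordinate division: frontal, parietal, occipital,
temporal, cingulate, subcortical), their division-pair profile, the top 10 %
most significant links, and per-subject mean sub-network connectivity,
which feeds the interaction, stratified and partial-correlation follow-ups.

## Worked example

`examples/03_run_nbs.py` plants a 10-link hyperconnected component
(covariance +0.3 in the low-expression group) in a 20-node, 30 + 30 cohort
and runs the full procedure:

```
null max-extent distribution: median 1, max 6
component 0: 10 links over 7 nodes, p_FWE = 0.0020, 100% of links higher in L
component 1: 1 links over 2 nodes, p_FWE = 0.5788, 0% of links higher in L
overlap with planted edges: Jaccard = 1.00
```

The largest detected component is exactly the planted edge set (Jaccard 1),
its 10 links far exceed every permuted maximal extent (p_FWE = 1/501 ≈
.002), and all its links show higher connectivity in the low-expression
group — the planted hyperconnectivity, recovered. The second "component" is
a single noise edge, correctly assigned a large p.

The other examples walk the remaining capabilities: cohort simulation (01),
the per-subject functional pipeline (02), 116-node sub-network
characterization against the bundled atlas partition (04), association
follow-ups (05), and the end-to-end driver with its reproducibility
manifest (06). A thin CLI mirrors the driver:

```sh
connectome-nbs simulate --config sim.yaml --out cohort/
connectome-nbs validate cohort/
connectome-nbs run --config pipeline.yaml
```

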