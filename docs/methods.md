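# Methods

## Problem and model

`specview` addresses metabolite annotation: given a tandem mass
spectrum (MS/MS) of an unknown small molecule and a set of candidate
structures, decide which candidate produced the spectrum.  The package
learns a *shared embedding space* for four views of a metabolite datum:

- **mol** — the molecular graph (heavy atoms as nodes, bonds as edges),
- **fp** — a binary Morgan fingerprint (1024 bits, radius 5),
- **s** — one measured MS/MS spectrum, as a set of formula-annotated peaks,
- **cs** — the consensus spectrum of all spectra of the same molecule
  (training) or measured feature (inference).

Training pulls the four views of the same datum together and pushes
non-matching data apart with a temperature-scaled softmax contrastive
loss applied to *every* unordered pair of active views (the full-graph
paradigm; 6 pairs for 4 views, 12 directional terms):

    L        = sum over pairs (Vp, Vq) of  L(Vp, Vq)
    L(Vp,Vq) = L_contrast(Vp→Vq) + L_contrast(Vq→Vp)
    L_contrast(Vp→Vq) = -(1/B) Σ_i log [ h(v_p^i, v_q^i) / Σ_j h(v_p^i, v_q^j) ]
    h(a, b)  = exp( cos(a, b) / τ )

Negatives for datum *i* are the other B−1 members of the same batch,
shared by both directions of a pair.  The directional term equals the
softmax cross-entropy of identifying the matching sample, so it is
bounded below by 0 and equals log B exactly when all similarities are
equal (both properties are tested).

At inference, candidates are ordered by cosine similarity between a
spectral-view embedding and a molecule-view embedding.  Four ranking
views exist (mol-s, fp-s, mol-cs, fp-cs), and multi-spectrum queries
support two paradigms: *aggregate-then-rank* (merge spectra into a
consensus, rank once) and *rank-then-aggregate* (rank per spectrum,
combine per-candidate ranks by mean rank or by summed reciprocal rank).

## Peak representation

Peaks are annotated before encoding: each of the 60 most intense peaks
is matched to the element-wise subformula of the precursor formula
whose adduct-shifted monoisotopic mass is nearest in ppm, within a
±20 ppm tolerance.  Ties take the smaller |ppm|, then the
lexicographically smaller Hill formula — the tie rule is this package's
choice, as is the order of operations (intensity filter → annotate →
one peak per formula → rescale intensities to max 1).  The annotated
peak is encoded as a vector in R¹⁵: 14 element counts over
E = {C,H,O,N,P,S,Cl,F,Br,I,B,As,Si,Se}, each divided by the maximum
count of that element observed in the training annotations, then the
normalized intensity.  Counts outside the training range clamp to 1
with a warning; intensity normalization is per-spectrum max-scaling
(the concrete scheme is a package choice).  Consensus spectra are built
*after* annotation: the formula set is the union over the group's
spectra and each formula keeps the maximum intensity seen, so every
constituent spectrum is a subset of its consensus.  Consensus size is
not capped after merging.  A formula-free alternative ("binned" mode)
grids peaks at 1 Da over 0–1000 Da, max intensity per bin, rescaled to
max 1.

Supported adducts are [M+H]⁺ and [M+Na]⁺ (proton mass 1.007276 Da with
the electron mass accounted for); negative mode is out of scope.
Monoisotopic atomic masses are IUPAC standard values hard-coded to
≥ 6 decimals.

## Encoders

All encoders emit vectors of one shared dimension *d* and are written
on a small in-package reverse-mode autodiff core (`specview.nn`,
float64, exact gradients — verified against finite differences).

- **Graph**: 3 graph-convolution layers over the symmetrically
  normalized adjacency with self-loops, mean pooling, then a 2-layer
  feed-forward head.  Node inputs are the atom features (type one-hot
  over E plus an "other" bucket, mass, valence, ring flag, formal
  charge, radical electrons, chirality one-hot, degree, hydrogen
  count, aromaticity) concatenated with the mean incident bond feature
  vector (bond-type one-hot, ring, conjugation, stereo one-hot), so
  edge attributes inform the convolution without per-edge weights.
- **Fingerprint**: 3-layer MLP over the 1024-bit vector.
- **Spectrum / consensus**: a 3-layer per-peak MLP, one transformer
  encoder block with 2 attention heads, masked mean pooling over real
  peak positions, and a linear head.  No positional encodings — peaks
  are a set — and padded positions receive a −10³⁰ attention bias, so
  the embedding is invariant to peak order and to the amount of batch
  padding (tested at 1e-5).  The spectrum and consensus encoders share
  this architecture but never parameters.  In binned mode both are
  replaced by 3-layer MLPs over the bin vector.

Open architectural details (hidden widths, activation, normalization,
pooling flavor, set summary) are package choices: defaults d = 256,
hidden 512, ReLU, post-residual layer normalization, mean pooling; all
recorded in checkpoints (JSON: config + parameters + normalization
statistics, so inference is self-contained).  Embeddings are not
L2-normalized at the encoder output; the loss and the ranking both use
cosine similarity, which normalizes implicitly.

## Training

Defaults follow the reference recipe: Adam, learning rate 7.0e-5,
batch size 64, 1500 epochs, temperature τ = 0.05.  A batch is composed
at the molecule level: each molecule contributes its graph,
fingerprint, its group's fixed consensus, and *one* individual
spectrum re-sampled uniformly per epoch (the composition rule is a
package choice; it avoids false negatives from the same molecule
appearing twice in a batch).  Any view subset of size ≥ 2 can be
trained; inactive encoders are untouched.  No learning-rate schedule
or early stopping by default.  Non-finite gradients abort with a
diagnostic; clipping is optional config.  Training is deterministic
given the seed.

## Candidate retrieval and evaluation

Candidate sets come either from a 10 ppm monoisotopic-mass window
around the target mass or from exact formula equality, capped at 256
(nearest-by-mass decoys kept).  Score ties assign the target the worst
rank of its tie group, so rank@k is never inflated by ties; queries
with nothing annotatable count as failures rather than being dropped.
rank@k is reported for k = 1, 5, 20 with percentile-bootstrap
confidence intervals (99.9% level; resample count configurable, 20 000
for final figures and 2 000 in the fast default path).  MCES@1 is the
mean maximum-common-edge-subgraph distance
(edges(a) + edges(b) − 2·|MCES|) between target and top-ranked
candidate; the implementation is an exact descending-size subset
search with labeled-subgraph monomorphism checks, valid for molecules
up to 12 bonds (a hard cap — large-scale approximate MCES is out of
scope), and is tested against an exhaustive node-mapping oracle.

## Synthetic data

The generator defines the study conditions for all desk-scale
experiments: 50 molecules (a curated list of real small structures,
including isomer pairs, extended by randomly grown single-bonded
C/N/O/S trees when more are requested), 3 spectra per molecule at
emulated "collision energies", 12 fragments per molecule, [M+H]⁺,
5 ppm m/z jitter (15 ppm in the annotation stress test), intensity
decay 0.7 per fragment rank with log-normal noise (σ = 0.3), dropout
0.5.  Fragments are true subformulas of the molecule, sampled from the
mass-resolvable subset (no sibling subformula within 40 ppm), so
ground-truth formulas are recoverable by construction at the 20 ppm
tolerance.  Energy levels own disjoint fragment shares and see the
others' with probability 1 − dropout, which makes the peak union
strictly richer than any single spectrum — the property consensus
construction exploits.  The generator emulates the *statistical* shape
of repository data, not fragmentation chemistry: intensities, neutral
losses and rearrangements of real spectra are not modeled, so passing
tests demonstrate correctness of the machinery and learnability of the
representation, not annotation accuracy on real data.

The `SubformulaProfileEmbedder` is an analytic stand-in for trained
encoders: molecules as indicator vectors over their complete
subformula set, spectra as indicators over observed peaks.  It is used
to study ranking/aggregation semantics in isolation — in particular
the constructed case where every single spectrum is ambiguous between
two candidates but the peak union pins down the target, where
aggregate-then-rank succeeds and both rank-then-aggregate strategies
fail.

## Desk-scale study sizes

The end-to-end learnability study trains d = 32 / hidden 64 encoders
for 300 epochs at learning rate 1e-3 (batch 25) on the 50-molecule
task and retrieves against 8 random decoys per query — sizes chosen so
the whole cycle runs in about a minute on one CPU while still
exercising every code path.  The acceptance script
(`scripts/acceptance.py`) re-runs this study from scratch along with
the loss-oracle, annotation-recovery and paradigm-comparison
computations.

## Known limitations

- Exact MCES only, ≤ 12 bonds per molecule.
- Positive-mode adducts only; no isotope patterns; no de novo formula
  assignment (precursor formulas are an upstream input at inference).
- The contrastive recipe at full scale (d = 256, 1500 epochs, large
  spectral libraries) is supported by the code but not exercised by
  the test suite, which runs desk-scale configurations throughout.
- The autodiff core is minimal by design (no GPU, no mixed precision,
  single-threaded numpy); it is sized for the desk-scale studies.
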