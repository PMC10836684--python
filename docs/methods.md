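# Methods

This note documents the models behind the virtual instrument, the
defaults and why they were chosen, and what the simulation does and does
not emulate. The package's purpose is to reproduce the *software*
workflow of automated multi-domain hydrogel photopatterning — protocol
compilation, scheduling, and micrograph quantification — against a
simulated chamber; it makes no claim to predict wet-lab physics beyond
the calibrations noted below.

## Image-to-layout compilation

A raster image is reduced to an `n × n` grid of per-channel **block
means** (binning), the cell colors are clustered with **k-means** in RGB
space, and each cluster becomes a binary **location map**. Decisions:

- *Bin, then cluster.* Mean-color binning is robust to anti-aliased
  pixel art; majority-color binning was rejected because a single
  anti-aliased cell can carry a color no palette entry matches.
- *Remainder folding.* When the image side is not a multiple of `n`
  (e.g. 355 = 15·23 + 10), remainder pixels fold into the last
  row/column block, so every pixel contributes to exactly one cell.
- *k-means.* k-means++ initialization, up to 50 restarts
  (scikit-learn `n_init=50`), seeded and therefore bit-reproducible.
  On tiny grids the result attains the global within-cluster-SSE
  optimum found by exhaustive partition enumeration (verified in the
  test suite); the restarts are the guard against local minima.
  If `k` exceeds the number of distinct cell colors, degenerate
  clusters are collapsed with a warning.
- *Ink assignment.* Maps are ordered by descending cell count (largest
  domain = ink 1), a deterministic convention the caller can override
  by reassigning vials.
- *Coordinates.* Origin top-left, x rightward, y downward (image
  convention), micrometers throughout. Grid cell `(i, j)` maps to
  `origin + (j·pitch, i·pitch)`; pitch ≥ post size is enforced so
  pixel-art posts never overlap unintentionally.

Strip layouts place domain *i* at `x = i·(size − overlap)`, which makes
the intersection of consecutive footprints exactly `overlap` wide — the
10 µm interfaces that hold multi-domain architectures together through
lift-off.

## Protocol semantics

A **round** is `FLOW(vial)` → per site (`MOVE`, `FLOW(vial, reflow)`,
`PATTERN`) → `WASH`. The brief re-flow of the same ink before each
exposure mirrors the practice that keeps patterned-size variance low; it
defaults to 3 s ("a few seconds" is otherwise unquantified) and is
configurable. A wash is emitted after **every** round including the
last. Rounds are never merged even when consecutive rounds draw the same
ink from different vials — vial identity, not ink identity, defines the
round. Exposure defaults to 1 s (the short exposure used with the LAP
photoinitiator for DNA-crosslinked inks).

Validation flags: more than 4 distinct ink vials (the 5th port is the
wash line); ink vials under the minimum working volume (default 100 µL,
the conservative reliable-operation value; a documented override down to
50 µL exists); `PATTERN` without a `FLOW` since the last wash; multiple
inks within one round; a missing terminal wash; unresolved mask/vial
references. Validation reports rather than raises; execution refuses
invalid protocols.

Serialization is canonical JSON under schema `mapdh-protocol/1` with
YAML accepted on read; unknown fields are rejected so that
`parse(serialize(p)) == p` is an identity, not a projection.

## The virtual chamber

- **Mass ledger.** `FLOW` consumes `flow_rate × duration` µL from its
  vial (default 1 µL/s); flowing from an empty or insufficient vial is
  an execution error. The wash line is treated as unlimited unless
  declared as a vial.
- **Patterning.** `PATTERN` requires the chamber to hold the current
  round's ink and creates a domain whose footprint is the mask's
  micrometer dimensions at the current stage position, plus an optional
  additive **size bias**. The default bias is zero; a descriptive
  calibrated profile (`observed_size_bias()`:
  +1.5 µm at 50 µm, +7.1 µm at 20 µm, +3.7 µm at 10 µm nominal masks)
  reproduces observed mean patterned sizes and is labeled calibration,
  not optics.
- **Contiguity.** Overlapping or abutting footprints are mechanically
  contiguous: they detach, lift off, and are collected as one cluster,
  and each pair of facing edges is marked *constrained* for swelling.
  Overlap regions carry the union of compositions (both domains render
  there); no interpenetration physics is modeled.
- **Wash-off.** When a sacrificial layer is present, each `WASH`
  removes each attached cluster *patterned in an earlier round* with
  probability `p_washoff` (a round's own wash never removes its fresh
  gel — premature loss is a multi-round-exposure phenomenon). For a
  three-round architecture this gives loss probability
  `1 − (1 − p)²`; with the calibration `p = 0.25`, 25 architectures
  lose ≈ 10.9 on average, within one binomial standard deviation of the
  observed 12/25. `DISSOLVE_SACRIFICIAL` frees all remaining attached
  gels; `COLLECT` recovers each free cluster with probability
  `p_collect`. Both probabilities are Bernoulli calibrations — the
  underlying adhesion physics is out of scope.
- **Hybridization/quenching.** A free strand at concentration `c` (nM)
  drives the quenched fraction of its anchored complement toward 1 as
  `q ← 1 − (1 − q)·exp(−k·c·Δt)` with
  `k = hybridization_rate_per_nM_h = 0.01 /(nM·h)`, chosen so a 500 nM
  quencher saturates within a ~1 h incubation. Complements come from an
  explicit Watson–Crick table (`5Q_R1'` ↔ `5Acry_3Cy3_R1` by default,
  extensible per run). Domains lacking the complement are untouched;
  emission scales linearly with `(1 − q)` and is exactly zero at
  `q = 1`.
- **Swelling.** *This rate law is a stand-in.* The
  hybridization-chain-reaction mechanism that extends DNA crosslinks is
  not modeled; each domain edge whose crosslink system (S1/S2) has
  received its hairpin signal follows

  `ΔL/L₀(t) = A_sys · (1 − e^(−t/τ))`,

  with `τ = 8 h` (an order-of-magnitude anchor consistent with most
  swelling occurring in the first ~10 h) and the amplitude `A_sys` a
  **calibration input**: the measured equilibrium relative swelling.
  Defaults are `A_S1 = 0.51`, `A_S2 = 0.6`; the packaged multi-domain
  experiment uses `A_S1 = 0.4, A_S2 = 0.6`, the free-edge equilibria
  observed for that architecture (constraint by neighbors makes the
  single- and multi-domain amplitudes genuinely different quantities).
  Edges shared with a neighboring domain swell at
  `constrained_edge_factor = 0.5` of the free strain, so the
  closest-vs-farthest edge difference approaches `0.5·A` (≈ 0.2 for
  `A = 0.4`, matching the measured 0.217). Non-crosslinked domains and
  unmatched systems are fixed points; ΔL/L₀ starts at 0, is monotone
  nondecreasing, and is bounded by `A_sys`. The hairpin signal
  concentration (20 µM final) is recorded but does not enter the rate
  law.

## Rendering and quantification

Per channel, pixel intensity = `background + Σ_domains gain ×
concentration × (1 − quenched_fraction)` over strands labeled with that
channel's fluorophore, plus i.i.d. Gaussian noise (`background = 100`,
`σ = 5`, `gain = 1 count/nM` by default), clipped at zero — no PSF,
shot-noise, or photobleaching model. Swollen rectangular domains render
as quadrilaterals whose side length at each edge equals that edge's
strained length; named shapes (circle/triangle/plus) scale isotropically.
Rendering is deterministic per seed.

Quantification mirrors manual practice: Otsu's threshold (256-bin
between-class-variance maximization, delegated to scikit-image and
checked in the tests against an exhaustive-scan oracle — where empty
histogram bins tie the optimum the threshold is non-unique and only
optimality is asserted), largest 8-connected component, axis-aligned
bounding box with length = box height × pixel size (the bounding-box
side matches the manual rectangle procedure; Feret diameters are not
used). ΔL/L₀ curves divide by the first (pre-signal) measurement, so
they start at exactly 0. For the three-domain strip, measuring the
bounding-box side in each domain's own channel automatically reads the
*free* edge — the edge opposite green — because the constrained edge is
shorter. Across-round homogeneity uses one-way ANOVA at α = 0.05 (no
specific test is canonical for this comparison; identical groups are
reported as F = 0, p = 1 rather than NaN). Multi-object images are
measured per connected component and matched to rounds by centroid
position.

## What the synthetic data does and does not show

The generator reproduces: flat-field multi-channel micrographs with
Gaussian noise, exact domain geometry under the swelling law, channel
separation, and Bernoulli loss/collection counts. It does **not**
reproduce: optical blur and focus gradients, polymerization
inhomogeneity (real gels swell non-uniformly), domain misalignment from
weak anchoring, bowing of non-swelling domains under neighbor stress, or
gel folding/wrinkling after collection. Passing round-trip tests
therefore demonstrates the correctness of the compilation, scheduling,
bookkeeping, and measurement code — not that the physics of a real
chamber is captured. Because rendered edges are sharp, measured lengths
quantize to whole pixels; at default optics the 12-round
characterization grid yields identical 51 px lengths in every round
(degenerate ANOVA, reported as p = 1), while fluorescence retains noise
variance and exercises the test non-degenerately.

## Problem sizes and tolerances

Default experiment sizes are the study conditions themselves: 12 rounds
× 5 posts, 15 × 15 pixel-art grids (225 sites), 25 three-domain
architectures, 50-seed repeats for swelling recovery, 200 µm gels at
1 µm/pixel. Equilibrium recovery through the noisy pipeline is expected
within ±0.05 of the configured amplitude (a one-pixel boundary bias on a
200 px baseline contributes ≈ 0.01). The acceptance script reports the
mean over 50 seeds; per-seed spread at default noise is small (< 0.02
s.d.) because Otsu thresholding of a high-contrast square is stable.
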