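# mapdh

Design, virtually execute, and quantify **multi-domain automated
photopatterning of DNA-functionalized hydrogels**.

Multi-domain DNA-functionalized hydrogels are fabricated by repeatedly
flowing a pre-gel "ink" (PEGDA monomer + LAP photoinitiator +
acrydite-modified DNA strands) into a microfluidic chamber, shaping UV
light with a digital micromirror device (DMD) to photopolymerize posts at
chosen stage positions, and washing before the next ink — one
flow → print → wash *round* per ink, for up to 4 inks with as little as
100 µL each. The anchored DNA makes the resulting architectures
addressable: a quencher-modified complement dims exactly the domains that
anchor its target strand, and hairpin signal pairs drive
hybridization-chain-reaction swelling of matching DNA-crosslinked domains.

This package implements that workflow against a **simulated instrument**,
so multi-domain patterning experiments can be designed, executed
virtually, and analyzed end-to-end without hardware:

- **`mapdh.layout`** — image → protocol compilation: bin a raster image to
  an *n* × *n* grid, k-means-cluster the cell colors, emit one binary
  *location map* per ink domain (the maps partition the grid), and place
  each cell at micrometer stage coordinates; plus hand-specified layouts
  such as strips of 200 µm domains with 10 µm overlapping borders.
- **`mapdh.protocol`** — compile layouts + ink/mask assignments into a
  validated, schema-versioned command stream
  (`FLOW / MOVE / PATTERN / WASH / ADD_SOLUTION / DISSOLVE_SACRIFICIAL /
  COLLECT`), enforce the round grammar, the 4-ink-port limit and the
  100 µL minimum working volume, estimate per-vial ink usage, and
  round-trip protocols through JSON (YAML accepted on read).
- **`mapdh.instrument`** — the virtual chamber: vial volumes, patterning
  with optional calibrated size bias, premature wash-off of weakly
  anchored gels, sacrificial-layer lift-off and collection, quenching
  hybridization, saturating-exponential swelling
  ΔL/L₀(t) = A·(1 − e^(−t/τ)) with constrained shared edges, and
  rendering of synthetic multi-channel fluorescence micrographs.
- **`mapdh.quantify`** — micrograph analysis as done on real data: Otsu
  binarization (256-bin between-class-variance maximization), largest
  8-connected component, bounding-box length/width in µm, ROI mean
  fluorescence, ΔL/L₀ swelling curves, and per-round statistics with a
  one-way ANOVA homogeneity test.
- **`mapdh.experiments`** — complete virtual experiments (12-round
  reproducibility grid, pixel-art image, quench architecture,
  lift-off/collection yield, single- and multi-domain swelling), and
  **`mapdh.fixtures`** — synthetic inputs with ground-truth manifests.
- **`mapdh` CLI** — thin shell access:
  `mapdh compile | run | measure | swell-analyze | fixtures`.

Intended users: groups building or modeling automated hydrogel-patterning
platforms who want to draft and sanity-check protocols, and anyone needing
a reproducible synthetic-micrograph benchmark for hydrogel image
quantification.

## Worked example

Compile a four-color pixel-art image and run it:

```python
from mapdh.experiments import pixel_art_protocol
from mapdh.fixtures import watermelon_image
from mapdh import execute, validate_protocol

img, _ = watermelon_image()                      # 355x355 px, 4 colors
protocol, maps, _ = pixel_art_protocol(img, n=15, k=4, seed=0)
print(protocol.n_rounds, protocol.n_patterns)    # -> 4 225
state, events = execute(protocol, seed=0)
print(len(state.domains))                        # -> 225
```

Each of the 4 rounds flows one ink and patterns that domain's grid cells
as 50 µm posts; the 4 location maps partition the 15 × 15 grid, so 225
posts are patterned in total.

Swelling, measured through the full render-and-measure pipeline
(`python examples/swelling_curves.py`):

```
single-domain S1 swelling (A = 0.51, tau = 8 h):
  t =   0.0 h   dL/L0 = +0.000
  t =  12.0 h   dL/L0 = +0.388
  t =  24.0 h   dL/L0 = +0.478
  t =  60.0 h   dL/L0 = +0.498
endpoint at 60 h: 0.498 (configured equilibrium 0.51)
```

The endpoint is the relative length change of the gel 60 h after the S1
hairpin signal was added, recovered from noisy synthetic micrographs by
Otsu thresholding — within a boundary pixel of the configured equilibrium.
The other scripts in `examples/` demonstrate protocol compilation,
round-to-round reproducibility statistics, addressable quenching, and
lift-off/collection yields; each prints what its numbers mean.

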