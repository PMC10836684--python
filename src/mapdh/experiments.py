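"""Canonical virtual experiments composing the full pipeline.

Each function builds the inputs (layout, inks, masks), compiles a
protocol, executes it on the virtual instrument, and — where relevant —
renders synthetic micrographs and quantifies them, mirroring the
platform's characterization experiments: the 12-round reproducibility
grid, the four-color pixel-art image, the addressable-quenching
architecture, lift-off/collection yield, and single- and multi-domain
DNA-signal-induced swelling measured through the render-and-Otsu
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig, SwellingConfig
from .errors import CompilationError
from .instrument import (
    ChamberState,
    add_swelling_signal,
    advance_time,
    execute,
    render,
)
from .layout import (
    DomainLayout,
    LayoutSite,
    bin_image,
    build_location_maps,
    cluster_colors,
    grids_to_layout,
    make_strip_layout,
)
from .protocol import (
    AddSolution,
    Collect,
    CompileParams,
    Dissolve,
    InkSpec,
    Mask,
    Protocol,
    StrandSpec,
    compile_protocol,
    make_rect_mask,
    make_shape_mask,
)
from .quantify import (
    Measurement,
    RoundStats,
    SwellingCurve,
    measure_objects,
    measure_stack,
    round_stats,
    swelling_curve,
)

__all__ = [
    "SwellingRunResult",
    "characterization_protocol",
    "characterization_statistics",
    "liftoff_collection_experiment",
    "multi_domain_swelling_experiment",
    "pixel_art_protocol",
    "quench_architecture_protocol",
    "single_domain_swelling_experiment",
]

#: (strand name, fluorophore channel) for the three orthogonal imaging dyes.
FLUOR_PALETTE = [
    ("5Acry_3Cy3_polyT10", "Cy3"),
    ("5Acry_3ATTO488_polyT10", "ATTO488"),
    ("5Acry_3TYE665_polyT10", "TYE665"),
]


def characterization_protocol(
    n_rounds: int = 12,
    posts_per_round: int = 5,
    post_um: float = 50.0,
    pitch_um: float = 100.0,
    vial_cycle: tuple[int, ...] = (1, 2, 3, 4),
    params: CompileParams | None = None,
) -> Protocol:
    """The round-to-round reproducibility experiment.

    ``n_rounds`` patterning rounds cycle through the ink vials
    ``vial_cycle`` (default [1,2,3,4] repeated); each round patterns a
    column of ``posts_per_round`` square posts before moving to the next
    column, and every round ends with a wash. All vials carry the same
    100 nM Cy3-labeled ink so per-round length and fluorescence
    statistics are directly comparable.
    """
    sites = [
        LayoutSite(
            domain_id=r,
            center_x_um=r * pitch_um,
            center_y_um=i * pitch_um,
            width_um=post_um,
            height_um=post_um,
        )
        for r in range(n_rounds)
        for i in range(posts_per_round)
    ]
    layout = DomainLayout(sites=sites, pitch_um=pitch_um)
    strand = StrandSpec(
        name="5Acry_3Cy3_polyT10", concentration_nM=100.0, fluorophore="Cy3"
    )
    vials = [
        InkSpec(vial_id=v, strands=[strand], volume_ul=150.0)
        for v in sorted(set(vial_cycle))
    ]
    mask = make_rect_mask(post_um, post_um, name=f"square{post_um:g}")
    inks = {r: vial_cycle[r % len(vial_cycle)] for r in range(n_rounds)}
    masks = {r: mask for r in range(n_rounds)}
    return compile_protocol(layout, inks, masks, vials, params=params)


def characterization_statistics(
    seed: int = 0,
    config: RunConfig | None = None,
    n_rounds: int = 12,
    posts_per_round: int = 5,
    pitch_um: float = 100.0,
) -> tuple[list[Measurement], RoundStats, RoundStats]:
    """Run the reproducibility experiment end to end and summarize it.

    Executes the 12-round protocol, renders the full chamber, measures
    every post (Otsu + per-object bounding boxes), assigns each post to
    its round by column position, and returns the measurements plus the
    per-round length and fluorescence statistics with the across-round
    one-way ANOVA.
    """
    config = config or RunConfig()
    protocol = characterization_protocol(
        n_rounds=n_rounds, posts_per_round=posts_per_round, pitch_um=pitch_um
    )
    state, _ = execute(protocol, seed=seed, config=config)
    margin = pitch_um
    field = (-margin, -margin,
             n_rounds * pitch_um + margin, posts_per_round * pitch_um + margin)
    stack = render(state, config, field_um=field, channels=["Cy3"],
                   seed=int(np.random.default_rng(seed).integers(2**31)))
    measurements = measure_objects(stack.channel("Cy3"), stack.pixel_size_um)
    x0 = field[0]
    for m in measurements:
        x_um = x0 + m.centroid_px[1] * stack.pixel_size_um
        m.round_id = int(round(x_um / pitch_um)) + 1
        m.mean_fluorescence["Cy3"] = m.mean_fluorescence.pop("img")
    stats_len = round_stats(measurements, metric="length_um")
    stats_fluor = round_stats(measurements, metric="fluorescence", channel="Cy3")
    return measurements, stats_len, stats_fluor


def pixel_art_protocol(
    image: np.ndarray,
    n: int = 15,
    k: int = 4,
    seed: int = 0,
    post_um: float = 50.0,
    pitch_um: float = 100.0,
    params: CompileParams | None = None,
):
    """Compile a raster image into a multi-domain patterning protocol.

    Bins the image to ``n x n``, k-means clusters the cell colors, emits
    one location map per cluster (largest domain first = ink 1), converts
    the maps to stage coordinates, and compiles one round per ink. With
    four inks the fourth carries all three fluorophores (only three
    orthogonal imaging channels exist), matching the pink domain of the
    four-color demonstration.

    Returns ``(protocol, maps, clustering)``.
    """
    if k > 4:
        raise CompilationError(f"k={k} inks exceed the 4 ink ports")
    grid = bin_image(image, n)
    clustering = cluster_colors(grid, k, seed=seed)
    maps = build_location_maps(clustering)
    layout = grids_to_layout(maps, post_um, pitch_um)
    params = params or CompileParams(flow_s=5.0, reflow_s=1.0)
    vials = []
    for d in range(len(maps)):
        if d < 3:
            name, fluor = FLUOR_PALETTE[d]
            strands = [
                StrandSpec(name=name, concentration_nM=500.0, fluorophore=fluor)
            ]
        else:  # fourth ink: all three fluorophores
            strands = [
                StrandSpec(name=nm, concentration_nM=500.0, fluorophore=fl)
                for nm, fl in FLUOR_PALETTE
            ]
        vials.append(InkSpec(vial_id=d + 1, strands=strands, volume_ul=400.0))
    mask = make_rect_mask(post_um, post_um, name=f"pixel{post_um:g}")
    inks = {d: d + 1 for d in range(len(maps))}
    masks = {d: mask for d in range(len(maps))}
    protocol = compile_protocol(layout, inks, masks, vials, params=params)
    return protocol, maps, clustering


def quench_architecture_protocol(
    size_um: float = 100.0,
    pitch_um: float = 200.0,
    quencher_conc_nM: float = 500.0,
    include_quench_step: bool = True,
) -> Protocol:
    """The addressable-hybridization architecture.

    Four domains — circle (Cy3-labeled 5Acry_3Cy3_R1), triangle
    (ATTO488), plus (TYE665), and square (all three strands) — followed,
    optionally, by addition of the quencher-modified complement 5Q_R1'
    which suppresses Cy3 emission only where 5Acry_3Cy3_R1 is anchored
    (circle and square).
    """
    shapes = ["circle", "triangle", "plus", "rect"]
    centers = [(0.0, 0.0), (pitch_um, 0.0), (0.0, pitch_um), (pitch_um, pitch_um)]
    sites = [
        LayoutSite(
            domain_id=d,
            center_x_um=cx,
            center_y_um=cy,
            width_um=size_um,
            height_um=size_um,
            shape=shapes[d],
        )
        for d, (cx, cy) in enumerate(centers)
    ]
    layout = DomainLayout(sites=sites, pitch_um=pitch_um)
    r1 = StrandSpec(name="5Acry_3Cy3_R1", concentration_nM=500.0, fluorophore="Cy3")
    atto = StrandSpec(
        name="5Acry_3ATTO488_polyT10", concentration_nM=500.0, fluorophore="ATTO488"
    )
    tye = StrandSpec(
        name="5Acry_3TYE665_polyT10", concentration_nM=500.0, fluorophore="TYE665"
    )
    vials = [
        InkSpec(vial_id=1, strands=[r1], volume_ul=200.0),
        InkSpec(vial_id=2, strands=[atto], volume_ul=200.0),
        InkSpec(vial_id=3, strands=[tye], volume_ul=200.0),
        InkSpec(vial_id=4, strands=[r1, atto, tye], volume_ul=200.0),
    ]
    masks = {d: make_shape_mask(shapes[d], size_um, name=f"{shapes[d]}{size_um:g}")
             for d in range(4)}
    inks = {0: 1, 1: 2, 2: 3, 3: 4}
    protocol = compile_protocol(layout, inks, masks, vials)
    if include_quench_step:
        protocol.commands.append(
            AddSolution(strands={"5Q_R1'": quencher_conc_nM}, incubation_h=1.0)
        )
    return protocol


@dataclass
class SwellingRunResult:
    """Measured swelling curves plus the raw per-checkpoint measurements."""

    curves: dict[str, SwellingCurve]
    measurements: dict[str, list[Measurement]] = field(default_factory=dict)
    state: ChamberState | None = None


def _crosslinked_ink(
    vial_id: int, system: str, tracer: tuple[str, str], volume_ul: float = 200.0
) -> InkSpec:
    """PEGDA-10K ink with a fluorescent tracer and a DNA crosslink pair."""
    name, fluor = tracer
    return InkSpec(
        vial_id=vial_id,
        monomer_label="PEGDA-10K",
        strands=[
            StrandSpec(name=name, concentration_nM=500.0, fluorophore=fluor),
            StrandSpec(name=f"{system}_crossA", concentration_nM=1000.0,
                       crosslink_role=system),
            StrandSpec(name=f"{system}_crossB", concentration_nM=1000.0,
                       crosslink_role=system),
        ],
        volume_ul=volume_ul,
    )


def single_domain_swelling_experiment(
    seed: int = 0,
    config: RunConfig | None = None,
    L0_um: float = 200.0,
    checkpoint_hours: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 60.0),
) -> SwellingRunResult:
    """Pattern, lift off, collect, and swell one DNA-crosslinked hydrogel.

    A single S1-crosslinked square domain is fabricated on a sacrificial
    layer, lifted off and collected; the S1 hairpin signal pair (20 uM
    final) is then added and the gel imaged at each checkpoint. Lengths
    are measured from the rendered micrographs through the Otsu pipeline
    (default noise model), and dL/L0 is taken against the pre-signal
    baseline. With the default swelling amplitude A_S1 = 0.51 and tau =
    8 h the measured endpoint at 60 h is ~0.51.
    """
    config = config or RunConfig()
    layout = DomainLayout(
        sites=[LayoutSite(domain_id=0, center_x_um=0.0, center_y_um=0.0,
                          width_um=L0_um, height_um=L0_um)],
        pitch_um=L0_um,
    )
    vials = [_crosslinked_ink(1, "S1", FLUOR_PALETTE[0])]
    mask = make_rect_mask(L0_um, L0_um, name=f"square{L0_um:g}")
    protocol = compile_protocol(layout, {0: 1}, {0: mask}, vials)
    protocol.commands += [Dissolve(), Collect()]
    state, _ = execute(protocol, seed=seed, config=config, sacrificial=True)

    rng = np.random.default_rng(seed)
    margin = L0_um  # field large enough for fully swollen gel
    field = (-margin, -margin, 2 * margin, 2 * margin)
    channel = FLUOR_PALETTE[0][1]
    times, lengths, measurements = [], [], []

    t_signal = state.time_h
    for i, h in enumerate(checkpoint_hours):
        if i == 0:
            assert h == 0.0, "first checkpoint must be the pre-signal baseline"
        else:
            advance_time(state, (t_signal + h) - state.time_h, config)
        stack = render(state, config, field_um=field, channels=[channel],
                       seed=int(rng.integers(2**31)))
        m = measure_stack(stack, channel)
        m.time_h = h
        measurements.append(m)
        times.append(h)
        lengths.append(m.length_um)
        if i == 0:
            add_swelling_signal(state, "S1", config)
    curve = swelling_curve(times, lengths)
    return SwellingRunResult(
        curves={"S1": curve}, measurements={"S1": measurements}, state=state
    )


#: Domain color names, fluorophores, and crosslink systems of the
#: three-domain architecture (green, the middle domain, has no crosslinks
#: and never swells).
MULTI_DOMAIN_SPEC = [
    ("red", ("5Acry_3TYE665_polyT10", "TYE665"), "S1"),
    ("green", ("5Acry_3ATTO488_polyT10", "ATTO488"), None),
    ("blue", ("5Acry_3Cy3_polyT10", "Cy3"), "S2"),
]


def multi_domain_swelling_experiment(
    seed: int = 0,
    config: RunConfig | None = None,
    size_um: float = 200.0,
    overlap_um: float = 10.0,
    checkpoint_hours: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 30.0, 36.0, 48.0, 60.0),
    s2_addition_h: float = 24.0,
) -> SwellingRunResult:
    """Sequentially addressable swelling of a three-domain strip.

    Three adjacent 200x200 um domains overlapped by 10 um: red
    (S1-crosslinked), green (no crosslinks, middle), blue
    (S2-crosslinked). The S1 signal is added after the baseline image and
    the S2 signal at ``s2_addition_h``. Each domain is measured in its own
    channel at the edge opposite green (the bounding-box side, which the
    shared-edge constraint does not shorten). Default amplitudes for this
    architecture are the free-edge equilibria A_S1 = 0.4 and A_S2 = 0.6.
    """
    if config is None:
        config = RunConfig(
            swelling=SwellingConfig(amplitude={"S1": 0.4, "S2": 0.6})
        )
    layout = make_strip_layout(3, size_um, overlap_um)
    vials = []
    inks = {}
    for d, (_, tracer, system) in enumerate(MULTI_DOMAIN_SPEC):
        if system is None:
            name, fluor = tracer
            vials.append(InkSpec(
                vial_id=d + 1,
                monomer_label="PEGDA-10K",
                strands=[StrandSpec(name=name, concentration_nM=500.0,
                                    fluorophore=fluor)],
                volume_ul=200.0,
            ))
        else:
            vials.append(_crosslinked_ink(d + 1, system, tracer))
        inks[d] = d + 1
    mask = make_rect_mask(size_um, size_um, name=f"square{size_um:g}")
    masks = {d: mask for d in range(3)}
    protocol = compile_protocol(layout, inks, masks, vials)
    protocol.commands += [Dissolve(), Collect()]
    state, _ = execute(protocol, seed=seed, config=config, sacrificial=True)

    rng = np.random.default_rng(seed)
    span = 2 * (size_um - overlap_um) + size_um  # strip extent in x
    margin = size_um
    field = (-margin, -margin, span + 2 * margin, 2 * margin)
    times: list[float] = []
    lengths: dict[str, list[float]] = {name: [] for name, _, _ in MULTI_DOMAIN_SPEC}
    meas: dict[str, list[Measurement]] = {name: [] for name, _, _ in MULTI_DOMAIN_SPEC}

    t_signal = state.time_h
    s2_added = False
    for i, h in enumerate(checkpoint_hours):
        if i > 0:
            if not s2_added and h >= s2_addition_h:
                advance_time(state, (t_signal + s2_addition_h) - state.time_h, config)
                add_swelling_signal(state, "S2", config)
                s2_added = True
            advance_time(state, (t_signal + h) - state.time_h, config)
        stack = render(state, config, field_um=field, seed=int(rng.integers(2**31)))
        for name, (_, fluor), _sys in MULTI_DOMAIN_SPEC:
            m = measure_stack(stack, fluor)
            m.time_h = h
            meas[name].append(m)
            lengths[name].append(m.length_um)
        times.append(h)
        if i == 0:
            add_swelling_signal(state, "S1", config)
    curves = {
        name: swelling_curve(times, lengths[name], edge_label="opposite-green")
        for name, _, _ in MULTI_DOMAIN_SPEC
    }
    return SwellingRunResult(curves=curves, measurements=meas, state=state)


def liftoff_collection_experiment(
    seed: int = 0,
    n_architectures: int = 25,
    config: RunConfig | None = None,
    size_um: float = 200.0,
    overlap_um: float = 10.0,
) -> dict:
    """Fabricate three-domain architectures with lift-off and collection.

    ``n_architectures`` sites each receive three overlapping domains in
    three patterning rounds on a sacrificial layer; weakly anchored
    architectures may wash away during rounds after their first, the
    survivors are lifted off in the NaCl dissolution step, and free
    architectures are collected with probability ``p_collect``. Returns
    per-architecture outcome counts.
    """
    config = config or RunConfig()
    step = size_um - overlap_um
    site_pitch = 4 * size_um  # well separated sites
    n_cols = int(np.ceil(np.sqrt(n_architectures)))
    sites = []
    for d in range(3):
        for s in range(n_architectures):
            sites.append(LayoutSite(
                domain_id=d,
                center_x_um=(s % n_cols) * site_pitch + d * step,
                center_y_um=(s // n_cols) * site_pitch,
                width_um=size_um,
                height_um=size_um,
            ))
    layout = DomainLayout(sites=sites, pitch_um=site_pitch, overlap_um=overlap_um)
    vials = [
        InkSpec(vial_id=d + 1,
                strands=[StrandSpec(name=nm, concentration_nM=500.0, fluorophore=fl)],
                volume_ul=250.0)
        for d, (nm, fl) in enumerate(FLUOR_PALETTE)
    ]
    mask = make_rect_mask(size_um, size_um, name=f"square{size_um:g}")
    protocol = compile_protocol(
        layout, {0: 1, 1: 2, 2: 3}, {d: mask for d in range(3)}, vials
    )
    protocol.commands += [Dissolve(), Collect()]
    state, events = execute(protocol, seed=seed, config=config, sacrificial=True)

    from .instrument import attached_clusters

    clusters = attached_clusters(
        state.domains, statuses=("attached", "free", "collected", "lost")
    )
    n_lost = sum(1 for c in clusters if any(d.status == "lost" for d in c))
    n_collected = sum(1 for c in clusters if all(d.status == "collected" for d in c))
    return {
        "n_architectures": len(clusters),
        "n_lost_before_liftoff": n_lost,
        "n_survived_to_liftoff": len(clusters) - n_lost,
        "n_collected": n_collected,
        "state": state,
        "events": events,
    }
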