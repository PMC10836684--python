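"""Virtual photopatterning instrument.

Executes a protocol against a simulated microfluidic chamber: flowing ink
decrements vial volumes, patterning photopolymerizes hydrogel domains at
the current stage position, washing flushes the chamber (and may
prematurely detach weakly anchored gels when a sacrificial layer is
present), dissolving the sacrificial layer lifts all gels off, and
collection recovers free gels. Post-fabrication chemistry — hybridization
of free DNA to anchored strands (quenching) and signal-induced
hybridization-chain-reaction swelling — is simulated with simple
saturating first-order kinetics, and synthetic fluorescence micrographs
are rendered from the chamber state.

The swelling law is an explicit stand-in (see docs/methods.md): each
domain edge whose crosslink system has received its hairpin signal
carries strain ``A * (1 - exp(-t / tau))``, reduced by a constant factor
on edges constrained by an attached neighboring domain. No
reaction-diffusion or polymer-network mechanics are modeled.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize

from .config import RunConfig
from .errors import (
    ExecutionError,
    InvalidParameterError,
    UnknownStrandError,
    UnknownVialError,
)
from .micrograph import MicrographStack
from .protocol import Protocol, validate_protocol

__all__ = [
    "DEFAULT_COMPLEMENTS",
    "ChamberContent",
    "ChamberState",
    "HydrogelDomain",
    "add_swelling_signal",
    "advance_time",
    "attached_clusters",
    "domain_edge_lengths",
    "domain_strain",
    "execute",
    "hybridize",
    "render",
    "state_snapshot",
]

#: Watson-Crick pairing of free strands to anchored strands (both directions).
#: 5Q_R1' is the quencher-modified complement of the Cy3-labeled 5Acry_3Cy3_R1.
DEFAULT_COMPLEMENTS: dict[str, str] = {
    "5Q_R1'": "5Acry_3Cy3_R1",
    "5Acry_3Cy3_R1": "5Q_R1'",
}

_SIGNAL_RE = re.compile(r"^(S\d+)_H\d+$")

EDGES = ("left", "right", "top", "bottom")


@dataclass
class HydrogelDomain:
    """One photopolymerized hydrogel post.

    ``width0_um``/``height0_um`` are the as-patterned (original) footprint
    dimensions; for square posts ``L0 == height0_um``. ``composition``
    maps strand name → concentration (nM); ``quenched_fraction`` maps
    strand name → fraction hybridized to a quencher in [0, 1].
    ``constrained_edges`` are edges shared with an attached neighbor,
    which swell at a reduced rate. ``status`` is one of attached / free /
    collected / lost.
    """

    domain_id: int
    center_x_um: float
    center_y_um: float
    width0_um: float
    height0_um: float
    shape: str = "rect"
    composition: dict[str, float] = field(default_factory=dict)
    fluorophores: dict[str, str] = field(default_factory=dict)
    quenched_fraction: dict[str, float] = field(default_factory=dict)
    crosslink_system: Optional[str] = None
    constrained_edges: set[str] = field(default_factory=set)
    patterned_round: int = 0
    status: str = "attached"
    L_um: float = 0.0  # current free-edge side length, refreshed on time steps

    def __post_init__(self) -> None:
        if not self.quenched_fraction:
            self.quenched_fraction = {name: 0.0 for name in self.composition}
        if self.L_um == 0.0:
            self.L_um = self.L0_um

    @property
    def L0_um(self) -> float:
        return self.height0_um

    @property
    def attached(self) -> bool:
        return self.status == "attached"

    def bounds0(self) -> tuple[float, float, float, float]:
        """As-patterned footprint (x0, y0, x1, y1) in um."""
        return (
            self.center_x_um - self.width0_um / 2,
            self.center_y_um - self.height0_um / 2,
            self.center_x_um + self.width0_um / 2,
            self.center_y_um + self.height0_um / 2,
        )


@dataclass(frozen=True)
class ChamberContent:
    kind: str  # "none" | "ink" | "wash" | "solution"
    vial_id: Optional[int] = None
    strands: frozenset = frozenset()


@dataclass
class ChamberState:
    """The virtual device state threaded through execution."""

    vials: dict[int, float]
    wash_vial_id: int = 5
    chamber_content: ChamberContent = field(
        default_factory=lambda: ChamberContent("none")
    )
    domains: list[HydrogelDomain] = field(default_factory=list)
    sacrificial_intact: bool = False
    time_h: float = 0.0
    stage_xy_um: tuple[float, float] = (0.0, 0.0)
    signal_start_h: dict[str, float] = field(default_factory=dict)
    complements: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMPLEMENTS)
    )
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    @classmethod
    def initial(
        cls,
        protocol: Protocol,
        sacrificial: bool = False,
        seed: int = 0,
        complements: dict[str, str] | None = None,
    ) -> "ChamberState":
        vials = {v.vial_id: v.volume_ul for v in protocol.vials}
        # wash buffer is effectively unlimited unless declared as a vial
        vials.setdefault(protocol.wash_vial_id, math.inf)
        table = dict(DEFAULT_COMPLEMENTS)
        if complements:
            table.update(complements)
        return cls(
            vials=vials,
            wash_vial_id=protocol.wash_vial_id,
            sacrificial_intact=sacrificial,
            complements=table,
            rng=np.random.default_rng(seed),
        )

    def domains_with_status(self, status: str) -> list[HydrogelDomain]:
        return [d for d in self.domains if d.status == status]


# --- geometry helpers -----------------------------------------------------

def _rects_touch(a: HydrogelDomain, b: HydrogelDomain, eps: float = 1e-6) -> bool:
    ax0, ay0, ax1, ay1 = a.bounds0()
    bx0, by0, bx1, by1 = b.bounds0()
    return ax0 <= bx1 + eps and bx0 <= ax1 + eps and ay0 <= by1 + eps and by0 <= ay1 + eps


def _mark_constraints(new: HydrogelDomain, other: HydrogelDomain) -> None:
    """Mark the facing edges of two touching footprints as constrained."""
    dx = other.center_x_um - new.center_x_um
    dy = other.center_y_um - new.center_y_um
    if abs(dx) >= abs(dy):
        if dx >= 0:
            new.constrained_edges.add("right")
            other.constrained_edges.add("left")
        else:
            new.constrained_edges.add("left")
            other.constrained_edges.add("right")
    else:
        if dy >= 0:
            new.constrained_edges.add("bottom")
            other.constrained_edges.add("top")
        else:
            new.constrained_edges.add("top")
            other.constrained_edges.add("bottom")


def attached_clusters(
    domains: Iterable[HydrogelDomain], statuses: tuple[str, ...] = ("attached",)
) -> list[list[HydrogelDomain]]:
    """Group domains into mechanically contiguous clusters.

    Overlapping or abutting footprints are contiguous (interfaces formed
    during patterning are strong enough to survive lift-off), so they
    detach and are collected as a unit. Union-find over pairwise
    footprint contact.
    """
    members = [d for d in domains if d.status in statuses]
    parent = list(range(len(members)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if _rects_touch(members[i], members[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[HydrogelDomain]] = {}
    for i, d in enumerate(members):
        groups.setdefault(find(i), []).append(d)
    return list(groups.values())


# --- swelling -------------------------------------------------------------

def domain_strain(domain: HydrogelDomain, state: ChamberState, config: RunConfig) -> float:
    """Free-edge relative swelling of a domain at the current time."""
    sys = domain.crosslink_system
    if sys is None or sys not in state.signal_start_h:
        return 0.0
    dt = state.time_h - state.signal_start_h[sys]
    if dt <= 0:
        return 0.0
    amp = config.swelling.amplitude.get(sys, 0.0)
    return amp * (1.0 - math.exp(-dt / config.swelling.tau_h))


def domain_edge_lengths(
    domain: HydrogelDomain, state: ChamberState, config: RunConfig
) -> dict[str, float]:
    """Side length measured at each edge of a (square/rect) domain.

    A constrained edge swells at ``constrained_edge_factor`` times the
    free-edge strain; the left/right entries are the vertical side
    lengths at those edges, top/bottom the horizontal ones.
    """
    s = domain_strain(domain, state, config)
    c = config.swelling.constrained_edge_factor
    f = {e: (c if e in domain.constrained_edges else 1.0) for e in EDGES}
    return {
        "left": domain.height0_um * (1 + s * f["left"]),
        "right": domain.height0_um * (1 + s * f["right"]),
        "top": domain.width0_um * (1 + s * f["top"]),
        "bottom": domain.width0_um * (1 + s * f["bottom"]),
    }


def _refresh_lengths(state: ChamberState, config: RunConfig) -> None:
    for d in state.domains:
        d.L_um = d.height0_um * (1.0 + domain_strain(d, state, config))


def advance_time(state: ChamberState, dt_h: float, config: RunConfig) -> ChamberState:
    """Advance the chamber clock; swelling strains update lazily from time."""
    if dt_h < 0:
        raise InvalidParameterError(f"negative time step {dt_h}")
    state.time_h += dt_h
    _refresh_lengths(state, config)
    return state


def add_swelling_signal(
    state: ChamberState,
    system: str,
    config: RunConfig,
    final_conc_uM: float | None = None,
) -> ChamberState:
    """Add a hairpin signal pair for one crosslink system at time `now`.

    Domains crosslinked with that system begin to swell; re-adding an
    already active signal is a no-op (the earlier start time stands).
    """
    conc = config.swelling.signal_conc_uM if final_conc_uM is None else final_conc_uM
    if conc <= 0:
        raise InvalidParameterError("signal concentration must be positive")
    state.signal_start_h.setdefault(system, state.time_h)
    _refresh_lengths(state, config)
    return state


def hybridize(
    state: ChamberState,
    strand: str,
    conc_nM: float,
    duration_h: float,
    config: RunConfig,
) -> ChamberState:
    """React a free strand with its anchored complement in every domain.

    The quenched fraction of the complement approaches 1 with first-order
    kinetics, rate ``hybridization_rate_per_nM_h * conc_nM``. Domains not
    containing the complement are untouched; a strand without a
    complement-table entry raises.
    """
    if strand not in state.complements:
        raise UnknownStrandError(strand)
    if conc_nM < 0 or duration_h < 0:
        raise InvalidParameterError("concentration and duration must be >= 0")
    target = state.complements[strand]
    decay = math.exp(-config.simulation.hybridization_rate_per_nM_h * conc_nM * duration_h)
    for d in state.domains:
        if target in d.composition:
            qf = d.quenched_fraction.get(target, 0.0)
            d.quenched_fraction[target] = 1.0 - (1.0 - qf) * decay
    return state


# --- execution ------------------------------------------------------------

def execute(
    protocol: Protocol,
    init: ChamberState | None = None,
    seed: int = 0,
    config: RunConfig | None = None,
    sacrificial: bool = False,
) -> tuple[ChamberState, list[dict]]:
    """Run a protocol against the virtual chamber.

    Returns the final state and a JSON-serializable event log (one entry
    per command, plus detachment/collection events). Execution refuses
    protocols that fail validation, patterning with the wrong chamber
    content, and flowing from an empty or depleted vial. Identical
    (protocol, seed, config) inputs reproduce the state exactly.
    """
    config = config or RunConfig()
    report = validate_protocol(protocol)
    if not report.passed:
        raise ExecutionError(
            "protocol failed validation: "
            + "; ".join(v.message for v in report.violations)
        )
    state = init or ChamberState.initial(protocol, sacrificial=sacrificial, seed=seed)
    events: list[dict] = []
    round_idx = 1
    round_vial: Optional[int] = None
    rate = config.simulation.flow_rate_ul_s

    for step, cmd in enumerate(protocol.commands):
        if cmd.op == "FLOW":
            if cmd.vial_id not in state.vials:
                raise UnknownVialError(cmd.vial_id)
            needed = rate * cmd.duration_s
            remaining = state.vials[cmd.vial_id]
            if remaining <= 0:
                raise ExecutionError(f"FLOW from empty vial {cmd.vial_id}")
            if remaining < needed:
                raise ExecutionError(
                    f"vial {cmd.vial_id} holds {remaining:.1f} uL but FLOW "
                    f"needs {needed:.1f} uL"
                )
            state.vials[cmd.vial_id] = remaining - needed
            if cmd.vial_id == state.wash_vial_id:
                state.chamber_content = ChamberContent("wash")
            else:
                state.chamber_content = ChamberContent("ink", vial_id=cmd.vial_id)
                round_vial = cmd.vial_id
            state.time_h += cmd.duration_s / 3600.0
            events.append(
                {"step": step, "op": "FLOW", "vial_id": cmd.vial_id,
                 "volume_ul": needed}
            )
        elif cmd.op == "MOVE":
            state.stage_xy_um = (cmd.x_um, cmd.y_um)
            events.append({"step": step, "op": "MOVE", "x_um": cmd.x_um, "y_um": cmd.y_um})
        elif cmd.op == "PATTERN":
            content = state.chamber_content
            if content.kind != "ink" or content.vial_id != round_vial or round_vial is None:
                raise ExecutionError(
                    f"PATTERN with chamber content {content.kind!r}; the round's "
                    "ink must fill the chamber before exposure"
                )
            mask = protocol.masks.get(cmd.mask_ref)
            if mask is None:
                raise ExecutionError(f"PATTERN references unknown mask {cmd.mask_ref!r}")
            ink = protocol.vial(content.vial_id)
            bias = config.simulation.bias_for(max(mask.width_um, mask.height_um))
            width0 = mask.width_um + bias
            height0 = mask.height_um + bias
            if width0 <= 0 or height0 <= 0:
                raise ExecutionError("size bias collapsed the domain to zero size")
            crosslink = next(
                (s.crosslink_role for s in ink.strands if s.crosslink_role), None
            )
            domain = HydrogelDomain(
                domain_id=len(state.domains),
                center_x_um=state.stage_xy_um[0],
                center_y_um=state.stage_xy_um[1],
                width0_um=width0,
                height0_um=height0,
                shape=mask.kind,
                composition={s.name: s.concentration_nM for s in ink.strands},
                fluorophores={
                    s.name: s.fluorophore for s in ink.strands if s.fluorophore
                },
                crosslink_system=crosslink,
                patterned_round=round_idx,
            )
            # overlapping regions merge compositions and constrain facing edges
            for other in state.domains:
                if other.attached and _rects_touch(domain, other):
                    _mark_constraints(domain, other)
            state.domains.append(domain)
            state.time_h += cmd.exposure_s / 3600.0
            events.append(
                {"step": step, "op": "PATTERN", "domain_id": domain.domain_id,
                 "mask": cmd.mask_ref, "vial_id": content.vial_id,
                 "round": round_idx}
            )
        elif cmd.op == "WASH":
            state.chamber_content = ChamberContent("wash")
            state.time_h += cmd.duration_s / 3600.0
            lost_ids: list[int] = []
            if state.sacrificial_intact and config.simulation.p_washoff > 0:
                for cluster in attached_clusters(state.domains):
                    # only gels surviving from earlier rounds are at risk:
                    # a round's own wash never removes its fresh gel
                    if not any(d.patterned_round < round_idx for d in cluster):
                        continue
                    if state.rng.random() < config.simulation.p_washoff:
                        for d in cluster:
                            d.status = "lost"
                            lost_ids.append(d.domain_id)
            events.append(
                {"step": step, "op": "WASH", "round": round_idx,
                 "lost_domain_ids": lost_ids}
            )
            round_idx += 1
            round_vial = None
        elif cmd.op == "ADD_SOLUTION":
            for name, conc in cmd.strands.items():
                m = _SIGNAL_RE.match(name)
                if m:
                    add_swelling_signal(state, m.group(1), config, conc / 1000.0)
                else:
                    hybridize(state, name, conc, cmd.incubation_h, config)
            state.chamber_content = ChamberContent(
                "solution", strands=frozenset(cmd.strands)
            )
            advance_time(state, cmd.incubation_h, config)
            events.append(
                {"step": step, "op": "ADD_SOLUTION",
                 "strands": dict(cmd.strands), "incubation_h": cmd.incubation_h}
            )
        elif cmd.op == "DISSOLVE_SACRIFICIAL":
            if not state.sacrificial_intact:
                raise ExecutionError("no intact sacrificial layer to dissolve")
            state.sacrificial_intact = False
            freed = []
            for d in state.domains:
                if d.attached:
                    d.status = "free"
                    freed.append(d.domain_id)
            state.time_h += cmd.duration_s / 3600.0
            events.append(
                {"step": step, "op": "DISSOLVE_SACRIFICIAL", "freed_domain_ids": freed}
            )
        elif cmd.op == "COLLECT":
            collected = []
            for cluster in attached_clusters(state.domains, statuses=("free",)):
                if state.rng.random() < config.simulation.p_collect:
                    for d in cluster:
                        d.status = "collected"
                        collected.append(d.domain_id)
            events.append(
                {"step": step, "op": "COLLECT", "collected_domain_ids": collected}
            )
        else:  # pragma: no cover - pydantic union is exhaustive
            raise ExecutionError(f"unknown command {cmd.op!r}")
    _refresh_lengths(state, config)
    return state, events


def state_snapshot(state: ChamberState) -> dict:
    """JSON-serializable snapshot of the chamber state."""
    return {
        "time_h": state.time_h,
        "vials_ul": {str(k): (None if math.isinf(v) else v)
                     for k, v in state.vials.items()},
        "chamber_content": state.chamber_content.kind,
        "sacrificial_intact": state.sacrificial_intact,
        "signal_start_h": dict(state.signal_start_h),
        "domains": [
            {
                "domain_id": d.domain_id,
                "center_um": [d.center_x_um, d.center_y_um],
                "size0_um": [d.width0_um, d.height0_um],
                "L_um": d.L_um,
                "shape": d.shape,
                "status": d.status,
                "patterned_round": d.patterned_round,
                "crosslink_system": d.crosslink_system,
                "constrained_edges": sorted(d.constrained_edges),
                "composition_nM": dict(d.composition),
                "quenched_fraction": dict(d.quenched_fraction),
            }
            for d in state.domains
        ],
    }


# --- rendering ------------------------------------------------------------

def _domain_footprint_polygon(
    domain: HydrogelDomain, state: ChamberState, config: RunConfig
) -> np.ndarray:
    """Quadrilateral (x, y) vertices of a swollen rectangular domain.

    Per-edge strains turn the square into a trapezoid: the vertical extent
    at the left/right edge and the horizontal extent at the top/bottom
    edge each equal that edge's side length.
    """
    e = domain_edge_lengths(domain, state, config)
    cx, cy = domain.center_x_um, domain.center_y_um
    return np.array(
        [
            [cx - e["top"] / 2, cy - e["left"] / 2],      # top-left
            [cx + e["top"] / 2, cy - e["right"] / 2],     # top-right
            [cx + e["bottom"] / 2, cy + e["right"] / 2],  # bottom-right
            [cx - e["bottom"] / 2, cy + e["left"] / 2],   # bottom-left
        ]
    )


def render(
    state: ChamberState,
    config: RunConfig | None = None,
    field_um: tuple[float, float, float, float] = (0.0, 0.0, 512.0, 512.0),
    channels: list[str] | None = None,
    seed: int = 0,
    statuses: tuple[str, ...] = ("attached", "free", "collected"),
) -> MicrographStack:
    """Render a synthetic multi-channel fluorescence micrograph.

    Per channel, pixel intensity = background + sum over covering domains
    of ``gain * concentration * (1 - quenched_fraction)`` for strands
    labeled with that channel's fluorophore, plus Gaussian noise, clipped
    at zero. Deterministic for a fixed seed. ``field_um`` is
    (x0, y0, width, height) in stage micrometers.
    """
    config = config or RunConfig()
    optics = config.optics
    x0, y0, fw, fh = field_um
    ps = optics.pixel_size_um
    shape = (max(1, round(fh / ps)), max(1, round(fw / ps)))
    visible = [d for d in state.domains if d.status in statuses]
    if channels is None:
        channels = sorted({ch for d in visible for ch in d.fluorophores.values()})
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    masks_px: list[tuple[HydrogelDomain, tuple[np.ndarray, np.ndarray]]] = []
    for d in visible:
        if d.shape == "rect":
            poly = _domain_footprint_polygon(d, state, config)
            rr, cc = draw_polygon((poly[:, 1] - y0) / ps, (poly[:, 0] - x0) / ps, shape)
        else:
            s = domain_strain(d, state, config)
            bitmap = _shape_array(d)
            h_px = max(1, round(d.height0_um * (1 + s) / ps))
            w_px = max(1, round(d.width0_um * (1 + s) / ps))
            scaled = resize(bitmap, (h_px, w_px), order=0, preserve_range=True) > 0.5
            r_off = round((d.center_y_um - y0) / ps - h_px / 2)
            c_off = round((d.center_x_um - x0) / ps - w_px / 2)
            rr, cc = np.nonzero(scaled)
            rr = rr + r_off
            cc = cc + c_off
            keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            rr, cc = rr[keep], cc[keep]
        masks_px.append((d, (rr, cc)))
    for ch in channels:
        img = np.full(shape, float(optics.background))
        for d, (rr, cc) in masks_px:
            signal = sum(
                conc * (1.0 - d.quenched_fraction.get(name, 0.0))
                for name, conc in d.composition.items()
                if d.fluorophores.get(name) == ch
            )
            if signal > 0:
                img[rr, cc] += optics.gain * signal
        if optics.noise_sigma > 0:
            img = img + rng.normal(0.0, optics.noise_sigma, size=shape)
        out[ch] = np.clip(img, 0.0, None)
    return MicrographStack(
        channels=out,
        pixel_size_um=ps,
        time_h=state.time_h,
        field_origin_um=(x0, y0),
    )


def _shape_array(d: HydrogelDomain) -> np.ndarray:
    from .protocol import _shape_bitmap

    h = max(1, round(d.height0_um))
    w = max(1, round(d.width0_um))
    kind = d.shape if d.shape in ("circle", "triangle", "plus") else "rect"
    return _shape_bitmap(kind, h, w).astype(float)
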