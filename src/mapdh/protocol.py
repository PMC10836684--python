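"""Protocol compilation, validation, and (de)serialization.

A patterning *protocol* is an ordered command stream executed by the
instrument (real or virtual). The round grammar mirrors automated
photopatterning practice: a round uses exactly one ink vial and consists of

1. ``FLOW`` — fill the chamber with that vial's ink,
2. *printing* — for each site: ``MOVE`` the stage, briefly re-``FLOW`` the
   same ink (a few seconds, which keeps patterned-size variance low), then
   ``PATTERN`` (project a DMD mask and expose), and
3. ``WASH`` — flush the chamber with buffer.

A wash is emitted after every round, including the last. Lift-off
protocols append ``DISSOLVE_SACRIFICIAL`` (1 M NaCl dissolves the
poly(acrylic acid) sacrificial layer) and ``COLLECT``.

Protocols serialize to versioned JSON (canonical) and parse from JSON or
YAML; unknown fields are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Annotated, Literal, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import (
    CompilationError,
    InvalidParameterError,
    ProtocolParseError,
    UnknownVialError,
)
from .layout import DomainLayout

__all__ = [
    "SCHEMA_VERSION",
    "AddSolution",
    "Collect",
    "CompileParams",
    "Dissolve",
    "Flow",
    "HardwareProfile",
    "InkSpec",
    "Mask",
    "Move",
    "Pattern",
    "Protocol",
    "StrandSpec",
    "ValidationReport",
    "Violation",
    "Wash",
    "compile_protocol",
    "estimate_ink_usage",
    "iter_rounds",
    "make_rect_mask",
    "make_shape_mask",
    "parse_protocol",
    "serialize_protocol",
    "validate_protocol",
]

SCHEMA_VERSION = "mapdh-protocol/1"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StrandSpec(_Model):
    """One DNA strand in an ink: name, concentration, optional fluorophore
    label (imaging channel) and crosslink role (swelling system S1/S2)."""

    name: str
    concentration_nM: float = Field(ge=0)
    fluorophore: Optional[str] = None
    acrydite: bool = True
    crosslink_role: Optional[str] = None


class InkSpec(_Model):
    """A pre-gel ink vial: monomer + photoinitiator + acrydite-DNA strands.

    The base formulation is 10 v/v% PEGDA (575 or 10K MW) with 1 w/v% LAP
    photoinitiator in 1X TAEM buffer.
    """

    vial_id: int
    monomer_label: str = "PEGDA-575"
    monomer_vv_percent: float = Field(default=10.0, ge=0)
    photoinitiator_label: str = "LAP"
    photoinitiator_wv_percent: float = Field(default=1.0, ge=0)
    strands: list[StrandSpec] = Field(default_factory=list)
    volume_ul: float = Field(default=200.0, ge=0)


class Mask(_Model):
    """A DMD illumination mask.

    Rectangles (and the named shapes circle / triangle / plus) are stored
    as micrometer dimensions and rasterized on demand at the DMD pixel
    size; arbitrary masks carry an explicit binary bitmap.
    """

    name: str
    kind: Literal["rect", "circle", "triangle", "plus", "bitmap"] = "rect"
    width_um: float = Field(gt=0)
    height_um: float = Field(gt=0)
    pixel_size_um: float = Field(default=1.0, gt=0)
    bitmap: Optional[list[list[int]]] = None

    def to_array(self) -> np.ndarray:
        """Rasterize to a binary uint8 array in DMD-pixel space."""
        if self.kind == "bitmap":
            if not self.bitmap:
                raise InvalidParameterError(f"mask {self.name!r} has no bitmap")
            arr = np.asarray(self.bitmap, dtype=np.uint8)
        else:
            w = round(self.width_um / self.pixel_size_um)
            h = round(self.height_um / self.pixel_size_um)
            if w < 1 or h < 1:
                raise InvalidParameterError(
                    f"mask {self.name!r} rounds to zero pixels at "
                    f"{self.pixel_size_um} um/px"
                )
            arr = _shape_bitmap(self.kind, h, w)
        if arr.sum() < 1:
            raise InvalidParameterError(f"mask {self.name!r} has no on-pixels")
        return arr


def _shape_bitmap(kind: str, h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if kind == "rect":
        return np.ones((h, w), dtype=np.uint8)
    if kind == "circle":
        r = min(h, w) / 2.0
        return (((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r).astype(np.uint8)
    if kind == "triangle":  # upward-pointing isoceles filling the box
        frac = yy / max(h - 1, 1)
        return (np.abs(xx - cx) <= frac * (w / 2.0)).astype(np.uint8)
    if kind == "plus":  # two crossed bars, each a third of the box wide
        bar = ((np.abs(xx - cx) <= w / 6.0) | (np.abs(yy - cy) <= h / 6.0))
        return bar.astype(np.uint8)
    raise InvalidParameterError(f"unknown mask kind {kind!r}")


def make_rect_mask(
    width_um: float, height_um: float, pixel_size_um: float = 1.0, name: str | None = None
) -> Mask:
    """Build a centered rectangular mask; errors if it rounds to zero pixels."""
    if width_um <= 0 or height_um <= 0 or pixel_size_um <= 0:
        raise InvalidParameterError("mask dimensions and pixel size must be positive")
    m = Mask(
        name=name or f"rect_{width_um:g}x{height_um:g}um",
        kind="rect",
        width_um=width_um,
        height_um=height_um,
        pixel_size_um=pixel_size_um,
    )
    m.to_array()  # validate now
    return m


def make_shape_mask(
    kind: str, size_um: float, pixel_size_um: float = 1.0, name: str | None = None
) -> Mask:
    """Build a named-shape mask (rect, circle, triangle, plus) of given size."""
    m = Mask(
        name=name or f"{kind}_{size_um:g}um",
        kind=kind,  # type: ignore[arg-type]
        width_um=size_um,
        height_um=size_um,
        pixel_size_um=pixel_size_um,
    )
    m.to_array()
    return m


# --- commands -------------------------------------------------------------

class Flow(_Model):
    op: Literal["FLOW"] = "FLOW"
    vial_id: int
    duration_s: float = Field(gt=0)


class Move(_Model):
    op: Literal["MOVE"] = "MOVE"
    x_um: float
    y_um: float


class Pattern(_Model):
    op: Literal["PATTERN"] = "PATTERN"
    mask_ref: str
    exposure_s: float = Field(gt=0)
    intensity_label: str = "UV-100%"


class Wash(_Model):
    op: Literal["WASH"] = "WASH"
    duration_s: float = Field(gt=0)


class AddSolution(_Model):
    """Introduce free DNA at final concentrations (nM) for incubation."""

    op: Literal["ADD_SOLUTION"] = "ADD_SOLUTION"
    strands: dict[str, float]
    incubation_h: float = Field(default=1.0, gt=0)


class Dissolve(_Model):
    op: Literal["DISSOLVE_SACRIFICIAL"] = "DISSOLVE_SACRIFICIAL"
    duration_s: float = Field(default=3600.0, gt=0)


class Collect(_Model):
    op: Literal["COLLECT"] = "COLLECT"


Command = Annotated[
    Union[Flow, Move, Pattern, Wash, AddSolution, Dissolve, Collect],
    Field(discriminator="op"),
]


class HardwareProfile(_Model):
    """Static instrument limits: ink ports (a 5th port is the wash line),
    plumbing dead volume, and DMD projection pixel size."""

    n_ink_ports: int = Field(default=4, ge=1)
    dead_volume_ul: float = Field(default=30.0, ge=0)
    pixel_size_um: float = Field(default=1.0, gt=0)


class Protocol(_Model):
    schema_version: Literal["mapdh-protocol/1"] = SCHEMA_VERSION
    commands: list[Command] = Field(default_factory=list)
    vials: list[InkSpec] = Field(default_factory=list)
    wash_vial_id: int = 5
    hardware_profile: HardwareProfile = Field(default_factory=HardwareProfile)
    masks: dict[str, Mask] = Field(default_factory=dict)

    def vial(self, vial_id: int) -> InkSpec:
        for v in self.vials:
            if v.vial_id == vial_id:
                return v
        raise UnknownVialError(vial_id)

    @property
    def n_rounds(self) -> int:
        return sum(1 for c in self.commands if c.op == "WASH")

    @property
    def n_patterns(self) -> int:
        return sum(1 for c in self.commands if c.op == "PATTERN")


def iter_rounds(p: Protocol) -> list[list[Command]]:
    """Split the command stream into maximal FLOW...WASH round segments.

    Commands after the last WASH (lift-off / collection stages) form a
    trailing segment only if non-empty.
    """
    rounds: list[list[Command]] = []
    current: list[Command] = []
    for c in p.commands:
        current.append(c)
        if c.op == "WASH":
            rounds.append(current)
            current = []
    if current:
        rounds.append(current)
    return rounds


class CompileParams(_Model):
    """Durations used when expanding a layout into commands.

    ``reflow_s`` is the brief same-ink flow before each exposure;
    ``exposure_s`` defaults to 1 s (the short exposure used for
    LAP-initiated DNA-crosslinked inks, and a sensible default for the
    rest)."""

    flow_s: float = Field(default=10.0, gt=0)
    reflow_s: float = Field(default=3.0, gt=0)
    exposure_s: float = Field(default=1.0, gt=0)
    wash_s: float = Field(default=30.0, gt=0)
    intensity_label: str = "UV-100%"


def compile_protocol(
    layout: DomainLayout,
    inks: dict[int, int],
    masks: dict[int, Mask],
    vials: list[InkSpec],
    params: CompileParams | None = None,
    wash_vial_id: int = 5,
    hardware_profile: HardwareProfile | None = None,
) -> Protocol:
    """Compile a layout plus domain→vial and domain→mask assignments into a
    protocol.

    One round is emitted per layout domain (ascending domain id): FLOW the
    domain's vial, then per site MOVE / re-FLOW / PATTERN, then WASH. The
    terminal round is washed too. Compilation is deterministic and
    order-stable.
    """
    params = params or CompileParams()
    hardware_profile = hardware_profile or HardwareProfile()
    declared = {v.vial_id for v in vials}
    commands: list[Command] = []
    mask_registry: dict[str, Mask] = {}
    for domain_id in layout.domain_ids:
        if domain_id not in inks:
            raise CompilationError(f"domain {domain_id} has no ink vial assigned")
        if domain_id not in masks:
            raise CompilationError(f"domain {domain_id} has no mask assigned")
        vial_id = inks[domain_id]
        if vial_id not in declared:
            raise CompilationError(
                f"domain {domain_id} maps to undeclared vial {vial_id}"
            )
        mask = masks[domain_id]
        mask_registry[mask.name] = mask
        commands.append(Flow(vial_id=vial_id, duration_s=params.flow_s))
        for site in layout.sites_of(domain_id):
            commands.append(Move(x_um=site.center_x_um, y_um=site.center_y_um))
            commands.append(Flow(vial_id=vial_id, duration_s=params.reflow_s))
            commands.append(
                Pattern(
                    mask_ref=mask.name,
                    exposure_s=params.exposure_s,
                    intensity_label=params.intensity_label,
                )
            )
        commands.append(Wash(duration_s=params.wash_s))
    distinct_inks = {c.vial_id for c in commands if c.op == "FLOW"}
    if len(distinct_inks) > hardware_profile.n_ink_ports:
        raise CompilationError(
            f"{len(distinct_inks)} distinct ink vials exceed the "
            f"{hardware_profile.n_ink_ports} ink ports"
        )
    return Protocol(
        commands=commands,
        vials=vials,
        wash_vial_id=wash_vial_id,
        hardware_profile=hardware_profile,
        masks=mask_registry,
    )


class Violation(_Model):
    code: str
    message: str


class ValidationReport(_Model):
    passed: bool
    violations: list[Violation] = Field(default_factory=list)

    def codes(self) -> set[str]:
        return {v.code for v in self.violations}


#: Vials below this volume are flagged; automated patterning is reliable
#: down to 100 uL (with a documented override down to 50 uL).
DEFAULT_MIN_WORKING_VOLUME_UL = 100.0


def validate_protocol(
    p: Protocol, min_working_volume_ul: float = DEFAULT_MIN_WORKING_VOLUME_UL
) -> ValidationReport:
    """Check a protocol against instrument limits and the round grammar.

    Flags: more distinct ink vials than ink ports; ink vials below the
    minimum working volume; PATTERN commands with no FLOW since the last
    WASH ("pattern without ink"); more than one distinct ink within a
    round; a missing terminal WASH; and unresolved mask or vial
    references. Returns an itemized pass/fail report rather than raising.
    """
    violations: list[Violation] = []
    declared = {v.vial_id for v in p.vials}

    ink_vials = {c.vial_id for c in p.commands if c.op == "FLOW"} - {p.wash_vial_id}
    if len(ink_vials) > p.hardware_profile.n_ink_ports:
        violations.append(
            Violation(
                code="ink ports exceeded",
                message=f"{len(ink_vials)} distinct ink vials used but only "
                f"{p.hardware_profile.n_ink_ports} ink ports available",
            )
        )
    for v in p.vials:
        if v.vial_id in ink_vials and v.volume_ul < min_working_volume_ul:
            violations.append(
                Violation(
                    code="volume below minimum",
                    message=f"vial {v.vial_id} holds {v.volume_ul} uL, below the "
                    f"{min_working_volume_ul} uL minimum working volume",
                )
            )
    for c in p.commands:
        if c.op == "FLOW" and c.vial_id not in declared and c.vial_id != p.wash_vial_id:
            violations.append(
                Violation(
                    code="unknown vial",
                    message=f"FLOW references undeclared vial {c.vial_id}",
                )
            )
        if c.op == "PATTERN" and c.mask_ref not in p.masks:
            violations.append(
                Violation(
                    code="unknown mask",
                    message=f"PATTERN references unknown mask {c.mask_ref!r}",
                )
            )

    # round grammar
    flowed: set[int] = set()
    saw_pattern_cmd = False
    pattern_after_last_wash = False
    for c in p.commands:
        if c.op == "FLOW":
            flowed.add(c.vial_id)
        elif c.op == "PATTERN":
            saw_pattern_cmd = True
            pattern_after_last_wash = True
            round_inks = flowed - {p.wash_vial_id}
            if not round_inks:
                violations.append(
                    Violation(
                        code="pattern without ink",
                        message="PATTERN with no ink FLOW since the last WASH",
                    )
                )
            elif len(round_inks) > 1:
                violations.append(
                    Violation(
                        code="multiple inks in round",
                        message=f"round flows {sorted(round_inks)} before PATTERN; "
                        "a round must use exactly one ink vial",
                    )
                )
        elif c.op == "WASH":
            flowed = set()
            pattern_after_last_wash = False
    if saw_pattern_cmd and pattern_after_last_wash:
        violations.append(
            Violation(
                code="missing terminal wash",
                message="the final patterning round is not followed by a WASH",
            )
        )
    return ValidationReport(passed=not violations, violations=violations)


def estimate_ink_usage(p: Protocol, flow_rate_ul_s: float) -> dict[int, float]:
    """Estimate per-vial consumption in uL: flow rate x total FLOW seconds.

    All declared vials (plus the wash vial) are reported, including unused
    ones at 0 uL. FLOWs from undeclared vials raise.
    """
    if flow_rate_ul_s <= 0:
        raise InvalidParameterError("flow rate must be positive")
    usage = {v.vial_id: 0.0 for v in p.vials}
    usage.setdefault(p.wash_vial_id, 0.0)
    for c in p.commands:
        if c.op == "FLOW":
            if c.vial_id not in usage:
                raise UnknownVialError(c.vial_id)
            usage[c.vial_id] += flow_rate_ul_s * c.duration_s
    return usage


def serialize_protocol(p: Protocol, path: str | Path | None = None) -> str:
    """Serialize to canonical, schema-versioned JSON (optionally to a file)."""
    text = json.dumps(p.model_dump(mode="json"), indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_protocol(source: str | Path) -> Protocol:
    """Parse a protocol from a JSON (canonical) or YAML file or string.

    Unknown fields, missing sections, and schema-version mismatches are
    rejected with field context in the error message.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ProtocolParseError(f"not valid JSON or YAML: {e}") from e
    if not isinstance(data, dict):
        raise ProtocolParseError("protocol file must contain a mapping at top level")
    if "vials" not in data:
        raise ProtocolParseError("protocol file is missing the 'vials' section")
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ProtocolParseError(
            f"unsupported schema_version {version!r}; expected {SCHEMA_VERSION!r}"
        )
    try:
        return Protocol.model_validate(data)
    except ValidationError as e:
        locs = "; ".join(
            "/".join(str(x) for x in err["loc"]) + ": " + err["msg"]
            for err in e.errors()[:5]
        )
        raise ProtocolParseError(f"protocol does not match schema: {locs}") from e
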