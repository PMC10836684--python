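"""Exception hierarchy.

Errors are grouped by pipeline stage so the CLI can map them onto distinct
exit codes: validation problems (bad parameters, bad protocol grammar),
execution problems (the virtual chamber refusing a command), and I/O or
parsing problems.
"""


class MAPDHError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MAPDHError, ValueError):
    """A scalar argument is out of its documented range."""


class InvalidInputError(MAPDHError, ValueError):
    """An input array/image violates a structural precondition."""


class CompilationError(MAPDHError):
    """A layout cannot be compiled into a protocol (e.g. unmapped domain)."""


class ProtocolParseError(MAPDHError):
    """A protocol file is malformed or does not match the schema."""


class ExecutionError(MAPDHError):
    """The virtual instrument refused a command (wrong chamber content,
    empty vial, dissolving an absent sacrificial layer, ...)."""


class UnknownStrandError(MAPDHError, KeyError):
    """A DNA strand has no entry in the complement table."""


class UnknownChannelError(MAPDHError, KeyError):
    """A fluorescence channel label is not present in a micrograph stack."""


class UnknownVialError(MAPDHError, KeyError):
    """A vial id is referenced that the protocol does not declare."""


class UnknownFixtureError(MAPDHError, KeyError):
    """Requested synthetic fixture name is not registered."""


class DegenerateImageError(MAPDHError, ValueError):
    """An image is constant, so no threshold separates two classes."""


class NoObjectError(MAPDHError, ValueError):
    """Binarization produced no foreground object to measure."""
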