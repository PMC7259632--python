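"""Exception hierarchy shared across the package."""


class TurnprintError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(TurnprintError):
    """Malformed record in a PDB document; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class PDBFormatError(TurnprintError):
    """A value cannot be represented in the fixed-width PDB columns."""


class TopologyError(TurnprintError):
    """Frames of a trajectory do not share one topology."""


class SelectionError(TurnprintError):
    """A required residue or atom is absent from the structure."""


class DegenerateInputError(TurnprintError):
    """Input too small or degenerate for the requested computation."""


class RadiusError(TurnprintError):
    """No van der Waals radius is available for an element."""


class FeasibilityError(TurnprintError):
    """Requested synthetic geometry is not realizable."""


class PlacementError(TurnprintError):
    """Requested synthetic contact cannot be placed without side effects."""
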