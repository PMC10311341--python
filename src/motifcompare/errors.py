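"""Exception hierarchy for motifcompare."""


class MotifCompareError(Exception):
    """Base class for all package errors."""


class LocationParseError(MotifCompareError):
    """A motif-location record could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructureError(MotifCompareError):
    """Unreadable structure file or a structure without nucleic-acid residues."""


class MissingResidueError(MotifCompareError):
    """A motif location references a residue absent from the structure."""


class ContractError(MotifCompareError):
    """An operation was called with inputs violating its contract."""


class DegenerateGeometryError(MotifCompareError):
    """Superposition was requested on degenerate (too few / collinear) points."""


class TooShortError(MotifCompareError):
    """Motif too short for coordinate alignment."""


class UndefinedRMSDError(MotifCompareError):
    """RMSD requested with zero usable atom pairs."""
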