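"""Exception hierarchy for dnajconf."""


class DnajconfError(Exception):
    """Base class for all package errors."""


class PDBParseError(DnajconfError):
    """A PDB record could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message, line_number=None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class TopologyError(DnajconfError):
    """Frames of a trajectory do not share an identical topology."""


class SchemeError(DnajconfError):
    """A domain scheme is invalid or missing a required region."""


class ContactError(DnajconfError):
    """Invalid input to a contact-analysis operation."""


class GenerationError(DnajconfError):
    """The synthetic-conformer generator failed to place a chain."""


class RestraintError(DnajconfError):
    """A cross-link restraint table is malformed or unsatisfiable."""
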