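"""Exception hierarchy shared across the package."""


class SigmaSwitchError(Exception):
    """Base class for all package errors."""


class InputError(SigmaSwitchError):
    """Invalid argument values or inconsistent inputs."""


class FormatError(SigmaSwitchError):
    """Malformed file content (FASTA/GFF3/TSV)."""


class SelectionError(SigmaSwitchError):
    """An atom selection resolved to the wrong number of atoms."""


class DegeneracyError(SigmaSwitchError):
    """A numerical operation received a degenerate input set."""


class GenerationError(SigmaSwitchError):
    """The synthetic-data generator could not satisfy its design."""
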