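"""Exception hierarchy for the package.

Every error raised by the public API derives from :class:`TraitPhyloError`
so callers can catch pipeline failures with a single except clause.
"""


class TraitPhyloError(Exception):
    """Base class for all package errors."""


class FormatError(TraitPhyloError):
    """Malformed input file (bad symbol, unparseable newick, ...)."""


class ValidationError(TraitPhyloError):
    """Structurally invalid object (duplicate taxa, mismatched tip sets, ...)."""


class MissingReferenceError(TraitPhyloError):
    """A label refers to a taxon/character/level that does not exist."""


class ParameterError(TraitPhyloError):
    """A model parameter outside its admissible domain."""


class DegenerateInputError(TraitPhyloError):
    """Input that makes the requested computation meaningless
    (empty character selection, zero-depth tree, constant trait vector)."""


class SimulationFailureError(TraitPhyloError):
    """Forward simulation could not satisfy its conditioning after
    the configured number of retries."""
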