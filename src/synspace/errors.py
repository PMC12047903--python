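"""Exception hierarchy for the synspace toolkit.

Every error raised on purpose by the library derives from :class:`SynspaceError`,
so callers can catch the whole family with one clause. Parsing of predictor
output never raises -- malformed text is reported through validity flags
instead (see :mod:`synspace.corpus`).
"""


class SynspaceError(Exception):
    """Base class for all synspace errors."""


class InvalidSmiles(SynspaceError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"invalid SMILES: {smiles!r}")


class EmptyCatalog(SynspaceError):
    """A building-block file produced zero valid records."""


class InvalidTemplate(SynspaceError):
    """A reaction SMARTS failed to parse or violates slot constraints."""


class NoFeasibleReaction(SynspaceError):
    """No template has every reactant slot covered by the catalog."""


class SamplingExhausted(SynspaceError):
    """The route sampler hit its dead-end retry budget."""


class ReplayFailure(SynspaceError):
    """A recorded product is not reproduced when the route is re-executed.

    ``step_index`` is the 0-based forward index of the failing step.
    """

    def __init__(self, step_index: int, message: str = ""):
        self.step_index = step_index
        super().__init__(message or f"route replay failed at step {step_index}")


class UnknownTemplate(SynspaceError):
    """A template id or SMARTS is not present in the registry."""


class UnknownTarget(SynspaceError):
    """The perfect oracle was asked about a molecule outside its corpus."""


class PredictorUnavailable(SynspaceError):
    """A remote predictor endpoint could not be reached."""


class UnassignableReaction(SynspaceError):
    """No permutation of a reaction's reactants matches the template slots."""


class EmptyCandidateSet(SynspaceError):
    """Nearest-neighbour search produced no usable candidate for a slot."""


class NoProducts(SynspaceError):
    """Applying a template to matched reactants yielded no valid product."""


class ReconstructionFailed(SynspaceError):
    """No building-block combination survived forward replay."""


class CoreNotInTarget(SynspaceError):
    """The fixed core given to hit expansion is not a substructure of the target."""


class IOFailure(SynspaceError):
    """A corpus file could not be read or written."""
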