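"""Exception hierarchy shared across the pipeline stages."""


class FBDRankError(Exception):
    """Base class for all package errors."""


class ParseError(FBDRankError):
    """An input file could not be parsed into valid domain objects."""


class ValidationError(FBDRankError):
    """A domain invariant was violated."""


class PropagationError(FBDRankError):
    """The transform of a Monte Carlo propagation failed on a draw."""


class ModelInconsistencyError(FBDRankError):
    """Elicited inputs are mutually incoherent beyond repair (e.g. most
    joint draws have more deaths than cases)."""


class RankingError(FBDRankError):
    """Group-ranking inputs violate the consensus-procedure contract."""


class AttributionError(FBDRankError):
    """Attribution matrix or expert-response invariants violated."""


class PrioritizationError(FBDRankError):
    """Value-chain configuration or point allocation is inconsistent."""
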