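"""Exception hierarchy shared across the package."""


class AnkPredError(Exception):
    """Base class for all package-specific errors."""


class InputError(AnkPredError):
    """A coordinate or assignment file could not be read."""


class EmptyStructureError(InputError):
    """The file contains no usable C-alpha atoms."""


class MissingChainError(AnkPredError):
    """Requested chain id is not present in the structure."""

    def __init__(self, chain_id: str, available: list[str]):
        self.chain_id = chain_id
        self.available = list(available)
        super().__init__(
            f"chain {chain_id!r} not found; available chains: "
            f"{', '.join(available) or '(none)'}"
        )


class DegenerateStructureError(AnkPredError):
    """Fewer than two residues: no contact network can be built."""


class ComputationError(AnkPredError):
    """A numerical routine failed to meet its accuracy contract."""


class AssignmentMissingError(AnkPredError):
    """No secondary-structure records found for the requested chain."""


class TooShortChainError(AnkPredError):
    """Chain too short for the geometric secondary-structure assigner."""


class DegenerateProfileError(AnkPredError):
    """A repeat profile slice is all zero and cannot be normalized."""


class TooFewPointsError(AnkPredError):
    """Fewer than three points: rigid superposition is ill-posed."""


class FixtureConstructionError(AnkPredError):
    """A synthetic-fixture spec produced a self-clashing geometry."""
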