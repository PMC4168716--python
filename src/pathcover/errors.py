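"""Exception hierarchy shared across the package."""


class PathCoverError(Exception):
    """Base class for all package errors."""


class CycleError(PathCoverError):
    """The input graph is not acyclic."""


class FormatError(PathCoverError):
    """An instance or solution file is syntactically malformed."""


class ValidationError(PathCoverError):
    """An instance violates a structural invariant (bad subpath, missing edge, ...)."""


class InfeasibleError(PathCoverError):
    """No solution satisfies the constraints (e.g. a required element off every S-T route)."""


class MergeError(PathCoverError):
    """A merged subpath constraint is not a path of the graph; signals corrupted state."""


class LiftError(PathCoverError):
    """A lifted cover fails verification against the original constraints; signals a bug."""


class DecompositionError(PathCoverError):
    """A flow handed to the path decomposition violates conservation; signals a bug."""


class RealizationError(PathCoverError):
    """A pairwise-compatible constraint class admits no single witness path."""


class LimitError(PathCoverError):
    """A configured size budget (FPT budget, oracle budget) was exceeded."""


class GadgetError(PathCoverError):
    """The hardness-gadget source graph is unusable (bipartite or has isolated vertices)."""
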