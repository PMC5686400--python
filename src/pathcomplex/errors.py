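"""Exception hierarchy.

A *false verdict* (e.g. "these two pieces do not construct the target") is a
legitimate result and is returned as a boolean; exceptions are reserved for
inputs that are malformed or outside a solver's supported domain.
"""


class PathcomplexError(Exception):
    """Base class for all package errors."""


class StructuralError(PathcomplexError):
    """Malformed pathway structure: dangling ids, non-injective embeddings,
    out-of-range step indices. Distinct from a false validity verdict."""


class DomainError(PathcomplexError, ValueError):
    """Input outside an operation's domain (empty string, n < 1, symbol not
    in the declared alphabet, ...)."""


class SizeLimitError(PathcomplexError):
    """Refusal of an input above a solver's exact-search size cap."""


class ArchetypeError(PathcomplexError):
    """Invalid archetype specification (e.g. equivalence-closure violation)."""


class ParseError(PathcomplexError):
    """Malformed input file."""
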