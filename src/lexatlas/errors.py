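"""Exception hierarchy for lexatlas.

All package-raised errors derive from :class:`LexatlasError` so callers
(and the CLI) can catch one base class.
"""


class LexatlasError(Exception):
    """Base class for all lexatlas errors."""


class FormatError(LexatlasError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(LexatlasError):
    """A value violates a domain invariant (range, finiteness, arity)."""


class KeyLookupError(LexatlasError):
    """A (lemma, pos) key is absent from the lexicon or graph."""


class ConflictError(LexatlasError):
    """Two anchored entries make contradictory demands (no silent overwrite)."""


class BootstrapError(LexatlasError):
    """Propagation cannot start: no scored anchors in the lexicon."""


class EmptyPoleError(LexatlasError):
    """A construct pole has no words resolvable in the lexicon."""


class InsufficiencyError(LexatlasError):
    """The antonym pool cannot cover a required cell pair."""

    def __init__(self, message, cell_pair=None):
        super().__init__(message)
        self.cell_pair = cell_pair


class DegenerateParametersError(LexatlasError):
    """Synthetic-data parameters admit no valid output (e.g. edgeless graph)."""
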