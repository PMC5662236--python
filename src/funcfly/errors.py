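"""Exception types raised across the package."""


class FuncflyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FuncflyError, ValueError):
    """A file does not conform to its declared format (column counts, stanzas...)."""


class ValidationError(FuncflyError, ValueError):
    """Structurally valid input violates a domain invariant (negative expression,
    duplicated identifiers, non-numeric cells...)."""


class ParameterError(FuncflyError, ValueError):
    """A caller-supplied parameter is outside its admissible range."""


class CycleError(FuncflyError, ValueError):
    """The ontology graph contains a directed cycle; carries one offending cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"ontology contains a cycle: {' -> '.join(self.cycle)}")


class DatasetError(FuncflyError, ValueError):
    """A per-term dataset cannot be built or split (too few positives/negatives)."""


class DegenerateModelError(FuncflyError, ValueError):
    """A trained model carries no usable signal (e.g. all feature importances 0)."""
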