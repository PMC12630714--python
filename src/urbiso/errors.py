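"""Typed exceptions raised by urbiso readers, validators and analyses."""


class UrbisoError(Exception):
    """Base class for all urbiso errors."""


class SchemaError(UrbisoError):
    """A required column or field is missing from an input file."""


class ValidationError(UrbisoError):
    """A record violates a domain invariant (range, sign, uniqueness)."""


class ReferentialError(UrbisoError):
    """A cross-reference (edge endpoint, city_ref) does not resolve."""


class GenerationError(UrbisoError):
    """A synthetic configuration cannot produce a valid dataset."""


class AnalysisError(UrbisoError):
    """An analysis precondition is not met (too few cities, empty group...)."""
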