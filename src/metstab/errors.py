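"""Exception hierarchy shared across the package."""


class MetstabError(Exception):
    """Base class for all metstab errors."""


class FormatError(MetstabError):
    """Input file does not conform to the expected layout (missing/bad columns)."""


class ValidationError(MetstabError):
    """Data violate a structural invariant (duplicate keys, non-finite values...)."""


class CompletenessError(MetstabError):
    """A genotype x environment two-way table has empty cells."""


class DesignError(MetstabError):
    """Experimental-design requirement not met (too few blocks/environments...)."""


class DegenerateError(MetstabError):
    """Computation undefined on this input (zero variance, collinear markers...)."""
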