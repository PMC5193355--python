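"""Exception hierarchy for indelsift."""


class IndelSiftError(Exception):
    """Base class for all package-specific errors."""


class VcfParseError(IndelSiftError):
    """A VCF source could not be parsed."""


class SampleLookupError(IndelSiftError, KeyError):
    """A requested sample id is not present in the source."""


class DegenerateVariantError(IndelSiftError):
    """ref == alt after normalization; the record encodes no variant."""


class ValidationError(IndelSiftError, ValueError):
    """An input value violates a documented precondition."""


class MissingGenotypeError(IndelSiftError):
    """A dosage required by the contrast filter is missing."""


class ConsistencyError(IndelSiftError):
    """Conflicting reference alleles at one site during merging."""


class MapCoverageError(IndelSiftError):
    """A chromosome is absent from the genetic map."""


class ModelValidationError(IndelSiftError):
    """A gene model contains an invalid interval."""


class ConfigError(IndelSiftError):
    """A simulation or pipeline configuration is infeasible."""
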