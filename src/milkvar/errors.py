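"""Typed exceptions shared across the package."""


class MilkvarError(Exception):
    """Base class for all package errors."""


class RangeError(MilkvarError):
    """A position falls outside the supported coordinate range."""


class UnsupportedVariantError(MilkvarError):
    """Raised for non-SNV records where only single-base substitutions are handled."""


class FormatError(MilkvarError):
    """A required field or column is missing from an input file."""


class PanelError(MilkvarError):
    """Sample panel and VCF header disagree."""


class ConfigError(MilkvarError):
    """Invalid configuration values."""


class IntegrityError(MilkvarError):
    """Internal inconsistency between data structures that should agree."""


class CombinatorialLimitError(MilkvarError):
    """Too many heterozygous sites to enumerate haplotype pairs."""
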