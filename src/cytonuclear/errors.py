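"""Exception hierarchy shared across the package."""


class CytonuclearError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CytonuclearError, ValueError):
    """Input data or parameters violate a documented contract."""


class TableFormatError(ValidationError):
    """An annotation table is structurally malformed (e.g. missing column)."""


class UndefinedStatisticError(ValidationError):
    """A statistic has no defined value (zero denominator, empty set)."""


class EnumerationLimitError(CytonuclearError, RuntimeError):
    """Exact-test enumeration would exceed the configured table cap.

    The asymptotic chi-square p-value (``chisq_pvalue``) is the intended
    fallback for tables this large.
    """
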