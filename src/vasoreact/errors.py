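"""Exception hierarchy shared across the package."""


class VasoreactError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VasoreactError, ValueError):
    """A simulation or analysis parameter violates its declared domain."""


class DomainError(VasoreactError, ValueError):
    """A physical quantity is outside the domain of a formula (e.g. MAP <= 0)."""


class InsufficientDataError(VasoreactError, ValueError):
    """A recording does not cover the window an operation needs."""


class DegenerateDataError(VasoreactError, ValueError):
    """Data carry no information for the requested statistic."""


class DesignError(VasoreactError, ValueError):
    """A cohort table does not form the factorial design an analysis requires."""
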