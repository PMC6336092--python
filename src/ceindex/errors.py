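"""Exception hierarchy for the assessment pipeline."""


class CEIError(Exception):
    """Base class for all assessment errors."""


class SchemaError(CEIError):
    """Configuration or input data violates the documented schema."""


class ReferenceUndefinedError(CEIError):
    """No positive retained observation; the reference point cannot be set."""

    def __init__(self, service_id: str):
        self.service_id = service_id
        super().__init__(
            f"REFERENCE_UNDEFINED: all retained observations for service "
            f"{service_id!r} are zero or missing; normalization is impossible"
        )


class DegenerateAbscissaError(CEIError):
    """All trend points share one year; a slope cannot be fit."""

    def __init__(self, year: int):
        super().__init__(
            f"DEGENERATE_ABSCISSA: all trend points fall in year {year}"
        )


class EmptyCommunityError(CEIError):
    """All abundance counts are zero; diversity is undefined."""


class UnknownPairError(CEIError, KeyError):
    """A (site, service) pair absent from the assessment was requested."""

    def __init__(self, site_id: str, service_id: str):
        super().__init__(f"no scored cell for site {site_id!r}, service {service_id!r}")
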