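"""Exception hierarchy for the MR toolkit."""


class MRKitError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(MRKitError):
    """A file, column map, or analysis plan is malformed."""


class ValidationError(MRKitError):
    """An input value violates a documented invariant."""


class NoInstrumentsError(MRKitError):
    """Instrument selection returned an empty set."""

    def __init__(self, p_threshold: float):
        self.p_threshold = p_threshold
        super().__init__(
            f"no instruments reach the significance threshold p < {p_threshold:g}"
        )


class HarmonizationError(MRKitError):
    """No instrument survived exposure/outcome harmonization."""


class DegenerateInstrumentError(MRKitError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""

    def __init__(self, variant_id: str):
        self.variant_id = variant_id
        super().__init__(
            f"instrument {variant_id} has zero exposure effect; "
            "the Wald ratio is undefined"
        )


class InsufficientInstrumentsError(MRKitError):
    """An estimator or diagnostic needs more instruments than were supplied."""

    def __init__(self, needed: int, got: int, what: str):
        self.needed = needed
        self.got = got
        super().__init__(f"{what} requires >= {needed} instruments, got {got}")


class SingularCorrelationError(MRKitError):
    """The LD-weighted covariance matrix is (numerically) singular."""

    def __init__(self) -> None:
        super().__init__(
            "instrument covariance matrix is singular; prune perfectly "
            "correlated instruments (|r| = 1) before the correlated IVW fit"
        )
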