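"""Exception types shared across the package."""


class RvPowerError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RvPowerError, ValueError):
    """A function argument is outside its documented domain."""


class InfeasibleSFSError(RvPowerError):
    """The requested site-frequency-spectrum target would require *adding*
    variants to at least one frequency bin; thinning can only remove."""


class NoSupportError(RvPowerError):
    """A frequency-effect map has no sampling weight at the queried MAF."""


class InfeasibleEffectError(RvPowerError):
    """A (MAF, RR, prevalence) combination has no valid penetrance solution
    in (0, 1) under the additive relative-risk coding."""


class ExhaustionError(RvPowerError):
    """An iterative sampler exceeded its restart / iteration budget."""


class NoQualifyingVariantsError(RvPowerError):
    """No variant passes the MAF filter, so a gene-based test is undefined."""


class ResolutionError(RvPowerError):
    """Too few null replicates to resolve the requested false-positive rate."""
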