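"""Exception types shared across the package."""


class MRLHError(Exception):
    """Base class for all package errors."""


class FormatError(MRLHError):
    """A file or table does not conform to the documented schema."""


class ConfigError(MRLHError):
    """An invalid simulation or analysis configuration."""


class MonomorphicVariantError(MRLHError):
    """LD was requested for a variant with zero dosage variance."""

    def __init__(self, variant_id: str):
        self.variant_id = variant_id
        super().__init__(f"variant {variant_id!r} is monomorphic among complete cases")


class NoInstrumentsError(MRLHError):
    """Instrument filtering/clumping left nothing to analyse."""


class HarmonizationError(MRLHError):
    """Harmonization retained zero variants."""


class UndefinedRatioError(MRLHError):
    """Wald ratio requested with a zero exposure association."""


class CollinearityError(MRLHError):
    """The multivariable exposure design is (numerically) rank deficient."""


class EstimatorInputError(MRLHError):
    """Too few variants, or otherwise unusable input, for an estimator."""
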