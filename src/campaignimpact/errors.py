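"""Exception types shared across the package."""


class CampaignImpactError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CampaignImpactError):
    """An input configuration is invalid (bad probability, path, window...)."""


class NonEstimableError(CampaignImpactError):
    """A model or statistic cannot be computed from the given data."""


class EmptyInputError(CampaignImpactError):
    """An operation that requires data received none."""


class CorpusFormatError(CampaignImpactError):
    """A corpus file is malformed beyond the tolerated fraction."""
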