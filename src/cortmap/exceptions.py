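"""Exception hierarchy used across the package.

Analysis functions signal degenerate inputs explicitly instead of returning
silent NaNs; callers that aggregate over cells/pairs catch the specific
subclasses and record the exclusion.
"""


class CortmapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CortmapError, ValueError):
    """Invalid parameter value or inconsistent configuration."""


class MissingSitesError(CortmapError):
    """A gridded recording is missing stimulation sites."""

    def __init__(self, sites):
        self.sites = sorted(sites)
        super().__init__(f"missing stimulation sites: {self.sites}")


class UndefinedResultError(CortmapError):
    """The requested statistic is undefined for this input (e.g. no
    significant pixels, zero total input)."""


class TooWeakSignalError(CortmapError):
    """A projection/band is too weak to quantify."""


class ExcludedPairError(CortmapError):
    """A cell pair cannot enter the cohort statistic (e.g. zero Pyr total);
    the exclusion is recorded by the caller rather than silently dropped."""


class IndeterminateConnectionError(CortmapError):
    """Connectivity cannot be assessed (no presynaptic spikes at any step)."""


class SchemaError(CortmapError):
    """Sweep-container file does not match the expected schema/version."""
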