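"""Exception hierarchy shared across the pipeline."""


class HistoError(Exception):
    """Base class for all histocascade errors."""


class FormatError(HistoError):
    """File is not a readable (pyramidal) image."""


class MetadataError(HistoError):
    """Required image metadata (e.g. base magnification) is missing."""


class BoundsError(HistoError):
    """Region request extends outside the stored image."""


class ResolutionError(HistoError):
    """Requested magnification exceeds the base magnification."""


class ChannelError(HistoError):
    """Image has the wrong number of channels for the operation."""


class GeometryError(HistoError):
    """Arrays that must be spatially aligned are not."""


class ConfigError(HistoError):
    """Unknown identifier or invalid configuration value."""


class GenerationError(HistoError):
    """Synthetic data generation could not satisfy its constraints."""


class EmptyCohortError(HistoError):
    """No usable patches/WSIs in the cohort."""


class SampleSizeError(HistoError):
    """Too few samples for the requested fit."""


class ModelError(HistoError):
    """Model handle is incompatible with the requested operation."""
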