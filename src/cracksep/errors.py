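"""Exception hierarchy shared across the pipeline."""


class CrackSepError(Exception):
    """Base class for all errors raised by this package."""


class UnsupportedImageError(CrackSepError):
    """Input image is not a single-channel 8-bit grayscale image.

    The pipeline consumes images that were already preprocessed (8-bit
    conversion, channel selection, contrast enhancement, median smoothing);
    it never converts silently, because conversion would change the meaning
    of the intensity threshold encoded in the filename.
    """


class NamingConventionError(CrackSepError):
    """Filename does not carry the required ``_XXXthld`` threshold suffix."""


class EmptyDatasetError(CrackSepError):
    """Dataset root contains no series with at least one conforming image."""


class ConfigurationError(CrackSepError):
    """A parameter is outside its allowed domain."""


class InsufficientSampleError(CrackSepError):
    """A statistical routine received fewer observations than it requires."""


class ContractViolationError(CrackSepError):
    """An internal quantity violated its documented invariant."""


class SceneError(CrackSepError):
    """A synthetic scene description is invalid (e.g. overlapping cracks)."""
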