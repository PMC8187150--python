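"""Exception hierarchy.

Every error raised by the package derives from :class:`EpisigError` so callers
can catch domain failures without swallowing programming errors.
"""


class EpisigError(Exception):
    """Base class for all episig-specific failures."""


# --- input / format layer ---------------------------------------------------

class FormatError(EpisigError):
    """A file does not match the expected text layout (header, columns)."""


class BetaRangeError(EpisigError):
    """A beta value (or fraction-like parameter) falls outside [0, 1]."""


class ReconciliationError(EpisigError):
    """Sample sheet and beta matrix disagree about which samples exist."""


class SchemaError(EpisigError):
    """A table violates a per-row schema invariant (roles, labels, links)."""


# --- knowledge database -----------------------------------------------------

class IntegrityError(EpisigError):
    """Cross-references inside a knowledge database do not resolve."""


class CorruptStoreError(EpisigError):
    """An on-disk knowledge database is missing a required component."""


# --- signature discovery ----------------------------------------------------

class CohortSizeError(EpisigError):
    """Too few reference cases or controls for the requested operation."""


class EmptySignatureError(EpisigError):
    """No probe survived selection; an empty signature is never returned silently."""


class MergeError(EpisigError):
    """Signatures cannot be merged (version or identifier scheme conflict)."""


# --- classification ---------------------------------------------------------

class TrainingError(EpisigError):
    """Classifier training received a single class or otherwise unusable labels."""


class FoldError(EpisigError):
    """Cross-validation fold count exceeds the positive-class size."""


class CalibrationError(EpisigError):
    """Platt calibration requires decision values from both classes."""


# --- evidence ---------------------------------------------------------------

class EmbeddingError(EpisigError):
    """Too few samples to embed."""


class SeparabilityError(EpisigError):
    """Reference cases and controls do not split at the k=2 tree cut."""


# --- locus screening --------------------------------------------------------

class LocusCoverageError(EpisigError):
    """Fewer than the minimum number of probes available for a locus."""


class ControlReferenceError(EpisigError):
    """Control reference statistics are unusable (e.g. non-positive SD)."""


# --- reporting --------------------------------------------------------------

class CompositionError(EpisigError):
    """Evidence items passed to a report do not describe the same sample."""


class ComparisonError(EpisigError):
    """Replicate results cannot be compared (disorder panels differ)."""
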