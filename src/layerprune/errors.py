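"""Exception taxonomy for the layerprune toolkit.

Every error raised by the library derives from :class:`LayerPruneError`,
so callers (and the CLI) can map failure classes to exit codes without
string matching.
"""


class LayerPruneError(Exception):
    """Base class for all layerprune errors."""


class InvalidArgumentError(LayerPruneError, ValueError):
    """A caller-supplied argument violates an operation's contract."""


class InvalidDataError(LayerPruneError, ValueError):
    """A dataset or input batch violates a precondition (empty split,
    single-class labels, sequence longer than the model's window, ...)."""


class ParseError(LayerPruneError, ValueError):
    """A serialized dataset or report could not be parsed; the message
    names the offending line or column."""


class ResourceError(LayerPruneError, RuntimeError):
    """An external resource (checkpoint, benchmark accession) could not
    be retrieved."""


class UnknownSplitError(ResourceError):
    """The requested benchmark split name does not exist for the task."""


class UnsupportedArchitectureError(ResourceError):
    """A checkpoint was retrieved but is not an encoder-only transformer
    with an enumerable layer stack."""


class NumericFailureError(LayerPruneError, ArithmeticError):
    """Training produced a non-finite loss; the message names the epoch."""


class StalenessError(LayerPruneError, RuntimeError):
    """A resume directory's digest does not match the current data or
    configuration; continuing would silently mix experiments."""


class ConfigError(LayerPruneError, ValueError):
    """A run configuration failed validation; the message aggregates every
    offending key rather than stopping at the first."""


class GenerationError(LayerPruneError, RuntimeError):
    """The synthetic generator could not satisfy its constraints (e.g.
    rejection sampling of motif-free backgrounds exceeded its cap)."""


class CannotBuildVariantError(LayerPruneError, ValueError):
    """A pruned variant cannot be constructed from the classification
    (no cornerstone layers, or every layer marked unfavourable)."""


class DegenerateTimingError(LayerPruneError, ArithmeticError):
    """A baseline wall time of zero makes time proportions undefined."""


class AurocUndefinedError(InvalidDataError):
    """AUROC is undefined because only one class is present.

    The partially filled result (confusion counts, accuracy, F1, %TP)
    is attached as the ``partial`` attribute.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial
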