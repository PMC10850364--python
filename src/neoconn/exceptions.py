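"""Error hierarchy for the neoconn pipeline.

All neoconn errors derive from :class:`NeoconnError` so callers can catch the
package's failures with one clause; most also derive from the closest builtin
(``ValueError`` / ``OSError``) so they behave idiomatically in generic code.
"""


class NeoconnError(Exception):
    """Base class for all neoconn errors."""


class ConfigurationError(NeoconnError, ValueError):
    """Invalid simulation / filter / pipeline configuration."""


class DimensionError(NeoconnError, ValueError):
    """Array shapes or node sets do not line up."""


class LayoutError(NeoconnError, ValueError):
    """Montage layout violates its invariants (e.g. an empty lobe)."""


class FormatError(NeoconnError, ValueError):
    """A file does not match its declared on-disk format."""


class DegenerateDataError(NeoconnError, ValueError):
    """Data degenerate for the requested statistic (constant channel, zero variance)."""


class ComparisonError(NeoconnError, ValueError):
    """Two objects being compared are incompatible (node order, sparsity, pairing)."""


class PartitionError(NeoconnError, ValueError):
    """A community partition does not cover the node set."""


class CompletenessError(NeoconnError, ValueError):
    """A table is missing required (group, sparsity, metric) cells."""


class StatisticalError(NeoconnError, ValueError):
    """A statistical procedure cannot run on the given sample."""


class EmptySelectionError(NeoconnError, ValueError):
    """Feature selection retained zero columns; no model can be trained."""


class StratificationError(NeoconnError, ValueError):
    """Cross-validation folds cannot be stratified with the given labels."""


class PipelineError(NeoconnError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
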