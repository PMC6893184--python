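"""Exception hierarchy for recgain."""


class RecgainError(Exception):
    """Base class for all recgain errors."""


class InvalidMapError(RecgainError, ValueError):
    """Marker table cannot define a genetic map (too few markers, bad ordering)."""


class InconsistentMapError(InvalidMapError):
    """Genetic positions decrease beyond the smoothing tolerance."""


class OutOfRangeError(RecgainError, ValueError):
    """Physical position queried outside the mapped range."""


class InvalidTargetError(RecgainError, ValueError):
    """Landscape transform asked to shrink or keep the genetic length."""


class InvalidCountError(RecgainError, ValueError):
    """Marker/QTL count below the minimum."""


class InsufficientGenesError(RecgainError, ValueError):
    """More QTL requested than genes available on a chromosome."""


class UnsortedInputError(RecgainError, ValueError):
    """Positions expected sorted were not."""


class InvalidInterferenceError(RecgainError, ValueError):
    """Gamma interference shape parameter below 1."""


class DegenerateTraitError(RecgainError, ValueError):
    """Zero genetic variance where a heritability < 1 is required."""


class DegenerateFitError(RecgainError, ValueError):
    """RR-BLUP asked to fit a constant response."""


class PanelMismatchError(RecgainError, ValueError):
    """Genotype matrix does not match the trained marker panel."""


class InsufficientReplicatesError(RecgainError, ValueError):
    """Fewer than two replicates for an aggregate statistic."""
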