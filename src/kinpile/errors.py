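"""Exception hierarchy for kinpile."""


class KinpileError(Exception):
    """Base class for all kinpile errors."""


class PanelFormatError(KinpileError):
    """A frequency-panel file is malformed or empty after filtering."""


class PileupParseError(KinpileError):
    """A pileup line could not be parsed."""


class PlinkFormatError(KinpileError):
    """A PLINK text file is malformed."""


class NoOverlapError(KinpileError):
    """A pair of individuals shares no usable loci."""


class EstimatorError(KinpileError):
    """Invalid inputs to the relatedness estimator."""


class SimulationRangeError(KinpileError):
    """An HRC estimate falls outside every simulated class distribution."""
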