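"""Exception hierarchy for tracekit."""


class TraceKitError(Exception):
    """Base class for all tracekit errors."""


class TraceFormatError(TraceKitError):
    """A trace file could not be parsed (bad magic, missing tag, truncation)."""


class UnsupportedFormatError(TraceKitError):
    """An unknown output/report format token was requested."""


class SimulationError(TraceKitError):
    """Invalid chromatogram simulation parameters."""


class AnchorError(TraceKitError):
    """A trace could not be anchored in the reference genome."""


class AmbiguousAnchorError(AnchorError):
    """Two or more loci received the same maximal seed support.

    The tied candidate anchors are attached as ``candidates``.
    """

    def __init__(self, message, candidates):
        super().__init__(message)
        self.candidates = candidates


class AlignmentError(TraceKitError):
    """Invalid alignment input (empty profile/sequence)."""


class DecompositionError(TraceKitError):
    """Allele decomposition could not be carried out."""


class VcfError(TraceKitError):
    """Invalid variant records handed to the VCF writer."""
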