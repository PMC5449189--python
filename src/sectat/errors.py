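"""Exception hierarchy."""


class SectatError(Exception):
    """Base class for all errors raised by sectat."""


class FastaError(SectatError):
    """Malformed or unusable FASTA input."""


class AlphabetError(SectatError):
    """A residue outside the accepted amino-acid alphabet."""


class TopologyFormatError(SectatError):
    """Malformed imported topology (TMHMM short line or i/o/M string)."""


class SpanError(SectatError):
    """A residue span that does not fit the sequence."""


class ScaleError(SectatError):
    """Malformed or incomplete hydrophobicity-scale configuration."""


class SynthesisError(SectatError):
    """The synthetic-sequence generator could not satisfy its target."""
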