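"""Exception hierarchy shared across the package."""


class ScanmutError(Exception):
    """Base class for all package-specific errors."""


class IllegalCharacter(ScanmutError):
    """A residual non-ACGTN character after input normalization."""

    def __init__(self, position: int, char: str):
        self.position = position
        self.char = char
        super().__init__(f"illegal character {char!r} at position {position}")


class EmptySequence(ScanmutError):
    """An operation that needs at least one base received none."""


class LengthMismatch(ScanmutError):
    """Two sequences that must be aligned position-by-position differ in length."""


class TooShort(ScanmutError):
    """Sequence shorter than the minimum an operation requires."""


class FrameOutOfRange(ScanmutError):
    """Translation frame offset at or beyond the sequence end."""


class PositionOutOfRange(ScanmutError):
    """Requested residue lacks the template flank needed for primer design."""


class RangeInvalid(ScanmutError):
    """An amino-acid range is empty, inverted or outside the ORF."""


class NoFeasiblePrimer(ScanmutError):
    """No primer (pair) satisfies the active constraint set."""


class EndMismatch(ScanmutError):
    """Simulated PCR product ends are not identical — designer bug."""


class AnchorOverlapsMutation(ScanmutError):
    """Two-fragment anchor region collides with the mutation site."""


class NoOverlap(ScanmutError):
    """Read and reference share no scoring alignment window."""


class JunctionMismatch(ScanmutError):
    """Cloning amplicon ends disagree at a junction — designer bug."""


class InclusionTooLong(ScanmutError):
    """A primer overhang would exceed the synthesis length limit."""


class MalformedFasta(ScanmutError):
    """Input file is not parseable FASTA."""


class SpecInvalid(ScanmutError):
    """Fixture specification is internally inconsistent."""
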