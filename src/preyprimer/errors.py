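"""Exception hierarchy.

Everything raised on bad user input derives from :class:`PreyPrimerError`,
so callers (and the CLI) can catch one type.
"""


class PreyPrimerError(ValueError):
    """Base class for all input-contract violations."""


class InvalidSequenceError(PreyPrimerError):
    """A residue outside the IUPAC nucleotide alphabet (plus '-')."""


class UnsupportedOligoError(PreyPrimerError):
    """Oligo too short (or otherwise unsuitable) for thermodynamics."""


class AlignmentContractError(PreyPrimerError):
    """Two strings that must be aligned (equal length) are not."""


class LengthMismatchError(PreyPrimerError):
    """Ragged multiple alignment."""


class PanelCompositionError(PreyPrimerError):
    """Panel violates the one-target / >=1-confounder composition."""


class SpanError(PreyPrimerError):
    """Coordinate span out of range or too short."""


class GapInPrimerError(PreyPrimerError):
    """A primer footprint crosses a gap in the reference."""


class GeometryError(PreyPrimerError):
    """Primer pair footprints overlap or are inverted."""


class IncompleteRecordError(PreyPrimerError):
    """Non-empty-gut assay record missing a PCR call."""


class EmptySurveyError(PreyPrimerError):
    """No assay records to summarize."""


class FixtureSpecError(PreyPrimerError):
    """Infeasible synthetic-panel or survey specification."""
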